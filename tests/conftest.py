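"""Shared fixtures: random variant tables and small simulation configs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from efrsnet.efrs import DAMAGE_SOURCES, VariantTable


def make_variant_table(
    rng: np.random.Generator,
    n_variants: int = 50,
    n_subjects: int = 10,
    maf_max: float = 0.05,
    missing_score_fraction: float = 0.0,
) -> VariantTable:
    """Random annotated variant table with {0,1,2} allele counts."""
    bases = np.array(list("ACGT"))
    ref = rng.integers(0, 4, n_variants)
    alt = (ref + rng.integers(1, 4, n_variants)) % 4
    variants = pd.DataFrame(
        {
            "chrom": [f"chr{1 + i % 22}" for i in range(n_variants)],
            "pos": 1000 + 13 * np.arange(n_variants),
            "ref": bases[ref],
            "alt": bases[alt],
            "maf_panel1": rng.uniform(0.0, maf_max, n_variants),
            "maf_panel2": rng.uniform(0.0, maf_max, n_variants),
            "LRT": rng.uniform(0, 1, n_variants),
            "MutationAssessor": rng.uniform(-6, 6, n_variants),
            "PolyPhen2": rng.uniform(0, 1, n_variants),
            "SIFT": rng.uniform(0, 1, n_variants),
            "CADD": rng.uniform(0, 60, n_variants),
            "in_target_set": rng.random(n_variants) < 0.7,
        }
    )
    if missing_score_fraction > 0:
        for src in DAMAGE_SOURCES:
            drop = rng.random(n_variants) < missing_score_fraction
            variants.loc[drop, src] = np.nan
    genotypes = pd.DataFrame(
        rng.integers(0, 3, size=(n_variants, n_subjects)).astype(np.int8),
        columns=[f"s{k:03d}" for k in range(n_subjects)],
    )
    return VariantTable(variants, genotypes)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240516)


@pytest.fixture
def variant_table(rng) -> VariantTable:
    return make_variant_table(rng)
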