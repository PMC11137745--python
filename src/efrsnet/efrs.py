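"""Exome functional risk score (EFRS).

The EFRS is an additive rare-variant burden score. For each subject it sums,
over rare exonic variants, the product of

* ``v_all`` — the subject's alternative-allele count (0, 1 or 2),
* ``w_s``  — a functional-damage weight in [0, 1] derived from one of five
  annotation sources (LRT, MutationAssessor, PolyPhen-2, SIFT, CADD), and
* ``w_f``  — a frequency weight in (0, 1] that up-weights rarer variants.

"Rare" means a minor allele frequency below a threshold (default 0.01) in
*both* reference panels (an East-Asian 1000 Genomes style panel and an
ExAC-style panel). Because damage and rarity are weighted simultaneously,
the score does not hinge on any single variant being observed, which keeps
it stable across subjects with disjoint variant sets.
"""

from __future__ import annotations

from collections.abc import Callable, Mapping
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DAMAGE_SOURCES",
    "SCORE_RANGES",
    "VariantTable",
    "WeightConfig",
    "EFRSResult",
    "filter_rare_variants",
    "functional_weight",
    "frequency_weight",
    "compute_efrs",
    "read_variant_table",
]

DAMAGE_SOURCES = ("LRT", "MutationAssessor", "PolyPhen2", "SIFT", "CADD")

#: Documented raw-score ranges per annotation source. Values outside these
#: ranges raise, rather than being silently clamped into a weight.
SCORE_RANGES: dict[str, tuple[float, float]] = {
    "LRT": (0.0, 1.0),            # p-value-like; small = deleterious
    "MutationAssessor": (-6.0, 6.0),  # functional-impact score; large = deleterious
    "PolyPhen2": (0.0, 1.0),      # probability damaging
    "SIFT": (0.0, 1.0),           # tolerance score; small = deleterious
    "CADD": (0.0, 99.0),          # phred-scaled
}

VARIANT_KEY = ["chrom", "pos", "ref", "alt"]


class ValidationError(ValueError):
    """Raised when a variant table or weight input violates its contract."""


@dataclass
class VariantTable:
    """Annotated variants plus per-subject alternative-allele counts.

    ``variants`` has one row per bi-allelic variant with columns
    ``chrom, pos, ref, alt, maf_panel1, maf_panel2``, one column per damage
    source in :data:`DAMAGE_SOURCES`, and a boolean ``in_target_set`` flag
    (membership in an externally defined ASD variant-site list).
    ``genotypes`` is aligned row-for-row with ``variants`` and holds one
    column per subject with values in {0, 1, 2}. Positions are 1-based.
    """

    variants: pd.DataFrame
    genotypes: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [c for c in VARIANT_KEY + ["maf_panel1", "maf_panel2"]
                   if c not in self.variants.columns]
        if missing:
            raise ValidationError(f"variant table missing columns: {missing}")
        if len(self.variants) != len(self.genotypes):
            raise ValidationError(
                f"{len(self.variants)} variants vs {len(self.genotypes)} genotype rows"
            )
        for col in ("maf_panel1", "maf_panel2"):
            vals = self.variants[col].to_numpy(dtype=float)
            ok = np.isnan(vals) | ((vals >= 0.0) & (vals <= 1.0))
            if not ok.all():
                raise ValidationError(f"{col} outside [0, 1]")
        if len(self.variants):
            if self.variants.duplicated(VARIANT_KEY).any():
                raise ValidationError("duplicate (chrom, pos, ref, alt) rows")
            gt = self.genotypes.to_numpy()
            if gt.size and not np.isin(gt, (0, 1, 2)).all():
                raise ValidationError("allele counts must be in {0, 1, 2}")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def subjects(self) -> list[str]:
        return list(self.genotypes.columns)

    def take(self, mask: np.ndarray) -> "VariantTable":
        """Row-subset both frames, preserving order."""
        return VariantTable(
            self.variants.loc[mask].reset_index(drop=True),
            self.genotypes.loc[mask].reset_index(drop=True),
        )


def _one_minus_mean_maf(maf1: float, maf2: float) -> float:
    mafs = [m for m in (maf1, maf2) if not np.isnan(m)]
    if not mafs:
        raise ValidationError("both panel frequencies missing")
    return 1.0 - float(np.mean(mafs))


def _neglog10_maf(maf1: float, maf2: float, eps: float = 1e-6, cap: float = 6.0) -> float:
    mafs = [m for m in (maf1, maf2) if not np.isnan(m)]
    if not mafs:
        raise ValidationError("both panel frequencies missing")
    w = -np.log10(float(np.mean(mafs)) + eps) / cap
    return float(np.clip(w, 1e-12, 1.0))


FREQUENCY_RULES: dict[str, Callable[[float, float], float]] = {
    "one_minus_mean_maf": _one_minus_mean_maf,
    "neglog10_maf": _neglog10_maf,
}


@dataclass(frozen=True)
class WeightConfig:
    """Choices that parameterize the score.

    ``source`` selects the annotation feeding w_s (default CADD);
    ``frequency_rule`` names the w_f strategy (default ``one_minus_mean_maf``,
    i.e. w_f = 1 - mean panel MAF); ``maf_threshold`` is the rarity cut
    applied to both panels; ``restrict_to_target_set`` limits the sum to
    variants flagged ``in_target_set``.
    """

    source: str = "CADD"
    frequency_rule: str = "one_minus_mean_maf"
    maf_threshold: float = 0.01
    restrict_to_target_set: bool = False

    def __post_init__(self) -> None:
        if self.source not in DAMAGE_SOURCES:
            raise ValidationError(f"unknown damage source {self.source!r}")
        if self.frequency_rule not in FREQUENCY_RULES:
            raise ValidationError(f"unknown frequency rule {self.frequency_rule!r}")
        if not (0.0 < self.maf_threshold <= 1.0):
            raise ValidationError("maf_threshold must be in (0, 1]")


@dataclass
class EFRSResult:
    """Per-subject scores plus provenance of how they were computed."""

    scores: pd.Series            # subject -> score, >= 0
    n_variants_used: int
    n_dropped: int               # variants lacking the chosen damage score
    config: WeightConfig = field(default_factory=WeightConfig)


def filter_rare_variants(table: VariantTable, threshold: float = 0.01) -> VariantTable:
    """Retain variants with MAF < ``threshold`` in both reference panels.

    A frequency missing from a panel is treated as 0 for filtering (absence
    from a panel is itself evidence of rarity). Row order is preserved; an
    empty table filters to an empty table.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValidationError("threshold must be in (0, 1]")
    if table.n_variants == 0:
        return table
    maf1 = table.variants["maf_panel1"].fillna(0.0).to_numpy(dtype=float)
    maf2 = table.variants["maf_panel2"].fillna(0.0).to_numpy(dtype=float)
    return table.take((maf1 < threshold) & (maf2 < threshold))


def _functional_weights(raw: np.ndarray, source: str) -> np.ndarray:
    """Vectorized raw->w_s map; NaN passes through (handled by caller)."""
    lo, hi = SCORE_RANGES[source]
    finite = ~np.isnan(raw)
    if ((raw[finite] < lo) | (raw[finite] > hi)).any():
        raise ValidationError(f"{source} raw score outside [{lo}, {hi}]")
    if source == "SIFT" or source == "LRT":
        return 1.0 - raw
    if source == "PolyPhen2":
        return raw.copy()
    if source == "CADD":
        return np.minimum(raw / 40.0, 1.0)
    if source == "MutationAssessor":
        return np.clip(raw / 5.0, 0.0, 1.0)
    raise ValidationError(f"unknown damage source {source!r}")  # pragma: no cover


def functional_weight(variant: Mapping[str, float], config: WeightConfig) -> float:
    """Damage weight w_s in [0, 1] for one variant; monotone in deleteriousness.

    SIFT and LRT are inverted (small raw = damaging), PolyPhen-2 is already a
    probability, CADD phred saturates at 40, MutationAssessor is clamped
    linearly over [0, 5].
    """
    raw = float(variant.get(config.source, np.nan))
    if np.isnan(raw):
        raise ValidationError(f"variant lacks a {config.source} score")
    return float(_functional_weights(np.array([raw]), config.source)[0])


def frequency_weight(variant: Mapping[str, float], config: WeightConfig) -> float:
    """Frequency weight w_f in (0, 1]; decreasing in panel frequency."""
    rule = FREQUENCY_RULES[config.frequency_rule]
    return rule(
        float(variant.get("maf_panel1", np.nan)),
        float(variant.get("maf_panel2", np.nan)),
    )


def compute_efrs(table: VariantTable, config: WeightConfig | None = None) -> EFRSResult:
    """Score every subject: EFRS = sum over variants of v_all * w_s * w_f.

    The table is expected to be pre-filtered for rarity (see
    :func:`filter_rare_variants`); variants lacking the configured damage
    source are excluded from the sum and counted in ``n_dropped``. Subjects
    whose allele counts are all zero score exactly 0.
    """
    config = config or WeightConfig()
    variants = table.variants
    genotypes = table.genotypes
    if genotypes.shape[1] == 0:
        raise ValidationError("no subject genotype columns present")

    keep = np.ones(len(variants), dtype=bool)
    if config.restrict_to_target_set and "in_target_set" in variants.columns:
        keep &= variants["in_target_set"].to_numpy(dtype=bool)
    raw = variants[config.source].to_numpy(dtype=float) if config.source in variants else np.full(len(variants), np.nan)
    has_score = ~np.isnan(raw)
    n_dropped = int((keep & ~has_score).sum())
    keep &= has_score

    if keep.sum() == 0:
        zeros = pd.Series(0.0, index=genotypes.columns, name="efrs")
        return EFRSResult(zeros, 0, n_dropped, config)

    w_s = _functional_weights(raw[keep], config.source)
    rule = FREQUENCY_RULES[config.frequency_rule]
    maf1 = variants.loc[keep, "maf_panel1"].to_numpy(dtype=float)
    maf2 = variants.loc[keep, "maf_panel2"].to_numpy(dtype=float)
    w_f = np.array([rule(a, b) for a, b in zip(maf1, maf2)])
    v = genotypes.loc[keep].to_numpy(dtype=float)          # variants x subjects
    scores = pd.Series((v * (w_s * w_f)[:, None]).sum(axis=0),
                       index=genotypes.columns, name="efrs")
    return EFRSResult(scores, int(keep.sum()), n_dropped, config)


# ---------------------------------------------------------------------------
# I/O: VCF (via cyvcf2) + sidecar annotation TSV
# ---------------------------------------------------------------------------

def read_variant_table(vcf_path, annotation_path) -> VariantTable:
    """Assemble a :class:`VariantTable` from a VCF and an annotation TSV.

    The VCF supplies genotypes (multi-allelic records are split into
    bi-allelic rows, alternative-allele counts computed per alternate
    allele; 1-based positions preserved). The TSV supplies the five damage
    scores, the two panel frequencies and the target-set flag, keyed on
    (chrom, pos, ref, alt). Variants absent from the TSV get NaN
    annotations.
    """
    from cyvcf2 import VCF

    rows, gt_rows = [], []
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    for record in vcf:
        genotypes = record.genotypes  # [[a0, a1, phased], ...]
        for alt_idx, alt in enumerate(record.ALT, start=1):
            counts = [
                int(g[0] == alt_idx) + int(g[1] == alt_idx) for g in genotypes
            ]
            rows.append(
                {"chrom": record.CHROM, "pos": record.POS,
                 "ref": record.REF, "alt": alt}
            )
            gt_rows.append(counts)
    vcf.close()

    variants = pd.DataFrame(rows, columns=VARIANT_KEY)
    genotypes = pd.DataFrame(gt_rows, columns=samples, dtype=np.int8)

    ann = pd.read_csv(annotation_path, sep="\t")
    ann = ann.drop_duplicates(VARIANT_KEY)
    merged = variants.merge(ann, on=VARIANT_KEY, how="left")
    if "in_target_set" in merged.columns:
        merged["in_target_set"] = merged["in_target_set"].fillna(False).astype(bool)
    return VariantTable(merged, genotypes)
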