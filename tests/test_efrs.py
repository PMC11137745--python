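"""Rare-variant filtering and EFRS scoring against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from efrsnet.efrs import (
    ValidationError,
    VariantTable,
    WeightConfig,
    compute_efrs,
    filter_rare_variants,
    frequency_weight,
    functional_weight,
    read_variant_table,
)
from conftest import make_variant_table


def efrs_oracle(table: VariantTable, config: WeightConfig) -> pd.Series:
    """Naive triple loop over variants x subjects, term by term."""
    scores = {s: 0.0 for s in table.subjects}
    for k in range(table.n_variants):
        row = table.variants.iloc[k]
        if config.restrict_to_target_set and not row["in_target_set"]:
            continue
        if np.isnan(row[config.source]):
            continue
        w_s = functional_weight(row, config)
        w_f = frequency_weight(row, config)
        for subject in table.subjects:
            scores[subject] += table.genotypes.iloc[k][subject] * w_s * w_f
    return pd.Series(scores)


class TestFilter:
    def test_double_panel_threshold(self, rng):
        table = make_variant_table(rng, n_variants=4, n_subjects=2)
        table.variants.loc[:, ["maf_panel1", "maf_panel2"]] = [
            [0.005, 0.02],   # removed: panel2 common
            [0.0, 0.0],      # retained: rarest case
            [0.009, 0.009],  # retained
            [0.02, 0.005],   # removed: panel1 common
        ]
        kept = filter_rare_variants(table, 0.01)
        assert kept.variants["maf_panel1"].tolist() == [0.0, 0.009]

    def test_matches_bruteforce_row_scan(self, rng):
        table = make_variant_table(rng, n_variants=1000, n_subjects=3, maf_max=0.03)
        kept = filter_rare_variants(table, 0.01)
        expected = [
            k for k in range(table.n_variants)
            if table.variants.iloc[k]["maf_panel1"] < 0.01
            and table.variants.iloc[k]["maf_panel2"] < 0.01
        ]
        assert kept.variants["pos"].tolist() == \
            table.variants.iloc[expected]["pos"].tolist()

    def test_missing_frequency_treated_as_rare(self, rng):
        table = make_variant_table(rng, n_variants=2, n_subjects=2)
        table.variants.loc[:, "maf_panel1"] = [np.nan, np.nan]
        table.variants.loc[:, "maf_panel2"] = [0.001, 0.5]
        kept = filter_rare_variants(table, 0.01)
        assert kept.n_variants == 1

    def test_idempotent_and_empty(self, variant_table):
        once = filter_rare_variants(variant_table, 0.01)
        twice = filter_rare_variants(once, 0.01)
        pd.testing.assert_frame_equal(once.variants, twice.variants)
        empty = once.take(np.zeros(once.n_variants, dtype=bool))
        assert filter_rare_variants(empty, 0.01).n_variants == 0


class TestWeights:
    @pytest.mark.parametrize(
        "source,raw,expected",
        [
            ("SIFT", 0.0, 1.0),            # maximally damaging endpoint
            ("SIFT", 1.0, 0.0),
            ("LRT", 0.0, 1.0),
            ("CADD", 40.0, 1.0),           # saturation of the phred map
            ("CADD", 20.0, 0.5),
            ("PolyPhen2", 0.85, 0.85),     # identity for probability source
            ("MutationAssessor", 2.5, 0.5),
            ("MutationAssessor", -3.0, 0.0),
        ],
    )
    def test_functional_weight_maps(self, source, raw, expected):
        cfg = WeightConfig(source=source)
        assert functional_weight({source: raw}, cfg) == pytest.approx(expected)

    def test_out_of_range_raw_rejected(self):
        with pytest.raises(ValidationError):
            functional_weight({"SIFT": 1.5}, WeightConfig(source="SIFT"))
        with pytest.raises(ValidationError):
            functional_weight({"CADD": -1.0}, WeightConfig(source="CADD"))

    def test_frequency_weight_default_rule(self):
        cfg = WeightConfig()
        assert frequency_weight({"maf_panel1": 0.0, "maf_panel2": 0.0}, cfg) == 1.0
        assert frequency_weight(
            {"maf_panel1": 0.004, "maf_panel2": 0.006}, cfg
        ) == pytest.approx(0.995)
        # one panel missing: mean over the present panel only
        assert frequency_weight(
            {"maf_panel1": np.nan, "maf_panel2": 0.01}, cfg
        ) == pytest.approx(0.99)
        with pytest.raises(ValidationError):
            frequency_weight({"maf_panel1": np.nan, "maf_panel2": np.nan}, cfg)

    def test_frequency_weight_matches_recompute(self, rng):
        cfg = WeightConfig()
        table = make_variant_table(rng, n_variants=200, n_subjects=1)
        for _, row in table.variants.iterrows():
            expected = 1.0 - (row["maf_panel1"] + row["maf_panel2"]) / 2.0
            assert frequency_weight(row, cfg) == pytest.approx(expected, abs=1e-15)


class TestComputeEfrs:
    def test_single_term_product(self):
        variants = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [100], "ref": ["A"], "alt": ["G"],
             "maf_panel1": [0.1], "maf_panel2": [0.1], "PolyPhen2": [0.5]}
        )
        genotypes = pd.DataFrame({"alice": [2], "bob": [0]})
        table = VariantTable(variants, genotypes)
        result = compute_efrs(table, WeightConfig(source="PolyPhen2"))
        assert result.scores["alice"] == pytest.approx(2 * 0.5 * 0.9)  # v*ws*wf
        assert result.scores["bob"] == 0.0

    @pytest.mark.parametrize("source", ["CADD", "SIFT", "PolyPhen2"])
    def test_matches_triple_loop_oracle(self, rng, source):
        cfg = WeightConfig(source=source)
        table = make_variant_table(rng, n_variants=50, n_subjects=10)
        result = compute_efrs(table, cfg)
        oracle = efrs_oracle(table, cfg)
        pd.testing.assert_series_equal(
            result.scores, oracle, check_names=False, atol=1e-12, rtol=0
        )

    def test_missing_scores_dropped_and_counted(self, rng):
        cfg = WeightConfig(source="CADD")
        table = make_variant_table(rng, n_variants=60, n_subjects=4,
                                   missing_score_fraction=0.3)
        result = compute_efrs(table, cfg)
        n_missing = int(table.variants["CADD"].isna().sum())
        assert result.n_dropped == n_missing
        assert result.n_variants_used == table.n_variants - n_missing
        pd.testing.assert_series_equal(
            result.scores, efrs_oracle(table, cfg),
            check_names=False, atol=1e-12, rtol=0,
        )

    def test_target_set_restriction(self, rng):
        cfg = WeightConfig(source="CADD", restrict_to_target_set=True)
        table = make_variant_table(rng, n_variants=40, n_subjects=3)
        result = compute_efrs(table, cfg)
        pd.testing.assert_series_equal(
            result.scores, efrs_oracle(table, cfg),
            check_names=False, atol=1e-12, rtol=0,
        )
        assert result.n_variants_used == int(table.variants["in_target_set"].sum())

    def test_monotone_in_added_variant(self, rng):
        cfg = WeightConfig(source="CADD")
        table = make_variant_table(rng, n_variants=20, n_subjects=3)
        before = compute_efrs(table, cfg).scores
        extra_v = pd.DataFrame(
            {"chrom": ["chrX"], "pos": [1], "ref": ["A"], "alt": ["T"],
             "maf_panel1": [0.001], "maf_panel2": [0.001], "CADD": [30.0]}
        )
        extra_g = pd.DataFrame({c: [1] for c in table.subjects})
        bigger = VariantTable(
            pd.concat([table.variants, extra_v], ignore_index=True),
            pd.concat([table.genotypes, extra_g], ignore_index=True),
        )
        after = compute_efrs(bigger, cfg).scores
        assert (after > before).all()

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_permutation_invariance_and_scale_bound(self, seed):
        """Score is order-free in variant rows and bounded by 2 per variant."""
        local = np.random.default_rng(seed)
        table = make_variant_table(local, n_variants=15, n_subjects=4)
        cfg = WeightConfig(source="SIFT")
        base = compute_efrs(table, cfg)
        perm = local.permutation(table.n_variants)
        shuffled = VariantTable(
            table.variants.iloc[perm].reset_index(drop=True),
            table.genotypes.iloc[perm].reset_index(drop=True),
        )
        pd.testing.assert_series_equal(
            base.scores, compute_efrs(shuffled, cfg).scores,
            check_names=False, atol=1e-12, rtol=0,
        )
        assert (base.scores >= 0).all()
        assert (base.scores <= 2 * base.n_variants_used + 1e-12).all()


def test_vcf_annotation_roundtrip(tmp_path, rng):
    """Writer -> cyvcf2 reader preserves variants, annotations and counts."""
    from efrsnet.synthetic import SimulationConfig, generate_variants, _write_vcf, _write_annotations

    cfg = SimulationConfig(n_subjects=6, n_variants=40, seed=5)
    table = generate_variants(cfg)
    _write_vcf(table, tmp_path / "g.vcf")
    _write_annotations(table, tmp_path / "a.tsv")
    back = read_variant_table(tmp_path / "g.vcf", tmp_path / "a.tsv")
    assert back.n_variants == table.n_variants
    np.testing.assert_array_equal(back.genotypes.to_numpy(),
                                  table.genotypes.to_numpy())
    assert back.subjects == table.subjects
    np.testing.assert_allclose(
        back.variants["maf_panel1"], table.variants["maf_panel1"], rtol=1e-6
    )
    np.testing.assert_allclose(
        back.variants["CADD"], table.variants["CADD"], rtol=1e-6
    )
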