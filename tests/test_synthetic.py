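"""Ground-truth cohort generator: determinism, calibration, planted effects."""

import numpy as np
import pandas as pd
import pytest

from efrsnet import connectivity as conn
from efrsnet.efrs import filter_rare_variants
from efrsnet.synthetic import (
    ConfigurationError,
    GroundTruth,
    InputError,
    ParameterError,
    SimulationConfig,
    generate_morphometry,
    generate_phenotypes,
    generate_timeseries,
    generate_variants,
    make_ground_truth,
    nearest_correlation,
    read_ground_truth,
    simulate_mediation_triples,
    write_cohort,
)

SMALL = dict(n_subjects=20, n_reference_subjects=30, n_regions=8,
             n_timepoints=40, n_variants=100)


def test_config_validation():
    with pytest.raises(ConfigurationError):
        SimulationConfig(n_regions=1)
    with pytest.raises(ConfigurationError):
        SimulationConfig(n_timepoints=2)
    with pytest.raises(ConfigurationError):
        SimulationConfig(n_variants=0)


def test_determinism_under_fixed_seed():
    """Same seed regenerates every artifact bit-identically."""
    outputs = []
    for _ in range(2):
        cfg = SimulationConfig(**SMALL, seed=42)
        gt = make_ground_truth(cfg)
        vt = generate_variants(cfg)
        ts = generate_timeseries(cfg, gt)
        ref, subj = generate_morphometry(cfg, gt)
        fc = np.linspace(-0.2, 0.2, cfg.n_subjects)
        phen = generate_phenotypes(cfg, gt, gt.efrs_true, fc)
        outputs.append((gt, vt, ts, ref, subj, phen))
    (gt1, vt1, ts1, ref1, subj1, ph1), (gt2, vt2, ts2, ref2, subj2, ph2) = outputs
    np.testing.assert_array_equal(gt1.efrs_true, gt2.efrs_true)
    pd.testing.assert_frame_equal(vt1.variants, vt2.variants)
    pd.testing.assert_frame_equal(vt1.genotypes, vt2.genotypes)
    for a, b in zip(ts1, ts2):
        np.testing.assert_array_equal(a.values, b.values)
    pd.testing.assert_frame_equal(ref1, ref2)
    pd.testing.assert_frame_equal(subj1, subj2)
    pd.testing.assert_frame_equal(ph1, ph2)
    assert gt1.perturbed_subjects == gt2.perturbed_subjects


class TestVariants:
    def test_rare_fraction_matches_configured_mass(self):
        cfg = SimulationConfig(n_subjects=5, n_variants=10_000, seed=2)
        vt = generate_variants(cfg)
        frac = float(
            ((vt.variants["maf_panel1"] < 0.01)
             & (vt.variants["maf_panel2"] < 0.01)).mean()
        )
        assert frac == pytest.approx(cfg.maf_mass_below(0.01), abs=0.02)

    def test_all_common_spectrum_filters_to_nothing(self):
        cfg = SimulationConfig(
            n_subjects=5, n_variants=500, seed=3,
            maf_rare_fraction=0.0, maf_common_range=(0.02, 0.3),
        )
        vt = generate_variants(cfg)
        assert filter_rare_variants(vt, 0.01).n_variants == 0

    def test_damage_sources_share_latent_deleteriousness(self):
        vt = generate_variants(SimulationConfig(n_subjects=5, n_variants=3000, seed=4))
        v = vt.variants
        # PolyPhen2 and CADD increase with damage; SIFT decreases
        assert np.corrcoef(v["PolyPhen2"], v["CADD"])[0, 1] > 0.7
        assert np.corrcoef(v["PolyPhen2"], v["SIFT"])[0, 1] < -0.7


class TestTimeseries:
    def test_shape_contract_full_scale(self):
        cfg = SimulationConfig(n_subjects=2, n_reference_subjects=30,
                               n_regions=90, n_timepoints=240, n_variants=10,
                               seed=0)
        gt = make_ground_truth(cfg)
        ts = generate_timeseries(cfg, gt)
        assert all(t.values.shape == (90, 240) for t in ts)
        assert ts[0].labels == cfg.labels()

    def test_null_coupling_uncorrelated_with_gene_score(self):
        cfg = SimulationConfig(n_subjects=200, n_reference_subjects=30,
                               n_regions=8, n_timepoints=120, n_variants=10,
                               seed=0)
        gt = make_ground_truth(cfg)
        ri, rj, _ = gt.planted_fc_pairs[0]
        gt.planted_fc_pairs = [(ri, rj, 0.0)]
        ts = generate_timeseries(cfg, gt)
        labels = cfg.labels()
        i, j = labels.index(ri), labels.index(rj)
        z = np.array([conn.fisher_z(conn.compute_fc(t)).values[i, j] for t in ts])
        e = (gt.efrs_true - gt.efrs_true.mean()) / gt.efrs_true.std()
        assert abs(np.corrcoef(e, z)[0, 1]) < 0.1

    def test_invalid_coupling_rejected(self):
        cfg = SimulationConfig(**SMALL, seed=1)
        gt = make_ground_truth(cfg)
        ri, rj, _ = gt.planted_fc_pairs[0]
        gt.planted_fc_pairs = [(ri, rj, 1.0)]  # |r| >= 1
        with pytest.raises(ParameterError):
            generate_timeseries(cfg, gt)
        gt.planted_fc_pairs = [("NOPE.L", rj, 0.3)]
        with pytest.raises(ParameterError, match="atlas"):
            generate_timeseries(cfg, gt)


class TestMorphometry:
    def test_planted_shift_raises_z_at_planted_pair(self):
        cfg = SimulationConfig(n_subjects=60, n_reference_subjects=120,
                               n_regions=8, n_timepoints=10, n_variants=10,
                               seed=6, perturbed_fraction=1.0)
        gt = make_ground_truth(cfg)
        ri, rj, delta = gt.planted_idscn_pairs[0]
        ref, subj = generate_morphometry(cfg, gt)
        rc = conn.reference_pcc(ref)
        labels = list(ref.columns)
        i, j = labels.index(ri), labels.index(rj)
        z_planted, z_other = [], []
        for sid, row in subj.iterrows():
            z = conn.idscn(row, rc, ref).values
            z_planted.append(abs(z[i, j]))
            mask = ~np.eye(len(labels), dtype=bool)
            mask[i, j] = mask[j, i] = False
            z_other.append(np.abs(z[mask]).mean())
        assert np.mean(z_planted) > np.mean(z_other)
        assert gt.perturbed_subjects == list(subj.index)

    def test_reference_group_size_guard_and_bad_shift(self):
        with pytest.raises(ConfigurationError, match="30"):
            cfg = SimulationConfig(**{**SMALL, "n_reference_subjects": 10}, seed=1)
            generate_morphometry(cfg, make_ground_truth(cfg))
        cfg = SimulationConfig(**SMALL, seed=1)
        gt = make_ground_truth(cfg)
        ri, rj, _ = gt.planted_idscn_pairs[0]
        gt.planted_idscn_pairs = [(ri, rj, 2.5)]
        with pytest.raises(ParameterError, match="shift"):
            generate_morphometry(cfg, gt)


class TestPhenotypes:
    def test_noiseless_limit_exactly_linear(self):
        cfg = SimulationConfig(**SMALL, seed=9)
        gt = make_ground_truth(cfg)
        gt.noise_sds["sm"] = 0.0
        efrs = np.linspace(50.0, 300.0, cfg.n_subjects)  # keeps S-M off the clip
        phen = generate_phenotypes(cfg, gt, efrs, np.zeros(cfg.n_subjects))
        expected = gt.intercept_sm + gt.slope_sm_on_efrs * efrs
        np.testing.assert_allclose(phen["sm"], expected, atol=1e-12)

    def test_optimal_fraction_expectation(self):
        """With optimal fraction 1/3, about 30 of 90 fall below the threshold."""
        counts = []
        for seed in range(10):
            cfg = SimulationConfig(n_subjects=90, n_reference_subjects=30,
                                   n_regions=4, n_timepoints=10, n_variants=10,
                                   seed=seed)
            gt = make_ground_truth(cfg)
            phen = generate_phenotypes(cfg, gt, gt.efrs_true, np.zeros(90))
            counts.append(int((phen["ados_total_t2"] < 7).sum()))
        assert np.mean(counts) == pytest.approx(30.0, abs=5.0)

    def test_sm_range_and_oso_monotone(self):
        cfg = SimulationConfig(**SMALL, seed=10)
        gt = make_ground_truth(cfg)
        phen = generate_phenotypes(cfg, gt, gt.efrs_true,
                                   np.zeros(cfg.n_subjects))
        assert phen["sm"].between(5.0, 13.0).all()
        assert phen["oso"].between(0, 8).all()
        assert set(phen["oso_grade"]) <= {"good", "average", "poor"}

    def test_missing_inputs_rejected(self):
        cfg = SimulationConfig(**SMALL, seed=1)
        gt = make_ground_truth(cfg)
        with pytest.raises(InputError, match="all 20 subjects"):
            generate_phenotypes(cfg, gt, gt.efrs_true[:-1], np.zeros(20))
        bad = gt.efrs_true.copy()
        bad[0] = np.nan
        with pytest.raises(InputError, match="missing"):
            generate_phenotypes(cfg, gt, bad, np.zeros(20))


def test_mediation_triples_moments():
    x, m, y = simulate_mediation_triples(-0.47, -0.36, -0.10, 20_000, seed=0)
    assert np.corrcoef(x, m)[0, 1] == pytest.approx(-0.47, abs=0.02)
    assert m.std() == pytest.approx(1.0, abs=0.02)
    assert y.std() == pytest.approx(1.0, abs=0.02)
    with pytest.raises(ParameterError):
        simulate_mediation_triples(1.2, 0.0, 0.0, 10)


def test_nearest_correlation_repair():
    bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
    fixed = nearest_correlation(bad)
    w = np.linalg.eigvalsh(fixed)
    assert w.min() > 0
    assert np.allclose(np.diag(fixed), 1.0)
    good = np.array([[1.0, 0.3], [0.3, 1.0]])
    np.testing.assert_allclose(nearest_correlation(good), good, atol=1e-12)


def test_cohort_roundtrip_lossless(tmp_path):
    """Writers -> readers reproduce arrays and tables exactly."""
    cfg = SimulationConfig(**SMALL, seed=11)
    gt = make_ground_truth(cfg)
    vt = generate_variants(cfg)
    ts = generate_timeseries(cfg, gt)
    ref, subj = generate_morphometry(cfg, gt)
    phen = generate_phenotypes(cfg, gt, gt.efrs_true,
                               np.linspace(-0.3, 0.3, cfg.n_subjects))
    manifest = write_cohort(tmp_path, cfg, gt, vt, ts, ref, subj, phen)
    assert set(manifest["files"]) >= {
        "genotypes.vcf", "annotations.tsv", "phenotypes.tsv",
        "ground_truth.json", "morphometry_reference.csv",
    }

    gt_back = read_ground_truth(tmp_path / "ground_truth.json")
    np.testing.assert_array_equal(gt_back.efrs_true, gt.efrs_true)
    assert gt_back.planted_fc_pairs == gt.planted_fc_pairs
    assert gt_back.mediation_pair == gt.mediation_pair

    ts_back = conn.read_timeseries_csv(
        tmp_path / "timeseries" / f"{ts[0].subject}_ts.csv", ts[0].subject
    )
    np.testing.assert_array_equal(ts_back.values, ts[0].values)

    phen_back = pd.read_csv(tmp_path / "phenotypes.tsv", sep="\t",
                            index_col="subject", float_precision="round_trip")
    np.testing.assert_array_equal(phen_back["sm"].to_numpy(),
                                  phen["sm"].to_numpy())
    ref_back = pd.read_csv(tmp_path / "morphometry_reference.csv",
                           index_col="subject", float_precision="round_trip")
    np.testing.assert_array_equal(ref_back.to_numpy(), ref.to_numpy())
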