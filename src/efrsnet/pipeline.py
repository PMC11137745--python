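"""Pipeline orchestration: run any stage, or the full synthetic study.

Stages (in dependency order):

``simulate``
    Generate the synthetic cohort and write every artifact (VCF +
    annotations, per-subject time-series CSVs, morphometry tables,
    phenotype TSV, ground-truth JSON, manifest).
``efrs``
    Read the VCF + annotation TSV, filter rare variants against both
    panels, and compute the genotype-derived EFRS per subject.
``fc`` / ``idscn``
    Build per-subject connectivity matrices for each modality.
``svr``
    Vectorize FC into pair features and fit the linear SVR for the
    social-adaptability score, with LOOCV metrics, permutation p and
    selected pairs.
``regress``
    Simple OLS of S-M on the gene score, outcome grouping, a multivariate
    logistic model of the outcome group on the gene score plus the selected
    connectivity pairs, and baseline group comparisons.
``mediate``
    Gene score -> mediation-pair FC -> ADI-R communication path model with
    bootstrap CI.

Each stage reads only files written by its upstream stages, so deleting an
intermediate and re-running a downstream stage fails with an error naming
the missing file. ``run_all`` executes everything and aggregates one
deterministic ``results.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectivity as conn
from . import efrs as efrs_mod
from . import feature_models as fm
from . import outcome_stats as ost
from . import synthetic as syn

__all__ = ["PipelineConfig", "PipelineError", "run_stage", "run_all", "STAGES"]

log = logging.getLogger("efrsnet")


class PipelineError(RuntimeError):
    """A stage could not run (missing upstream output, bad config)."""


@dataclass
class PipelineConfig:
    """Declarative configuration for every stage; unknown keys are rejected."""

    out_dir: str = "efrsnet_out"
    seed: int = 0
    simulation: syn.SimulationConfig = field(default_factory=syn.SimulationConfig)
    weights: efrs_mod.WeightConfig = field(default_factory=efrs_mod.WeightConfig)
    svr_c: float = 1.0
    svr_epsilon: float = 0.1
    svr_n_perm: int = 100
    svr_outcome: str = "sm"
    mediation_n_boot: int = 5000
    ados_threshold: float = 7.0
    logistic_max_pairs: int = 5

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw or {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        sim_raw = dict(raw.pop("simulation", {}) or {})
        sim_known = {f.name for f in dataclasses.fields(syn.SimulationConfig)}
        bad = set(sim_raw) - sim_known
        if bad:
            raise PipelineError(f"unknown simulation keys: {sorted(bad)}")
        w_raw = dict(raw.pop("weights", {}) or {})
        w_known = {f.name for f in dataclasses.fields(efrs_mod.WeightConfig)}
        bad = set(w_raw) - w_known
        if bad:
            raise PipelineError(f"unknown weights keys: {sorted(bad)}")
        cfg = cls(**raw)
        if "seed" not in sim_raw:
            sim_raw["seed"] = cfg.seed
        for key in ("maf_rare_beta", "maf_common_range"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        cfg.simulation = syn.SimulationConfig(**sim_raw)
        cfg.weights = efrs_mod.WeightConfig(**w_raw)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    @property
    def out(self) -> Path:
        return Path(self.out_dir)


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"missing upstream output: {path} (run stage '{produced_by}' first)"
        )
    return path


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _round(x: float, digits: int = 10) -> float:
    return float(np.round(float(x), digits))


def _update_manifest(cfg: PipelineConfig, stage: str, paths: list[Path]) -> None:
    manifest_path = cfg.out / "pipeline_manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    )
    for p in paths:
        digest = hashlib.sha256(p.read_bytes()).hexdigest()
        manifest[str(p.relative_to(cfg.out))] = {"stage": stage, "sha256": digest}
    _dump_json(manifest, manifest_path)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig) -> dict:
    sim = cfg.simulation
    log.info("simulate: n=%d, regions=%d, seed=%d", sim.n_subjects,
             sim.n_regions, sim.seed)
    gt = syn.make_ground_truth(sim)
    variants = syn.generate_variants(sim)
    series = syn.generate_timeseries(sim, gt)
    ref_morph, subj_morph = syn.generate_morphometry(sim, gt)

    labels = sim.labels()
    i = labels.index(gt.mediation_pair[0])
    j = labels.index(gt.mediation_pair[1])
    fc_pair = np.array(
        [conn.fisher_z(conn.compute_fc(ts)).values[i, j] for ts in series]
    )
    phenotypes = syn.generate_phenotypes(sim, gt, gt.efrs_true, fc_pair)
    manifest = syn.write_cohort(cfg.out, sim, gt, variants, series,
                                ref_morph, subj_morph, phenotypes)
    return {"n_files": len(manifest["files"]),
            "n_variants": variants.n_variants,
            "n_subjects": sim.n_subjects}


def stage_efrs(cfg: PipelineConfig) -> dict:
    vcf = _require(cfg.out / "genotypes.vcf", "simulate")
    ann = _require(cfg.out / "annotations.tsv", "simulate")
    table = efrs_mod.read_variant_table(vcf, ann)
    rare = efrs_mod.filter_rare_variants(table, cfg.weights.maf_threshold)
    result = efrs_mod.compute_efrs(rare, cfg.weights)
    out_path = cfg.out / "efrs_genotype.tsv"
    result.scores.rename_axis("subject").to_csv(out_path, sep="\t",
                                                float_format="%.17g")
    summary = {
        "n_variants_input": table.n_variants,
        "n_variants_rare": rare.n_variants,
        "n_variants_used": result.n_variants_used,
        "n_dropped": result.n_dropped,
        "source": cfg.weights.source,
        "maf_threshold": cfg.weights.maf_threshold,
        "mean_score": _round(result.scores.mean()),
        "sd_score": _round(result.scores.std()),
    }
    _dump_json(summary, cfg.out / "efrs_summary.json")
    _update_manifest(cfg, "efrs", [out_path, cfg.out / "efrs_summary.json"])
    log.info("efrs: %d/%d variants rare, mean score %.3f",
             rare.n_variants, table.n_variants, result.scores.mean())
    return summary


def _load_timeseries(cfg: PipelineConfig) -> list[conn.ROITimeSeries]:
    ts_dir = _require(cfg.out / "timeseries", "simulate")
    paths = sorted(ts_dir.glob("*_ts.csv"))
    if not paths:
        raise PipelineError(f"missing upstream output: {ts_dir}/*_ts.csv "
                            "(run stage 'simulate' first)")
    return [conn.read_timeseries_csv(p, p.name.replace("_ts.csv", ""))
            for p in paths]


def stage_fc(cfg: PipelineConfig) -> dict:
    series = _load_timeseries(cfg)
    fc_dir = cfg.out / "fc"
    fc_dir.mkdir(exist_ok=True)
    written = []
    for ts in series:
        mat = conn.compute_fc(ts)
        path = fc_dir / f"{ts.subject}_fc.tsv"
        conn.write_matrix_tsv(mat, path)
        written.append(path)
    _update_manifest(cfg, "fc", written)
    log.info("fc: wrote %d matrices", len(written))
    return {"n_subjects": len(written), "n_regions": len(series[0].labels)}


def stage_idscn(cfg: PipelineConfig) -> dict:
    ref_path = _require(cfg.out / "morphometry_reference.csv", "simulate")
    subj_path = _require(cfg.out / "morphometry_subjects.csv", "simulate")
    reference = pd.read_csv(ref_path, index_col="subject")
    subjects = pd.read_csv(subj_path, index_col="subject")
    ref_cov = conn.reference_pcc(reference)
    out_dir = cfg.out / "idscn"
    out_dir.mkdir(exist_ok=True)
    written = []
    for subject, row in subjects.iterrows():
        mat = conn.idscn(row, ref_cov, reference)
        path = out_dir / f"{subject}_idscn.tsv"
        conn.write_matrix_tsv(mat, path)
        written.append(path)
    _update_manifest(cfg, "idscn", written)
    log.info("idscn: wrote %d matrices (reference n=%d)", len(written), ref_cov.n)
    return {"n_subjects": len(written), "reference_n": ref_cov.n}


def _load_fc_features(cfg: PipelineConfig) -> fm.FeatureMatrix:
    fc_dir = _require(cfg.out / "fc", "fc")
    paths = sorted(fc_dir.glob("*_fc.tsv"))
    if not paths:
        raise PipelineError(f"missing upstream output: {fc_dir}/*_fc.tsv "
                            "(run stage 'fc' first)")
    mats = [conn.read_matrix_tsv(p, "FC", p.name.replace("_fc.tsv", ""))
            for p in paths]
    return fm.build_feature_matrix(mats)


def stage_svr(cfg: PipelineConfig) -> dict:
    features = _load_fc_features(cfg)
    phen_path = _require(cfg.out / "phenotypes.tsv", "simulate")
    phen = pd.read_csv(phen_path, sep="\t", index_col="subject")
    outcome = phen.loc[features.subjects, cfg.svr_outcome]
    result = fm.fit_svr(
        features, outcome, c=cfg.svr_c, epsilon=cfg.svr_epsilon,
        n_perm=cfg.svr_n_perm, seed=cfg.seed,
    )
    pairs = pd.DataFrame(
        [
            {"region_i": p["pair"][0], "region_j": p["pair"][1],
             "weight": p["weight"], "direction": p["direction"]}
            for p in result.selected_pairs
        ],
        columns=["region_i", "region_j", "weight", "direction"],
    )
    pairs_path = cfg.out / "svr_selected_pairs.tsv"
    pairs.to_csv(pairs_path, sep="\t", index=False, float_format="%.17g")
    summary = {
        "outcome": cfg.svr_outcome,
        "modality": features.modality,
        "n_pairs_selected": len(result.selected_pairs),
        "prediction_slope": _round(result.slope),
        "prediction_intercept": _round(result.intercept),
        "r_squared": _round(result.r_squared),
        "mse": _round(result.mse),
        "permutation_p": _round(result.permutation_p)
        if result.permutation_p is not None else None,
        "hyperparameters": result.hyperparameters,
    }
    _dump_json(summary, cfg.out / "svr_results.json")
    _update_manifest(cfg, "svr", [pairs_path, cfg.out / "svr_results.json"])
    log.info("svr: R^2=%.3f, %d pairs selected", result.r_squared,
             len(result.selected_pairs))
    return summary


def stage_regress(cfg: PipelineConfig) -> dict:
    phen_path = _require(cfg.out / "phenotypes.tsv", "simulate")
    pairs_path = _require(cfg.out / "svr_selected_pairs.tsv", "svr")
    phen = pd.read_csv(phen_path, sep="\t", index_col="subject")

    linear = ost.simple_linear(phen["efrs"], phen["sm"])
    grouped = ost.group_outcomes(phen, threshold=cfg.ados_threshold)
    n_opt = int((grouped["outcome_group"] == ost.OPTIMAL).sum())
    n_grouped = int(grouped["outcome_group"].notna().sum())

    features = _load_fc_features(cfg)
    selected = pd.read_csv(pairs_path, sep="\t")
    design = pd.DataFrame(
        {"efrs": phen.loc[features.subjects, "efrs"].to_numpy()},
        index=features.subjects,
    )
    pair_index = {pair: k for k, pair in enumerate(features.pair_labels)}
    for _, row in selected.head(cfg.logistic_max_pairs).iterrows():
        pair = (row["region_i"], row["region_j"])
        key = pair if pair in pair_index else (pair[1], pair[0])
        design[f"fc_{key[0]}-{key[1]}"] = features.values[:, pair_index[key]]
    y = (grouped.loc[features.subjects, "outcome_group"] == ost.POOR).astype(int)
    logistic = ost.logistic_model(design, y)

    comparison = ost.compare_groups(
        grouped.loc[grouped["outcome_group"].notna()],
        {"age": "continuous", "iq": "continuous", "sm": "continuous",
         "ados_total_t1": "continuous", "sex": "categorical"},
    )
    comp_path = cfg.out / "group_comparison.tsv"
    comparison.to_csv(comp_path, sep="\t", float_format="%.17g")

    summary = {
        "sm_on_efrs": {
            "slope": _round(linear.slope),
            "intercept": _round(linear.intercept),
            "p": _round(linear.pvalues["x"]),
            "n": linear.n,
        },
        "outcome_grouping": {
            "threshold": cfg.ados_threshold,
            "n_grouped": n_grouped,
            "n_optimal": n_opt,
            "optimal_percent": _round(100.0 * n_opt / n_grouped, 4),
        },
        "logistic_outcome": {
            "terms": {
                str(term): {
                    "odds_ratio": _round(logistic.odds_ratios[term]),
                    "ci_low": _round(logistic.conf_int.loc[term, "low"]),
                    "ci_high": _round(logistic.conf_int.loc[term, "high"]),
                    "p_bonferroni": _round(logistic.pvalues_adjusted[term]),
                    "class": str(logistic.term_class[term]),
                }
                for term in logistic.params.index
            },
            "notes": logistic.notes,
        },
    }
    _dump_json(summary, cfg.out / "regress_results.json")
    _update_manifest(cfg, "regress",
                     [comp_path, cfg.out / "regress_results.json"])
    log.info("regress: slope=%.4f, optimal %.1f%%", linear.slope,
             100.0 * n_opt / max(n_grouped, 1))
    return summary


def stage_mediate(cfg: PipelineConfig) -> dict:
    phen_path = _require(cfg.out / "phenotypes.tsv", "simulate")
    gt_path = _require(cfg.out / "ground_truth.json", "simulate")
    fc_dir = _require(cfg.out / "fc", "fc")
    phen = pd.read_csv(phen_path, sep="\t", index_col="subject")
    gt = syn.read_ground_truth(gt_path)

    ri, rj = gt.mediation_pair
    m_values = []
    for subject in phen.index:
        path = _require(fc_dir / f"{subject}_fc.tsv", "fc")
        mat = conn.read_matrix_tsv(path, "FC", subject)
        i, j = mat.labels.index(ri), mat.labels.index(rj)
        m_values.append(conn.fisher_z(mat).values[i, j])

    result = ost.mediate(
        phen["efrs"].to_numpy(), np.array(m_values),
        phen["adir_comm"].to_numpy(),
        n_boot=cfg.mediation_n_boot, seed=cfg.seed,
    )
    summary = {
        "pair": [ri, rj],
        "a": _round(result.a), "b": _round(result.b),
        "c": _round(result.c), "c_prime": _round(result.c_prime),
        "indirect": _round(result.indirect),
        "ci": [_round(result.ci_low), _round(result.ci_high)],
        "significant": result.significant,
        "n": result.n, "n_boot": result.n_boot,
    }
    _dump_json(summary, cfg.out / "mediation_results.json")
    _update_manifest(cfg, "mediate", [cfg.out / "mediation_results.json"])
    log.info("mediate: a=%.3f b=%.3f indirect=%.3f", result.a, result.b,
             result.indirect)
    return summary


STAGES = {
    "simulate": stage_simulate,
    "efrs": stage_efrs,
    "fc": stage_fc,
    "idscn": stage_idscn,
    "svr": stage_svr,
    "regress": stage_regress,
    "mediate": stage_mediate,
}


def run_stage(name: str, cfg: PipelineConfig) -> dict:
    """Run one named stage; returns its summary dict."""
    if name not in STAGES:
        raise PipelineError(f"unknown stage {name!r}; choose from {sorted(STAGES)}")
    cfg.out.mkdir(parents=True, exist_ok=True)
    return STAGES[name](cfg)


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage in dependency order; write and return results.json."""
    results = {"seed": cfg.seed, "stages": {}}
    for name in ("simulate", "efrs", "fc", "idscn", "svr", "regress", "mediate"):
        results["stages"][name] = run_stage(name, cfg)
    _dump_json(results, cfg.out / "results.json")
    return results
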