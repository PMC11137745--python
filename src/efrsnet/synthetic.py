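"""Synthetic cohort generator with known ground truth.

The study design this package analyzes — a followed-up ASD cohort with
exome variants, resting-state ROI time series, regional morphometry and
two-time-point phenotypes — has no deposited public dataset, so every
downstream stage is exercised on a fully synthetic cohort whose generating
parameters are recorded as ground truth:

* **variants** — rare-skewed minor-allele-frequency spectrum over two
  reference panels (a Beta-distributed rare component plus a uniform common
  component, so a MAF < 0.01 filter removes a known expected fraction),
  five correlated damage annotations driven by one latent deleteriousness
  per variant, and binomial per-subject allele counts;
* **time series** — multivariate-normal BOLD-like series whose correlation
  at planted region pairs is coupled, on the Fisher-z scale, to the
  standardized latent gene score (EFRS), so the across-subject correlation
  between EFRS and measured connectivity recovers the planted coupling;
* **morphometry** — reference-group draws from a fixed covariance plus
  "perturbed" subjects drawn with planted pairwise covariance shifts, the
  signal the IDSCN construction is meant to detect;
* **phenotypes** — the social-adaptability standard score (S-M) linear in
  EFRS, the ADI-R communication score generated through the X -> M -> Y
  mediation chain with configured standardized paths, follow-up ADOS totals
  with a configured optimal-outcome fraction, and an ordinal overall social
  outcome (OSO) grade monotone in S-M.

Everything is deterministic under the configured seed; independent
generator streams are derived per operation so stages can be re-run in any
order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import load_atlas_labels
from .connectivity import ROITimeSeries, write_timeseries_csv
from .efrs import DAMAGE_SOURCES, VariantTable

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ConfigurationError",
    "ParameterError",
    "InputError",
    "make_ground_truth",
    "generate_variants",
    "generate_timeseries",
    "generate_morphometry",
    "generate_phenotypes",
    "simulate_mediation_triples",
    "nearest_correlation",
    "write_cohort",
    "read_ground_truth",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


class ParameterError(ValueError):
    """Ground-truth parameter outside its admissible range."""


class InputError(ValueError):
    """A generator was called with missing or inconsistent inputs."""


# Population-scale constants for the clinical instruments (cohort-typical
# means/SDs used to put generated phenotypes on their native scales).
_ADIR_COMM_LOC, _ADIR_COMM_SCALE = 13.38, 5.04
_ADOS_T2_OPTIMAL = (1.83, 2.07, 0.0, 6.0)    # mean, sd, clip range
_ADOS_T2_POOR = (14.78, 6.62, 7.0, 30.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort sizes, spectra and seeds for all generators.

    The defaults emulate the follow-up study design: 90 analysis subjects,
    a 104-subject reference cohort, the 90-region atlas, 240 fMRI time
    points, a rare-skewed MAF spectrum, a latent gene score on the
    EFRS ~ Normal(150, 50) scale truncated at 0, and one third of the
    cohort reaching the optimal outcome.
    """

    n_subjects: int = 90
    n_reference_subjects: int = 104
    n_regions: int = 90
    n_timepoints: int = 240
    n_variants: int = 2000
    # MAF spectrum: mixture of a rare Beta component and a common Uniform one
    maf_rare_fraction: float = 0.85
    maf_rare_beta: tuple[float, float] = (0.5, 300.0)
    maf_common_range: tuple[float, float] = (0.01, 0.3)
    maf_panel_jitter_sd: float = 0.05     # lognormal sd between the two panels
    annotation_noise_sd: float = 0.1      # noise around the shared deleteriousness
    target_set_fraction: float = 0.7
    efrs_mean: float = 150.0
    efrs_sd: float = 50.0
    fc_subject_sd: float = 0.3            # across-subject sd of true Fisher z
    optimal_fraction: float = 1.0 / 3.0
    ados_threshold: float = 7.0
    perturbed_fraction: float = 0.5       # morphometry subjects with planted shift
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_subjects": self.n_subjects,
            "n_reference_subjects": self.n_reference_subjects,
            "n_variants": self.n_variants,
        }
        for name, value in counts.items():
            if value < 1:
                raise ConfigurationError(f"{name} must be positive, got {value}")
        if self.n_regions < 2:
            raise ConfigurationError("n_regions must be >= 2")
        if self.n_timepoints < 3:
            raise ConfigurationError("n_timepoints must be >= 3")
        if not (0.0 <= self.maf_rare_fraction <= 1.0):
            raise ConfigurationError("maf_rare_fraction must lie in [0, 1]")
        if self.efrs_sd <= 0 or self.fc_subject_sd <= 0:
            raise ConfigurationError("scale parameters must be positive")
        if not (0.0 <= self.optimal_fraction <= 1.0):
            raise ConfigurationError("optimal_fraction must lie in [0, 1]")

    def labels(self) -> tuple[str, ...]:
        return load_atlas_labels()[: self.n_regions]

    def subject_ids(self) -> list[str]:
        return [f"sub{i:04d}" for i in range(1, self.n_subjects + 1)]

    def reference_ids(self) -> list[str]:
        return [f"ref{i:04d}" for i in range(1, self.n_reference_subjects + 1)]

    def maf_mass_below(self, threshold: float = 0.01) -> float:
        """Configured spectrum mass below ``threshold`` (no panel jitter)."""
        a, b = self.maf_rare_beta
        lo, hi = self.maf_common_range
        rare = stats.beta.cdf(threshold, a, b)
        common = np.clip((threshold - lo) / (hi - lo), 0.0, 1.0)
        return float(self.maf_rare_fraction * rare
                     + (1.0 - self.maf_rare_fraction) * common)


@dataclass
class GroundTruth:
    """Generating parameters recorded alongside every synthetic cohort."""

    subjects: list[str]
    efrs_true: np.ndarray
    planted_fc_pairs: list[tuple[str, str, float]]
    planted_idscn_pairs: list[tuple[str, str, float]]
    mediation_pair: tuple[str, str]
    slope_sm_on_efrs: float = -0.013
    intercept_sm: float = 9.29
    path_a: float = -0.47
    path_b: float = -0.36
    path_cprime: float = -0.10
    noise_sds: dict = field(default_factory=lambda: {"sm": 0.5, "oso": 0.8})
    perturbed_subjects: list[str] = field(default_factory=list)
    seed: int = 0

    def validate(self, labels: tuple[str, ...]) -> None:
        label_set = set(labels)
        for ri, rj, _ in list(self.planted_fc_pairs) + list(self.planted_idscn_pairs):
            if ri == rj:
                raise ParameterError(f"planted pair ({ri}, {rj}) is not distinct")
            if ri not in label_set or rj not in label_set:
                raise ParameterError(f"planted pair ({ri}, {rj}) outside the atlas")
        for name in ("path_a", "path_b", "path_cprime"):
            value = getattr(self, name)
            if not -1.0 <= value <= 1.0:
                raise ParameterError(f"standardized {name}={value} outside [-1, 1]")
        for _, _, beta in self.planted_fc_pairs:
            if not -1.0 < beta < 1.0:
                raise ParameterError(f"FC coupling {beta} would imply |r| >= 1")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def make_ground_truth(config: SimulationConfig) -> GroundTruth:
    """Draw the latent gene score and assemble default planted effects.

    The gene score is EFRS ~ Normal(efrs_mean, efrs_sd) truncated at 0. The
    default planted FC pair is (MOG.L, PAL.L) with coupling equal to the
    mediation path a; on reduced atlases the first two / last two regions
    stand in so small test configurations stay valid.
    """
    labels = config.labels()
    rng = _rng(config, 1)
    a, b = -config.efrs_mean / config.efrs_sd, np.inf
    efrs = stats.truncnorm.rvs(
        a, b, loc=config.efrs_mean, scale=config.efrs_sd,
        size=config.n_subjects, random_state=rng,
    )
    if "MOG.L" in labels and "PAL.L" in labels:
        fc_pair = ("MOG.L", "PAL.L")
    else:
        fc_pair = (labels[0], labels[1])
    if "THA.L" in labels and "THA.R" in labels:
        idscn_pair = ("THA.L", "THA.R")
    else:
        idscn_pair = (labels[-2], labels[-1])
    gt = GroundTruth(
        subjects=config.subject_ids(),
        efrs_true=efrs,
        planted_fc_pairs=[(fc_pair[0], fc_pair[1], -0.47)],
        planted_idscn_pairs=[(idscn_pair[0], idscn_pair[1], 0.4)],
        mediation_pair=fc_pair,
        seed=config.seed,
    )
    gt.validate(labels)
    return gt


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

def generate_variants(config: SimulationConfig) -> VariantTable:
    """Rare-variant table: MAF spectrum, correlated annotations, genotypes.

    One true frequency per variant is drawn from the configured
    Beta/Uniform mixture; each panel observes it under small multiplicative
    lognormal jitter. The five damage scores share a latent deleteriousness
    d ~ Uniform(0, 1) perturbed by independent Gaussian noise, mapped onto
    each source's native scale (so sources correlate but disagree). Allele
    counts are Binomial(2, mean panel MAF) per subject.
    """
    rng = _rng(config, 2)
    n = config.n_variants
    a, b = config.maf_rare_beta
    lo, hi = config.maf_common_range
    is_rare = rng.random(n) < config.maf_rare_fraction
    f_true = np.where(is_rare, rng.beta(a, b, size=n), rng.uniform(lo, hi, size=n))
    jitter = config.maf_panel_jitter_sd
    maf1 = np.clip(f_true * np.exp(rng.normal(0.0, jitter, n)), 0.0, 0.5)
    maf2 = np.clip(f_true * np.exp(rng.normal(0.0, jitter, n)), 0.0, 0.5)

    d = rng.random(n)
    noise = {src: rng.normal(0.0, config.annotation_noise_sd, n)
             for src in DAMAGE_SOURCES}
    scores = {
        "SIFT": np.clip(1.0 - d + noise["SIFT"], 0.0, 1.0),
        "LRT": np.clip(1.0 - d + noise["LRT"], 0.0, 1.0),
        "PolyPhen2": np.clip(d + noise["PolyPhen2"], 0.0, 1.0),
        "CADD": np.clip(40.0 * (d + noise["CADD"]), 0.0, 99.0),
        "MutationAssessor": np.clip(5.0 * (d + noise["MutationAssessor"]), -6.0, 6.0),
    }

    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, n)
    alt_idx = (ref_idx + rng.integers(1, 4, n)) % 4
    chroms = [f"chr{1 + i % 22}" for i in range(n)]
    pos = 10_000 + 37 * np.arange(n)  # unique within each chromosome stride

    variants = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "ref": bases[ref_idx],
            "alt": bases[alt_idx],
            "maf_panel1": maf1,
            "maf_panel2": maf2,
            **scores,
            "in_target_set": rng.random(n) < config.target_set_fraction,
        }
    )
    p = np.clip((maf1 + maf2) / 2.0, 0.0, 0.5)
    counts = rng.binomial(2, p[:, None], size=(n, config.n_subjects))
    genotypes = pd.DataFrame(counts.astype(np.int8), columns=config.subject_ids())
    return VariantTable(variants, genotypes)


# ---------------------------------------------------------------------------
# Time series
# ---------------------------------------------------------------------------

def nearest_correlation(matrix: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Nearest-positive-definite repair by eigenvalue clipping at ``eps``,
    followed by rescaling to unit diagonal. Deterministic and idempotent on
    already-valid correlation matrices (up to the clip)."""
    sym = (matrix + matrix.T) / 2.0
    w, v = np.linalg.eigh(sym)
    if w.min() < eps:
        w = np.clip(w, eps, None)
        sym = (v * w) @ v.T
    d = np.sqrt(np.diag(sym))
    sym = sym / np.outer(d, d)
    np.fill_diagonal(sym, 1.0)
    return (sym + sym.T) / 2.0


def _base_correlation(rng: np.random.Generator, n_regions: int,
                      loading_range: float) -> np.ndarray:
    """Single-factor background correlation: R = uu' off-diagonal, unit diag.

    With |u| < 1 this is positive definite by construction."""
    u = rng.uniform(-loading_range, loading_range, n_regions)
    base = np.outer(u, u)
    np.fill_diagonal(base, 1.0)
    return base


def generate_timeseries(
    config: SimulationConfig, ground_truth: GroundTruth
) -> list[ROITimeSeries]:
    """Per-subject region x time series with EFRS-coupled planted pairs.

    Each subject's series is multivariate normal. At a planted pair with
    coupling beta, the generating Fisher z is
    ``z0 + beta*s*e + sqrt(1-beta^2)*s*eta`` for standardized gene score e,
    subject noise eta and across-subject scale s, then back-transformed —
    so correlations stay inside (-1, 1) and the across-subject correlation
    between EFRS and the pair's Fisher-z FC equals beta (up to the
    finite-series measurement attenuation). Subject covariances are
    repaired to the nearest correlation matrix before sampling.
    """
    labels = config.labels()
    ground_truth.validate(labels)
    index = {lab: k for k, lab in enumerate(labels)}
    rng = _rng(config, 3)
    base = _base_correlation(rng, config.n_regions, 0.3)

    e = (ground_truth.efrs_true - ground_truth.efrs_true.mean())
    sd = ground_truth.efrs_true.std()
    e = e / sd if sd > 0 else np.zeros_like(e)
    s = config.fc_subject_sd

    pair_z = {}
    for ri, rj, beta in ground_truth.planted_fc_pairs:
        z0 = np.arctanh(base[index[ri], index[rj]])
        eta = rng.standard_normal(config.n_subjects)
        pair_z[(index[ri], index[rj])] = z0 + beta * s * e + np.sqrt(1 - beta**2) * s * eta

    out = []
    for k, subject in enumerate(config.subject_ids()):
        corr = base.copy()
        for (i, j), z in pair_z.items():
            corr[i, j] = corr[j, i] = np.tanh(z[k])
        corr = nearest_correlation(corr)
        chol = np.linalg.cholesky(corr)
        series = chol @ rng.standard_normal((config.n_regions, config.n_timepoints))
        out.append(ROITimeSeries(subject, labels, series))
    return out


# ---------------------------------------------------------------------------
# Morphometry
# ---------------------------------------------------------------------------

def generate_morphometry(
    config: SimulationConfig, ground_truth: GroundTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reference table plus per-subject regional morphometry vectors.

    Reference subjects are drawn from a fixed multivariate normal (volume-
    like regional means, single-factor covariance). A configured fraction of
    analysis subjects is drawn from the same distribution with the planted
    pairwise correlation shifts applied (nearest-correlation repaired); the
    remainder are unperturbed. ``ground_truth.perturbed_subjects`` records
    which subjects carry the shift. Returns (reference, subjects), both
    subjects x regions.
    """
    if config.n_reference_subjects < 30:
        raise ConfigurationError("morphometry requires n_reference_subjects >= 30")
    labels = config.labels()
    ground_truth.validate(labels)
    index = {lab: k for k, lab in enumerate(labels)}
    rng = _rng(config, 4)

    mu = rng.uniform(2.0, 8.0, config.n_regions)
    sd = rng.uniform(0.3, 0.7, config.n_regions)
    corr = _base_correlation(rng, config.n_regions, 0.4)

    shifted = corr.copy()
    for ri, rj, delta in ground_truth.planted_idscn_pairs:
        i, j = index[ri], index[rj]
        r_new = shifted[i, j] + delta
        if not -1.0 < r_new < 1.0:
            raise ParameterError(
                f"covariance shift {delta} at ({ri}, {rj}) leaves (-1, 1)"
            )
        shifted[i, j] = shifted[j, i] = r_new
    shifted = nearest_correlation(shifted)

    chol = np.linalg.cholesky(corr) * sd[None, :].T
    chol_shift = np.linalg.cholesky(shifted) * sd[None, :].T

    reference = mu + (chol @ rng.standard_normal(
        (config.n_regions, config.n_reference_subjects))).T
    n_pert = int(round(config.perturbed_fraction * config.n_subjects))
    perturbed_idx = rng.choice(config.n_subjects, size=n_pert, replace=False)
    is_pert = np.zeros(config.n_subjects, dtype=bool)
    is_pert[perturbed_idx] = True
    draws = np.empty((config.n_subjects, config.n_regions))
    for k in range(config.n_subjects):
        l_mat = chol_shift if is_pert[k] else chol
        draws[k] = mu + l_mat @ rng.standard_normal(config.n_regions)

    subjects = config.subject_ids()
    ground_truth.perturbed_subjects = [s for s, p in zip(subjects, is_pert) if p]
    ref_df = pd.DataFrame(reference, index=config.reference_ids(), columns=labels)
    subj_df = pd.DataFrame(draws, index=subjects, columns=labels)
    return ref_df, subj_df


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def generate_phenotypes(
    config: SimulationConfig,
    ground_truth: GroundTruth,
    efrs,
    fc,
) -> pd.DataFrame:
    """Clinical phenotype table generated from the stated linear models.

    * S-M standard score = intercept + slope * EFRS + Gaussian noise,
      clipped to the instrument range [5, 13];
    * ADI-R communication is generated through the mediation chain on
      standardized variables: Y = b * z(FC) + c' * z(EFRS) + residual, with
      the residual scaled so Y has (approximately) unit variance, then
      mapped to the instrument scale;
    * follow-up ADOS totals are drawn so that on average the configured
      fraction of subjects falls below the outcome threshold;
    * OSO is an ordinal 0-8 score monotone (decreasing) in S-M, plus a
      trichotomized grade (good / average / poor).

    ``efrs`` and ``fc`` must be complete per-subject vectors (the latent
    gene score and the mediation-pair Fisher-z connectivity).
    """
    n = config.n_subjects
    efrs = np.asarray(efrs, dtype=float).ravel()
    fc = np.asarray(fc, dtype=float).ravel()
    if len(efrs) != n or len(fc) != n:
        raise InputError(
            f"need EFRS and FC for all {n} subjects "
            f"(got {len(efrs)} and {len(fc)})"
        )
    if not (np.isfinite(efrs).all() and np.isfinite(fc).all()):
        raise InputError("EFRS/FC contain missing or non-finite values")

    gt = ground_truth
    rng = _rng(config, 5)
    sm_noise = gt.noise_sds.get("sm", 0.5)
    sm = gt.intercept_sm + gt.slope_sm_on_efrs * efrs + rng.normal(0.0, sm_noise, n) \
        if sm_noise > 0 else gt.intercept_sm + gt.slope_sm_on_efrs * efrs
    sm = np.clip(sm, 5.0, 13.0)

    def z(v: np.ndarray) -> np.ndarray:
        s = v.std()
        return (v - v.mean()) / s if s > 0 else np.zeros_like(v)

    a, b, cp = gt.path_a, gt.path_b, gt.path_cprime
    resid_sd = np.sqrt(max(1.0 - b**2 - cp**2 - 2.0 * a * b * cp, 0.05))
    y_std = b * z(fc) + cp * z(efrs) + resid_sd * rng.standard_normal(n)
    adir_comm = np.clip(_ADIR_COMM_LOC + _ADIR_COMM_SCALE * y_std, 0.0, None)

    optimal = rng.random(n) < config.optimal_fraction
    mean_o, sd_o, lo_o, hi_o = _ADOS_T2_OPTIMAL
    mean_p, sd_p, lo_p, hi_p = _ADOS_T2_POOR
    ados_t2 = np.where(
        optimal,
        np.clip(np.round(rng.normal(mean_o, sd_o, n)), lo_o, hi_o),
        np.clip(np.round(rng.normal(mean_p, sd_p, n)), lo_p, hi_p),
    )

    oso_noise = gt.noise_sds.get("oso", 0.8)
    oso = np.clip(np.round(13.0 - sm + rng.normal(0.0, oso_noise, n)), 0.0, 8.0)
    oso_grade = np.where(oso <= 2, "good", np.where(oso <= 5, "average", "poor"))

    frame = pd.DataFrame(
        {
            "efrs": efrs,
            "fc_mediator": fc,
            "sm": sm,
            "adir_comm": adir_comm,
            "adir_social": np.clip(rng.normal(16.91, 5.78, n), 0.0, None),
            "adir_rrb": np.clip(rng.normal(4.54, 2.71, n), 0.0, None),
            "adir_development": np.clip(rng.normal(2.56, 1.67, n), 0.0, None),
            "ados_total_t1": np.clip(np.round(rng.normal(18.23, 5.31, n)), 7.0, 40.0),
            "ados_total_t2": ados_t2,
            "oso": oso,
            "oso_grade": oso_grade,
            "iq": np.clip(np.round(rng.normal(85.5, 20.8, n)), 70.0, 145.0),
            "age": np.clip(np.round(rng.normal(8.01, 3.25, n), 1), 2.0, 18.0),
            "sex": np.where(rng.random(n) < 92.0 / 104.0, "M", "F"),
        },
        index=pd.Index(config.subject_ids(), name="subject"),
    )
    frame["adir_total"] = (
        frame["adir_comm"] + frame["adir_social"]
        + frame["adir_rrb"] + frame["adir_development"]
    )
    return frame


def simulate_mediation_triples(
    a: float, b: float, c_prime: float, n: int,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardized (X, M, Y) from the linear mediation model.

    M = a X + sqrt(1 - a^2) e1 and Y = c' X + b M + residual, residuals
    scaled so all three variables have unit variance. Used for mediation
    parameter-recovery experiments.
    """
    for name, value in (("a", a), ("b", b), ("c_prime", c_prime)):
        if not -1.0 <= value <= 1.0:
            raise ParameterError(f"standardized path {name}={value} outside [-1, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = rng.standard_normal(n)
    m = a * x + np.sqrt(1.0 - a**2) * rng.standard_normal(n)
    resid_var = max(1.0 - b**2 - c_prime**2 - 2.0 * a * b * c_prime, 0.0)
    y = c_prime * x + b * m + np.sqrt(resid_var) * rng.standard_normal(n)
    return x, m, y


# ---------------------------------------------------------------------------
# Writers / readers
# ---------------------------------------------------------------------------

def _write_vcf(table: VariantTable, path: Path) -> None:
    """Plain-text VCF v4.2 with GT genotypes, 1-based positions."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    subjects = table.subjects
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=efrsnet synthetic cohort\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(table.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(subjects) + "\n")
        gt = table.genotypes.to_numpy()
        for row, counts in zip(table.variants.itertuples(index=False), gt):
            calls = "\t".join(gt_map[int(c)] for c in counts)
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{calls}\n")


def _write_annotations(table: VariantTable, path: Path) -> None:
    cols = ["chrom", "pos", "ref", "alt", "maf_panel1", "maf_panel2",
            *DAMAGE_SOURCES, "in_target_set"]
    table.variants[cols].to_csv(path, sep="\t", index=False, float_format="%.8g")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def ground_truth_to_dict(gt: GroundTruth) -> dict:
    out = dataclasses.asdict(gt)
    out["efrs_true"] = [float(v) for v in gt.efrs_true]
    out["planted_fc_pairs"] = [list(p) for p in gt.planted_fc_pairs]
    out["planted_idscn_pairs"] = [list(p) for p in gt.planted_idscn_pairs]
    out["mediation_pair"] = list(gt.mediation_pair)
    return out


def read_ground_truth(path) -> GroundTruth:
    raw = json.loads(Path(path).read_text())
    raw["efrs_true"] = np.asarray(raw["efrs_true"], dtype=float)
    raw["planted_fc_pairs"] = [tuple(p) for p in raw["planted_fc_pairs"]]
    raw["planted_idscn_pairs"] = [tuple(p) for p in raw["planted_idscn_pairs"]]
    raw["mediation_pair"] = tuple(raw["mediation_pair"])
    return GroundTruth(**raw)


def write_cohort(
    out_dir,
    config: SimulationConfig,
    ground_truth: GroundTruth,
    variants: VariantTable,
    timeseries: list[ROITimeSeries],
    reference_morphometry: pd.DataFrame,
    subject_morphometry: pd.DataFrame,
    phenotypes: pd.DataFrame,
) -> dict:
    """Write every cohort artifact and a manifest of paths + checksums.

    Layout: ``genotypes.vcf`` + ``annotations.tsv``, one region x time CSV
    per subject under ``timeseries/``, reference and subject morphometry
    CSVs, the phenotype TSV, ``ground_truth.json`` and ``manifest.json``.
    """
    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)

    _write_vcf(variants, out / "genotypes.vcf")
    _write_annotations(variants, out / "annotations.tsv")
    for ts in timeseries:
        write_timeseries_csv(ts, out / "timeseries" / f"{ts.subject}_ts.csv")
    reference_morphometry.to_csv(out / "morphometry_reference.csv",
                                 index_label="subject", float_format="%.17g")
    subject_morphometry.to_csv(out / "morphometry_subjects.csv",
                               index_label="subject", float_format="%.17g")
    phenotypes.to_csv(out / "phenotypes.tsv", sep="\t", float_format="%.17g")
    (out / "ground_truth.json").write_text(
        json.dumps(ground_truth_to_dict(ground_truth), indent=2, sort_keys=True)
    )

    files = sorted(
        str(p.relative_to(out))
        for p in out.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config": dataclasses.asdict(config),
        "files": {f: _sha256(out / f) for f in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
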