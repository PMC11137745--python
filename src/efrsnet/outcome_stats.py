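"""Outcome grouping, regression, group comparison and mediation.

This layer links the gene score, connectivity features and clinical
outcomes:

* outcome grouping — children whose follow-up ADOS total falls below the
  diagnostic threshold (default 7) are labelled ``ASD-`` (optimal outcome,
  diagnosis lost); at or above it, ``ASD+`` (diagnosis persistent);
* simple OLS of a continuous outcome (e.g. the S-M social-adaptability
  standard score) on the gene score;
* multivariate logistic models with Wald odds ratios, 95% CIs and
  Bonferroni-corrected p-values, terms classified risk (OR > 1) or
  protective (OR < 1);
* baseline group comparisons (t tests for continuous variables, chi-square
  for categorical);
* the gene-brain-behavior mediation model: standardized paths
  a (X -> M), b (M -> Y | X), c' (X -> Y | M), total effect c, and the
  indirect effect a*b with a seeded percentile-bootstrap CI. For linear
  models on complete data the decomposition c = c' + a*b holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "RegressionResult",
    "MediationResult",
    "group_outcomes",
    "simple_linear",
    "logistic_model",
    "compare_groups",
    "mediate",
]

OPTIMAL, POOR = "ASD-", "ASD+"


class DegenerateInputError(ValueError):
    """Zero-variance input where variation is required."""


@dataclass
class RegressionResult:
    """Unified container for linear and logistic fits."""

    family: str                               # "linear" or "logistic"
    params: pd.Series                         # term -> coefficient
    pvalues: pd.Series
    pvalues_adjusted: pd.Series | None = None # Bonferroni over model terms
    odds_ratios: pd.Series | None = None      # logistic only, exp(beta)
    conf_int: pd.DataFrame | None = None      # OR scale, columns low/high
    term_class: pd.Series | None = None       # "risk" / "protective" / "unstable"
    intercept: float = float("nan")
    slope: float = float("nan")               # convenience for simple OLS
    n: int = 0
    notes: list[str] = field(default_factory=list)


@dataclass
class MediationResult:
    """Standardized three-variable path model with bootstrap inference."""

    a: float            # X -> M
    b: float            # M -> Y given X
    c: float            # total effect X -> Y
    c_prime: float      # direct effect X -> Y given M
    indirect: float     # a * b
    ci_low: float
    ci_high: float
    significant: bool   # bootstrap CI excludes 0
    n: int
    n_boot: int
    seed: int | None


def group_outcomes(
    phenotypes: pd.DataFrame,
    threshold: float = 7.0,
    ados_column: str = "ados_total_t2",
) -> pd.DataFrame:
    """Label follow-up outcome groups from the time-2 ADOS total.

    Totals strictly below ``threshold`` are the optimal-outcome group
    (``ASD-``); totals at or above it the poor-outcome group (``ASD+``).
    Subjects missing the time-2 total are flagged lost to follow-up and get
    no group label.
    """
    if ados_column not in phenotypes.columns:
        raise KeyError(f"phenotype table lacks column {ados_column!r}")
    out = phenotypes.copy()
    total = out[ados_column].astype(float)
    group = pd.Series(pd.NA, index=out.index, dtype="object")
    group[total < threshold] = OPTIMAL
    group[total >= threshold] = POOR
    out["outcome_group"] = group
    out["lost_to_follow_up"] = total.isna()
    return out


def simple_linear(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with a two-sided slope t test."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need matched x/y with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in regression input")
    if np.ptp(x) == 0.0:
        raise DegenerateInputError("x has zero variance")
    fit = stats.linregress(x, y)
    params = pd.Series({"intercept": fit.intercept, "x": fit.slope})
    pvalues = pd.Series({"intercept": np.nan, "x": fit.pvalue})
    return RegressionResult(
        family="linear", params=params, pvalues=pvalues,
        intercept=float(fit.intercept), slope=float(fit.slope), n=len(x),
    )


def logistic_model(
    features: pd.DataFrame,
    outcome,
    correction: str = "bonferroni",
    alpha: float = 0.05,
) -> RegressionResult:
    """Maximum-likelihood logistic regression with ORs and Bonferroni p.

    ``outcome`` is binary (0/1 or two labels); per-term OR = exp(beta) with
    Wald 95% CI exp(beta +/- 1.96 SE); adjusted p = min(1, m * p) over the m
    non-intercept terms. Terms with OR > 1 are classified ``risk``, OR < 1
    ``protective``. Perfect or quasi-perfect separation is flagged and the
    offending terms are reported ``unstable`` instead of being returned as
    if trustworthy.
    """
    x = features.astype(float)
    y = np.asarray(outcome)
    if y.dtype.kind not in "biufc":
        levels = pd.unique(pd.Series(y).dropna())
        if len(levels) != 2:
            raise ValueError(f"outcome must be binary, found levels {levels!r}")
        y = (pd.Series(y) == levels[1]).to_numpy()
    y = y.astype(float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be coded 0/1")
    n, m = x.shape
    notes: list[str] = []
    if n < 10 * m:
        notes.append(f"n={n} < 10 x {m} features: estimates may be unstable")

    design = sm.add_constant(x, has_constant="add")
    try:
        fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", True))
    except Exception as exc:  # statsmodels raises on hard separation
        notes.append(f"fit failed: {exc}")
        fit, converged = None, False

    terms = list(x.columns)
    if fit is None:
        nan = pd.Series(np.nan, index=terms)
        return RegressionResult(
            family="logistic", params=nan, pvalues=nan,
            pvalues_adjusted=nan, odds_ratios=nan,
            term_class=pd.Series("unstable", index=terms), n=n, notes=notes,
        )

    params = fit.params[terms]
    se = fit.bse[terms]
    pvalues = fit.pvalues[terms]
    odds = np.exp(params)
    ci = pd.DataFrame(
        {"low": np.exp(params - 1.959963984540054 * se),
         "high": np.exp(params + 1.959963984540054 * se)},
        index=terms,
    )
    if correction == "bonferroni":
        adjusted = (pvalues * len(terms)).clip(upper=1.0)
    elif correction in (None, "none"):
        adjusted = pvalues.copy()
    else:
        raise ValueError(f"unknown correction {correction!r}")

    unstable = (se > 50.0) | se.isna()
    if not converged:
        unstable[:] = True
    term_class = pd.Series(
        np.where(unstable, "unstable",
                 np.where(odds > 1.0, "risk", "protective")),
        index=terms,
    )
    if unstable.any():
        notes.append(
            "unstable terms (separation or non-convergence): "
            + ", ".join(map(str, term_class[term_class == "unstable"].index))
        )
    return RegressionResult(
        family="logistic", params=params, pvalues=pvalues,
        pvalues_adjusted=adjusted, odds_ratios=odds, conf_int=ci,
        term_class=term_class, intercept=float(fit.params["const"]),
        n=n, notes=notes,
    )


def compare_groups(
    phenotypes: pd.DataFrame,
    variables: dict[str, str],
    group_column: str = "outcome_group",
    welch: bool = False,
) -> pd.DataFrame:
    """Two-group comparison table: t tests and chi-square.

    ``variables`` maps column name -> ``"continuous"`` (independent-sample t
    test, pooled variance by default, Welch with ``welch=True``) or
    ``"categorical"`` (Pearson chi-square on the contingency table, no
    continuity correction). Returns one row per variable with the statistic,
    its name and the p-value.
    """
    groups = phenotypes[group_column].dropna().unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {list(groups)}")
    g1 = phenotypes[phenotypes[group_column] == groups[0]]
    g2 = phenotypes[phenotypes[group_column] == groups[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 subjects")

    rows = []
    for var, kind in variables.items():
        if kind == "continuous":
            a = g1[var].dropna().to_numpy(dtype=float)
            b = g2[var].dropna().to_numpy(dtype=float)
            stat, p = stats.ttest_ind(a, b, equal_var=not welch)
            test = "welch_t" if welch else "pooled_t"
        elif kind == "categorical":
            table = pd.crosstab(phenotypes[group_column], phenotypes[var])
            if (table.to_numpy().sum(axis=0) == 0).any() or table.shape[1] < 2:
                stat, p, test = 0.0, 1.0, "chi2"
            else:
                stat, p, _, _ = stats.chi2_contingency(table, correction=False)
                test = "chi2"
        else:
            raise ValueError(f"unknown variable kind {kind!r} for {var!r}")
        rows.append({"variable": var, "test": test,
                     "statistic": float(stat), "p": float(p)})
    return pd.DataFrame(rows).set_index("variable")


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0.0:
        raise DegenerateInputError("zero-variance variable in mediation input")
    return (v - v.mean()) / sd


def _paths(x: np.ndarray, m: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Standardized OLS paths via closed-form correlations.

    a = r_xm; regressing standardized y on (m, x): b and c' from the
    two-predictor normal equations; c = r_xy. Exact OLS, cheap enough to sit
    inside a dense bootstrap loop.
    """
    x, m, y = _zscore(x), _zscore(m), _zscore(y)
    n = len(x)
    r_xm = float(x @ m) / (n - 1)
    r_xy = float(x @ y) / (n - 1)
    r_my = float(m @ y) / (n - 1)
    det = 1.0 - r_xm**2
    if det <= 0.0:
        raise DegenerateInputError("mediator collinear with x")
    b = (r_my - r_xy * r_xm) / det
    c_prime = (r_xy - r_my * r_xm) / det
    return r_xm, b, r_xy, c_prime


def mediate(
    x,
    m,
    y,
    n_boot: int = 5000,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> MediationResult:
    """Three-variable mediation with percentile-bootstrap indirect-effect CI.

    All variables are standardized, so paths are on the correlation scale:
    a from the OLS of m on x, b and c' from the OLS of y on (m, x), total
    effect c from the OLS of y on x, indirect effect = a*b. The bootstrap
    resamples complete (x, m, y) triples, re-standardizing within each
    resample; significance means the CI excludes 0.
    """
    x = np.asarray(x, dtype=float).ravel()
    m = np.asarray(m, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if not (len(x) == len(m) == len(y)):
        raise ValueError("x, m, y must be the same length")
    if len(x) < 20:
        raise ValueError("mediation requires n >= 20 complete triples")
    if not (np.isfinite(x).all() and np.isfinite(m).all() and np.isfinite(y).all()):
        raise ValueError("mediation input must be complete (no NaN/inf)")

    a, b, c, c_prime = _paths(x, m, y)
    indirect = a * b

    rng = np.random.default_rng(seed)
    n = len(x)
    boot = np.empty(n_boot)
    for k in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            ab, bb, _, _ = _paths(x[idx], m[idx], y[idx])
        except DegenerateInputError:
            boot[k] = np.nan
            continue
        boot[k] = ab * bb
    boot = boot[~np.isnan(boot)]
    tail = (1.0 - ci_level) / 2.0
    ci_low, ci_high = np.quantile(boot, [tail, 1.0 - tail])
    return MediationResult(
        a=a, b=b, c=c, c_prime=c_prime, indirect=indirect,
        ci_low=float(ci_low), ci_high=float(ci_high),
        significant=bool(ci_low > 0.0 or ci_high < 0.0),
        n=n, n_boot=n_boot, seed=seed,
    )
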