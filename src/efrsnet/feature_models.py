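"""SVR identification of outcome-predictive connectivity pairs.

Connectivity matrices are vectorized into subject x pair feature matrices
(FC entries Fisher-z transformed first) and a linear-kernel
epsilon-insensitive support vector regression is fit against a continuous
outcome. Model quality is judged on leave-one-out cross-validated
predictions: the out-of-fold predictions are regressed against the observed
outcome to give a prediction line (slope, intercept), R^2 and MSE, and a
label-permutation test supplies the model p-value. Signed feature weights
come from a final fit on all subjects; pairs with outlying |weight| are
reported as predictive, their sign giving the predicted direction.

Because the kernel is linear, the Gram matrix is precomputed once on
standardized features and reused across every cross-validation fold and
every permutation, which keeps desk-scale permutation tests cheap without
changing any estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .connectivity import ConnectivityMatrix, fisher_z

__all__ = [
    "FeatureMatrix",
    "SVRModelResult",
    "build_feature_matrix",
    "fit_svr",
    "select_pairs",
    "permutation_test",
]


@dataclass
class FeatureMatrix:
    """Subjects x connectivity-pair features with aligned pair labels."""

    values: np.ndarray                      # (n_subjects, n_pairs)
    pair_labels: list[tuple[str, str]]
    subjects: list[str]
    modality: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subjects), len(self.pair_labels)):
            raise ValueError("feature matrix shape inconsistent with labels")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing entries")


@dataclass
class SVRModelResult:
    """Fitted model summary: signed weights, selection, LOOCV fit quality."""

    weights: pd.Series                      # pair -> signed weight
    selected_pairs: list[dict]              # {"pair", "weight", "direction"}
    slope: float                            # observed ~ predicted line
    intercept: float
    r_squared: float
    mse: float
    permutation_p: float | None
    hyperparameters: dict = field(default_factory=dict)


def build_feature_matrix(matrices: list[ConnectivityMatrix]) -> FeatureMatrix:
    """Vectorize per-subject matrices: one column per pair (i < j, row-major).

    FC matrices are Fisher-z transformed first so across-subject statistics
    act on a variance-stabilized scale; FC_z and IDSCN matrices are taken
    as-is. All subjects must share modality and region labels.
    """
    if not matrices:
        raise ValueError("no connectivity matrices supplied")
    labels = matrices[0].labels
    modality = matrices[0].modality
    for m in matrices:
        if m.labels != labels:
            raise ValueError(f"region labels of subject {m.subject!r} do not match")
        if m.modality != modality:
            raise ValueError("mixed modalities in one feature matrix")
    if modality == "FC":
        matrices = [fisher_z(m) for m in matrices]
        modality = "FC_z"
    r = len(labels)
    iu, ju = np.triu_indices(r, k=1)
    rows = np.stack([m.values[iu, ju] for m in matrices])
    pairs = [(labels[i], labels[j]) for i, j in zip(iu, ju)]
    return FeatureMatrix(rows, pairs, [m.subject for m in matrices], modality)


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (x - mu) / sd


def _loocv_predictions(gram: np.ndarray, y: np.ndarray, c: float, epsilon: float) -> np.ndarray:
    n = len(y)
    preds = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        rest = idx[idx != i]
        model = SVR(kernel="precomputed", C=c, epsilon=epsilon)
        model.fit(gram[np.ix_(rest, rest)], y[rest])
        preds[i] = model.predict(gram[i, rest][None, :])[0]
    return preds


def _fit_quality(y: np.ndarray, preds: np.ndarray) -> tuple[float, float, float, float]:
    """Observed-vs-predicted line, squared correlation and MSE."""
    mse = float(np.mean((y - preds) ** 2))
    if np.ptp(preds) == 0.0:
        return 0.0, float(np.mean(y)), 0.0, mse
    slope, intercept = np.polyfit(preds, y, 1)
    r = np.corrcoef(preds, y)[0, 1]
    return float(slope), float(intercept), float(r**2), mse


def fit_svr(
    features: FeatureMatrix,
    outcome,
    c: float = 1.0,
    epsilon: float = 0.1,
    n_perm: int = 0,
    seed: int | None = None,
    standardize: bool = True,
) -> SVRModelResult:
    """Linear-kernel SVR with LOOCV evaluation and optional permutation p.

    Features are standardized (zero mean, unit variance per column) so
    weights are comparable across pairs. Weights come from a final fit on
    all subjects; ``n_perm`` > 0 adds a label-permutation p-value for the
    LOOCV R^2.
    """
    y = np.asarray(outcome, dtype=float).ravel()
    n = features.values.shape[0]
    if len(y) != n:
        raise ValueError(f"{len(y)} outcomes for {n} subjects")
    if n < 10:
        raise ValueError("need at least 10 subjects for cross-validated SVR")
    if not np.isfinite(y).all():
        raise ValueError("outcome contains non-finite values")
    if np.ptp(y) == 0.0:
        raise ValueError("constant outcome: regression is degenerate")

    x = _standardize(features.values) if standardize else features.values
    gram = x @ x.T

    preds = _loocv_predictions(gram, y, c, epsilon)
    slope, intercept, r2, mse = _fit_quality(y, preds)

    final = SVR(kernel="precomputed", C=c, epsilon=epsilon)
    final.fit(gram, y)
    w = x[final.support_].T @ final.dual_coef_.ravel()
    weights = pd.Series(w, index=pd.Index(features.pair_labels), name="weight")

    perm_p = None
    if n_perm:
        perm_p = _permutation_p(gram, y, r2, n_perm, seed, c, epsilon)

    result = SVRModelResult(
        weights=weights,
        selected_pairs=[],
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        mse=mse,
        permutation_p=perm_p,
        hyperparameters={"C": c, "epsilon": epsilon, "kernel": "linear",
                         "cv": "leave-one-out", "standardize": standardize,
                         "n_perm": n_perm, "seed": seed},
    )
    result.selected_pairs = select_pairs(result)
    return result


def select_pairs(result: SVRModelResult, n_sd: float = 2.0) -> list[dict]:
    """Pairs whose |weight| exceeds mean(|w|) + ``n_sd``·sd(|w|).

    The threshold is strict, so a flat weight profile selects nothing. The
    sign of the weight is reported as the predicted direction: positive
    weight means higher connectivity predicts a higher outcome value.
    """
    absw = result.weights.abs()
    cut = absw.mean() + n_sd * absw.std(ddof=0)
    chosen = result.weights[absw > cut].sort_values(key=np.abs, ascending=False)
    return [
        {"pair": pair, "weight": float(w),
         "direction": "positive" if w > 0 else "negative"}
        for pair, w in chosen.items()
    ]


def _permutation_p(
    gram: np.ndarray,
    y: np.ndarray,
    observed_r2: float,
    n_perm: int,
    seed: int | None,
    c: float,
    epsilon: float,
) -> float:
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        yp = rng.permutation(y)
        preds = _loocv_predictions(gram, yp, c, epsilon)
        _, _, r2p, _ = _fit_quality(yp, preds)
        if r2p >= observed_r2:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def permutation_test(
    features: FeatureMatrix,
    outcome,
    n_perm: int = 1000,
    seed: int | None = None,
    c: float = 1.0,
    epsilon: float = 0.1,
) -> float:
    """Label-permutation p-value for the LOOCV R^2 of the linear SVR.

    p = (1 + #{permuted R^2 >= observed}) / (n_perm + 1); the add-one rule
    keeps p strictly positive. Fewer than 100 permutations trigger a warning
    but are still computed.
    """
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} < 100 gives a coarse p-value grid",
            RuntimeWarning,
            stacklevel=2,
        )
    y = np.asarray(outcome, dtype=float).ravel()
    x = _standardize(features.values)
    gram = x @ x.T
    preds = _loocv_predictions(gram, y, c, epsilon)
    _, _, r2, _ = _fit_quality(y, preds)
    return _permutation_p(gram, y, r2, n_perm, seed, c, epsilon)
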