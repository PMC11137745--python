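"""Brain connectivity construction: functional connectivity and IDSCN.

Two modalities are supported on a shared 90-region atlas:

* **FC** — whole-brain functional connectivity: the Pearson correlation
  between every pair of regional BOLD time series, giving a symmetric
  region x region matrix with unit diagonal.

* **IDSCN** — the individual differential structural covariance network.
  A reference group defines a baseline inter-regional morphometric
  correlation matrix ``PCC_n``. For an index subject, every pairwise
  correlation is recomputed with that subject appended to the reference
  group (``PCC_{n+1}``) and the perturbation is Z-scored::

      Z(i, j) = (PCC_{n+1} - PCC_n) / ((1 - PCC_n**2) / (n - 1))

  Under the null (the subject drawn from the reference distribution) Z is
  approximately standard normal, so large |Z| flags subject-specific
  structural covariance change at that edge.

Preprocessing (motion correction, nuisance regression, segmentation) is
assumed done upstream: FC is computed on the supplied series as-is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ROITimeSeries",
    "ConnectivityMatrix",
    "ReferenceCovariance",
    "DegenerateInputError",
    "compute_fc",
    "fisher_z",
    "reference_pcc",
    "idscn",
    "read_timeseries_csv",
    "write_timeseries_csv",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "matrix_to_pairs",
]

_SYMMETRY_TOL = 1e-12


class DegenerateInputError(ValueError):
    """A zero-variance region (or similar degeneracy) makes the request ill-posed."""


@dataclass
class ROITimeSeries:
    """One subject's region x time BOLD matrix with atlas labels."""

    subject: str
    labels: tuple[str, ...]
    values: np.ndarray  # shape (n_regions, n_timepoints)

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.labels):
            raise ValueError(
                f"series shape {self.values.shape} inconsistent with "
                f"{len(self.labels)} labels"
            )


@dataclass
class ConnectivityMatrix:
    """Square symmetric connectivity for one subject.

    ``modality`` is ``"FC"`` (Pearson r, unit diagonal, off-diagonals in
    [-1, 1]), ``"FC_z"`` (Fisher z of FC, zero diagonal) or ``"IDSCN"``
    (Z scores, zero diagonal).
    """

    modality: str
    labels: tuple[str, ...]
    values: np.ndarray
    subject: str

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        r = len(self.labels)
        if self.values.shape != (r, r):
            raise ValueError(f"matrix shape {self.values.shape}, expected ({r}, {r})")
        if np.abs(self.values - self.values.T).max(initial=0.0) > _SYMMETRY_TOL:
            raise ValueError("matrix not symmetric to 1e-12")
        if self.modality == "FC":
            if not np.allclose(np.diag(self.values), 1.0, atol=_SYMMETRY_TOL):
                raise ValueError("FC diagonal must be exactly 1")
            off = self.values[~np.eye(r, dtype=bool)]
            if off.size and (np.abs(off) > 1.0 + 1e-12).any():
                raise ValueError("FC off-diagonals must lie in [-1, 1]")


@dataclass
class ReferenceCovariance:
    """Reference-group pairwise Pearson matrix PCC_n and its group size n."""

    labels: tuple[str, ...]
    pcc: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.pcc = np.asarray(self.pcc, dtype=float)
        if self.n < 3:
            raise ValueError("reference group must have n >= 3 subjects")
        if np.abs(self.pcc - self.pcc.T).max(initial=0.0) > _SYMMETRY_TOL:
            raise ValueError("PCC_n not symmetric")


def _check_no_constant_rows(values: np.ndarray, labels, what: str) -> None:
    spread = np.ptp(values, axis=1)
    flat = [labels[i] for i in np.nonzero(spread == 0.0)[0]]
    if flat:
        raise DegenerateInputError(f"constant {what} for region(s): {', '.join(flat)}")


def compute_fc(series: ROITimeSeries) -> ConnectivityMatrix:
    """Pearson-correlation functional connectivity for one subject."""
    if series.values.shape[1] < 3:
        raise ValueError("need at least 3 time points for FC")
    _check_no_constant_rows(series.values, series.labels, "time series")
    r = np.corrcoef(series.values)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix("FC", series.labels, np.clip(r, -1.0, 1.0),
                              series.subject)


def fisher_z(matrix: ConnectivityMatrix, clip: float = 1.0 - 1e-6) -> ConnectivityMatrix:
    """Variance-stabilize an FC matrix: z = atanh(r), zero diagonal.

    Off-diagonal |r| = 1 (collinear regions) is clipped to ``clip`` with a
    warning rather than propagating infinities.
    """
    if matrix.modality != "FC":
        raise ValueError(f"fisher_z expects an FC matrix, got {matrix.modality!r}")
    r = matrix.values.copy()
    np.fill_diagonal(r, 0.0)
    saturated = np.abs(r) >= 1.0
    if saturated.any():
        warnings.warn(
            f"{int(saturated.sum() // 2)} off-diagonal |r|=1 entries clipped "
            f"to {clip} before atanh",
            RuntimeWarning,
            stacklevel=2,
        )
        r = np.clip(r, -clip, clip)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix("FC_z", matrix.labels, z, matrix.subject)


def reference_pcc(reference_table: pd.DataFrame) -> ReferenceCovariance:
    """Pairwise Pearson correlation across reference subjects.

    ``reference_table`` is subjects x regions (one morphometric scalar per
    region, e.g. a gray-matter volume equivalent).
    """
    if reference_table.shape[0] < 3:
        raise ValueError("need at least 3 reference subjects")
    if reference_table.shape[1] < 2:
        raise ValueError("need at least 2 regions")
    values = reference_table.to_numpy(dtype=float)
    spread = np.ptp(values, axis=0)
    dead = [reference_table.columns[i] for i in np.nonzero(spread == 0.0)[0]]
    if dead:
        raise DegenerateInputError(
            f"zero-variance region(s) across reference: {', '.join(map(str, dead))}"
        )
    pcc = np.corrcoef(values, rowvar=False)
    pcc = (pcc + pcc.T) / 2.0
    np.fill_diagonal(pcc, 1.0)
    return ReferenceCovariance(tuple(reference_table.columns), pcc,
                               reference_table.shape[0])


def idscn(
    subject_vector: pd.Series,
    reference: ReferenceCovariance,
    reference_table: pd.DataFrame,
) -> ConnectivityMatrix:
    """Individual differential structural covariance network Z matrix.

    Appends the subject's regional vector to the reference group, recomputes
    every pairwise correlation, and Z-scores the perturbation against the
    approximate sampling variability (1 - PCC_n^2) / (n - 1) of a single
    added observation. Diagonal is 0.
    """
    if tuple(subject_vector.index) != reference.labels:
        raise ValueError("subject region labels do not match the reference labels")
    if tuple(reference_table.columns) != reference.labels:
        raise ValueError("reference table labels do not match the reference PCC")
    augmented = np.vstack(
        [reference_table.to_numpy(dtype=float),
         subject_vector.to_numpy(dtype=float)[None, :]]
    )
    spread = np.ptp(augmented, axis=0)
    dead = [reference.labels[i] for i in np.nonzero(spread == 0.0)[0]]
    if dead:
        raise DegenerateInputError(
            f"constant region(s) after appending subject: {', '.join(dead)}"
        )
    pcc_n1 = np.corrcoef(augmented, rowvar=False)
    pcc_n1 = (pcc_n1 + pcc_n1.T) / 2.0
    delta = pcc_n1 - reference.pcc
    denom = (1.0 - reference.pcc**2) / (reference.n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(denom > 0.0, delta / denom, 0.0)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return ConnectivityMatrix("IDSCN", reference.labels, z,
                              str(subject_vector.name or "subject"))


# ---------------------------------------------------------------------------
# I/O — CSV/TSV with a one-line label header
# ---------------------------------------------------------------------------

def write_timeseries_csv(series: ROITimeSeries, path) -> None:
    """Region x time CSV: a ``region`` label column followed by t0..t{T-1}."""
    df = pd.DataFrame(
        series.values,
        index=pd.Index(series.labels, name="region"),
        columns=[f"t{k}" for k in range(series.values.shape[1])],
    )
    df.to_csv(path, float_format="%.17g")


def read_timeseries_csv(path, subject: str | None = None) -> ROITimeSeries:
    df = pd.read_csv(path, index_col="region", float_precision="round_trip")
    name = subject if subject is not None else str(path)
    return ROITimeSeries(name, tuple(df.index), df.to_numpy(dtype=float))


def write_matrix_tsv(matrix: ConnectivityMatrix, path) -> None:
    """Labelled square matrix as TSV (row index + header = region labels)."""
    pd.DataFrame(matrix.values, index=matrix.labels, columns=matrix.labels).to_csv(
        path, sep="\t", float_format="%.17g", index_label="region"
    )


def read_matrix_tsv(path, modality: str, subject: str = "") -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col="region",
                     float_precision="round_trip")
    values = df.to_numpy(dtype=float)
    values = (values + values.T) / 2.0  # undo float-format rounding asymmetry
    if modality == "FC":
        np.fill_diagonal(values, 1.0)
    return ConnectivityMatrix(modality, tuple(df.index), values, subject)


def matrix_to_pairs(matrix: ConnectivityMatrix) -> pd.DataFrame:
    """Flatten to a (region_i, region_j, value) table, upper triangle i < j."""
    r = len(matrix.labels)
    iu, ju = np.triu_indices(r, k=1)
    return pd.DataFrame(
        {
            "region_i": [matrix.labels[i] for i in iu],
            "region_j": [matrix.labels[j] for j in ju],
            "value": matrix.values[iu, ju],
        }
    )
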