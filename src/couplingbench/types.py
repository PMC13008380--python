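"""Core containers shared across the benchmarking pipeline.

Conventions
-----------
* Time series are stored frames x regions (row = one TR).
* Coupling matrices are regions x regions with the diagonal stored as NaN
  (a region's self-coupling is undefined for FC metrics; rDCM keeps its
  self-connections separately on the assembled A-matrix).
* Undirected edges are indexed by the row-major lower triangle with
  0-based region indices, i.e. (1,0), (2,0), (2,1), (3,0), ...
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical metric names, in the family order used for reporting
#: (Correlation -> Partial correlation -> Mutual information -> Coherence
#:  -> PID -> rDCM)
METRIC_ORDER = [
    "pearson",
    "spearman",
    "partial",
    "glasso",
    "mi_time",
    "mi_freq",
    "coh_spectral",
    "coh_wavelet",
    "redundancy",
    "synergy",
    "rdcm_full",
    "rdcm_in",
    "rdcm_out",
]

DIRECTED_METRICS = {"rdcm_full", "rdcm_in", "rdcm_out"}


@dataclass
class ParcellatedTimeSeries:
    """One subject's parcellated BOLD signal, frames x regions."""

    subject_id: str
    data: np.ndarray
    tr_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (frames x regions)")
        if self.data.shape[0] < 2 or self.data.shape[1] < 2:
            raise ValueError("need at least 2 frames and 2 regions")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass
class MotionTrace:
    """Six rigid-body realignment parameters, frames x 6.

    Columns are trans_x, trans_y, trans_z (mm) then rot_x, rot_y, rot_z
    (radians).
    """

    subject_id: str
    params: np.ndarray
    tr_s: float
    rotation_unit: str = "radians"

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion parameters must be frames x 6")
        if self.rotation_unit not in ("radians", "degrees"):
            raise ValueError("rotation_unit must be 'radians' or 'degrees'")

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]


@dataclass
class FDTrace:
    """Per-frame framewise displacement in mm; the first frame is 0."""

    subject_id: str
    fd_mm: np.ndarray

    def __post_init__(self) -> None:
        self.fd_mm = np.asarray(self.fd_mm, dtype=float)
        if np.any(self.fd_mm < 0):
            raise ValueError("FD must be nonnegative")

    @property
    def mean_fd(self) -> float:
        return float(np.mean(self.fd_mm))


@dataclass
class CouplingMatrix:
    """Regions x regions coupling estimate for one subject and one metric."""

    subject_id: str
    metric_name: str
    values: np.ndarray
    symmetric: bool = True
    fisher_z: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("coupling matrix must be square")
        if self.symmetric:
            off = ~np.eye(self.values.shape[0], dtype=bool)
            a, b = self.values[off], self.values.T[off]
            ok = np.isclose(a, b, atol=1e-12, equal_nan=True)
            if not np.all(ok | (np.isnan(a) & np.isnan(b))):
                raise ValueError("matrix flagged symmetric but is not")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


def undirected_edge_index(n_regions: int) -> list[tuple[int, int]]:
    """Row-major lower-triangle edge list: (1,0), (2,0), (2,1), ..."""
    return [(i, j) for i in range(n_regions) for j in range(i)]


def directed_edge_index(n_regions: int) -> list[tuple[int, int]]:
    """All ordered off-diagonal pairs (target, source), row-major."""
    return [(i, j) for i in range(n_regions) for j in range(n_regions) if i != j]


def n_undirected_edges(n_regions: int) -> int:
    return n_regions * (n_regions - 1) // 2


def n_directed_edges(n_regions: int) -> int:
    return n_regions * (n_regions - 1)


def vectorize_matrix(values: np.ndarray, directed: bool = False) -> np.ndarray:
    """Flatten a coupling matrix into its canonical edge vector."""
    n = values.shape[0]
    if directed:
        idx = directed_edge_index(n)
    else:
        idx = undirected_edge_index(n)
    rows = np.array([i for i, _ in idx])
    cols = np.array([j for _, j in idx])
    return values[rows, cols]


@dataclass
class CohortEdgeStack:
    """Subjects x edges matrix for one metric, with per-subject covariates.

    This is the unit consumed by harmonization, QC-FC and prediction.
    """

    metric_name: str
    subjects: list[str]
    edge_index: list[tuple]
    values: np.ndarray
    covariates: pd.DataFrame = field(default=None)  # site, age, sex, ...

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subjects), len(self.edge_index)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.edge_index)} edges"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("edge stack contains non-finite values")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_edges(self) -> int:
        return len(self.edge_index)


def stack_matrices(
    matrices: list[CouplingMatrix], covariates: pd.DataFrame | None = None
) -> CohortEdgeStack:
    """Assemble per-subject coupling matrices into a CohortEdgeStack."""
    if not matrices:
        raise ValueError("no matrices to stack")
    metric = matrices[0].metric_name
    n = matrices[0].n_regions
    directed = not matrices[0].symmetric
    idx = directed_edge_index(n) if directed else undirected_edge_index(n)
    rows = []
    for m in matrices:
        if m.metric_name != metric or m.n_regions != n:
            raise ValueError("mixed metrics or region counts in stack")
        rows.append(vectorize_matrix(m.values, directed=directed))
    return CohortEdgeStack(
        metric_name=metric,
        subjects=[m.subject_id for m in matrices],
        edge_index=idx,
        values=np.vstack(rows),
        covariates=covariates,
    )
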