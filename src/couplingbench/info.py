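"""Information-theoretic coupling estimators.

Time-domain mutual information from binned (Freedman-Diaconis) marginal and
joint distributions, in nats; and a partial-information decomposition of
lagged past/future states into redundancy (minimum marginal past-to-future
MI) and synergy, under a Gaussian (covariance-determinant) MI estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import CouplingMatrix, ParcellatedTimeSeries


@dataclass
class BinSpec:
    edges: np.ndarray
    n_bins: int
    width: float


def freedman_diaconis_bins(x: np.ndarray) -> BinSpec:
    """Freedman-Diaconis binning: width h = 2*IQR*n^(-1/3), count
    ceil(range/h), edges spanning [min, max].

    Falls back to the Sturges rule when the IQR is zero, and to a single
    bin for constant input.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 samples for binning")
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        return BinSpec(np.array([lo, lo]), 1, 0.0)
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    if iqr == 0:
        warnings.warn("zero IQR; falling back to the Sturges rule", stacklevel=2)
        n_bins = int(np.ceil(np.log2(n) + 1))
        h = (hi - lo) / n_bins
    else:
        h = 2.0 * iqr * n ** (-1.0 / 3.0)
        n_bins = int(np.ceil((hi - lo) / h))
    edges = np.linspace(lo, hi, n_bins + 1)
    return BinSpec(edges, n_bins, h)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def binned_mi(x: np.ndarray, y: np.ndarray) -> float:
    """MI(X, Y) = I(X) + I(Y) - I(X, Y) on the product FD binning, nats."""
    bx, by = freedman_diaconis_bins(x), freedman_diaconis_bins(y)
    if bx.n_bins == 1 or by.n_bins == 1:
        return 0.0
    joint, _, _ = np.histogram2d(x, y, bins=(bx.edges, by.edges))
    joint /= joint.sum()
    hx = _entropy(joint.sum(axis=1))
    hy = _entropy(joint.sum(axis=0))
    hxy = _entropy(joint.ravel())
    return hx + hy - hxy


def mi_time_fc(series: ParcellatedTimeSeries, normalized: bool = False) -> CouplingMatrix:
    """Pairwise binned mutual information (nats); symmetric.

    ``normalized=True`` divides each MI by the joint entropy (a normalized
    variant bounded by 1)."""
    if series.n_frames < 32:
        raise ValueError("need at least 32 frames for binned MI")
    n = series.n_regions
    data = series.data
    specs = [freedman_diaconis_bins(data[:, r]) for r in range(n)]
    vals = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i):
            bi, bj = specs[i], specs[j]
            if bi.n_bins == 1 or bj.n_bins == 1:
                vals[i, j] = vals[j, i] = 0.0
                continue
            joint, _, _ = np.histogram2d(
                data[:, i], data[:, j], bins=(bi.edges, bj.edges)
            )
            joint /= joint.sum()
            hxy = _entropy(joint.ravel())
            mi = _entropy(joint.sum(axis=1)) + _entropy(joint.sum(axis=0)) - hxy
            if normalized and hxy > 0:
                mi /= hxy
            vals[i, j] = vals[j, i] = mi
    return CouplingMatrix(series.subject_id, "mi_time", vals, symmetric=True)


# ---------------------------------------------------------------------------
# Gaussian PID on lagged states
# ---------------------------------------------------------------------------

def gaussian_mi(cov: np.ndarray, idx_a: list[int], idx_b: list[int]) -> float:
    """MI between two blocks of a joint Gaussian:
    I = 0.5 * log( det S_a * det S_b / det S_ab ), nats."""
    a = np.ix_(idx_a, idx_a)
    b = np.ix_(idx_b, idx_b)
    ab = idx_a + idx_b
    s_ab = cov[np.ix_(ab, ab)]
    _, ld_a = np.linalg.slogdet(cov[a])
    _, ld_b = np.linalg.slogdet(cov[b])
    _, ld_ab = np.linalg.slogdet(s_ab)
    return max(0.0, 0.5 * (ld_a + ld_b - ld_ab))


@dataclass
class PIDComponents:
    redundancy: float
    synergy: float
    joint_mi: float
    marginal_mi_x: float
    marginal_mi_y: float
    lag: int


def phiid_pair(
    x: np.ndarray, y: np.ndarray, lag: int = 1, ridge: float = 1e-8
) -> PIDComponents:
    """Redundancy and synergy for one pair from the 4x4 lagged covariance.

    Variables are (X_t, Y_t, X_{t+lag}, Y_{t+lag}); the target N is the
    joint future (X_{t+lag}, Y_{t+lag}). Redundancy is the minimum of the
    two marginal past-to-future MIs; synergy is the joint past-to-future MI
    minus the union information I(N;M_X) + I(N;M_Y) - R.
    """
    if len(x) <= lag + 8:
        raise ValueError("series too short for the requested lag")
    past = np.column_stack([x[:-lag], y[:-lag]])
    fut = np.column_stack([x[lag:], y[lag:]])
    z = np.hstack([past, fut])
    cov = np.cov(z, rowvar=False)
    if np.linalg.matrix_rank(cov) < 4 or np.linalg.cond(cov) > 1e12:
        warnings.warn("rank-deficient lagged covariance; ridge applied", stacklevel=2)
        cov = cov + ridge * np.trace(cov) / 4.0 * np.eye(4)
    n_idx = [2, 3]
    mi_x = gaussian_mi(cov, n_idx, [0])
    mi_y = gaussian_mi(cov, n_idx, [1])
    mi_joint = gaussian_mi(cov, n_idx, [0, 1])
    r = min(mi_x, mi_y)
    s = mi_joint - (mi_x + mi_y - r)
    return PIDComponents(r, s, mi_joint, mi_x, mi_y, lag)


def phiid_components_fc(
    series: ParcellatedTimeSeries, lag: int = 1
) -> tuple[CouplingMatrix, CouplingMatrix]:
    """Redundancy and synergy matrices for all pairs (Gaussian estimator)."""
    n = series.n_regions
    red = np.full((n, n), np.nan)
    syn = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i):
            comp = phiid_pair(series.data[:, i], series.data[:, j], lag)
            red[i, j] = red[j, i] = comp.redundancy
            syn[i, j] = syn[j, i] = comp.synergy
    return (
        CouplingMatrix(series.subject_id, "redundancy", red, symmetric=True),
        CouplingMatrix(series.subject_id, "synergy", syn, symmetric=True),
    )
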