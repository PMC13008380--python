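"""Correlation-family coupling estimators.

Pearson and Spearman correlation (with Fisher r-to-z), full partial
correlation via precision-matrix inversion, and L1-regularized partial
correlation via the graphical lasso with a two-stage subset-based
lambda-range selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.covariance import graphical_lasso

from .types import CouplingMatrix, ParcellatedTimeSeries

FISHER_CLIP = 1.0 - 1e-7


def _corr_matrix(data: np.ndarray) -> np.ndarray:
    """Correlation matrix with zero-variance columns mapped to NaN."""
    sd = data.std(axis=0)
    bad = sd == 0
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} zero-variance region(s); rows set to NaN",
            stacklevel=3,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data, rowvar=False)
    r[bad, :] = np.nan
    r[:, bad] = np.nan
    return r


def _finish(
    r: np.ndarray, subject_id: str, metric: str, fisher_z: bool
) -> CouplingMatrix:
    if fisher_z:
        r = np.arctanh(np.clip(r, -FISHER_CLIP, FISHER_CLIP))
    np.fill_diagonal(r, np.nan)
    r = (r + r.T) / 2.0  # enforce exact symmetry against round-off
    return CouplingMatrix(subject_id, metric, r, symmetric=True, fisher_z=fisher_z)


def pearson_fc(
    series: ParcellatedTimeSeries, fisher_z: bool = True
) -> CouplingMatrix:
    """Product-moment correlation between all region pairs."""
    r = _corr_matrix(series.data)
    return _finish(r, series.subject_id, "pearson", fisher_z)


def spearman_fc(
    series: ParcellatedTimeSeries, fisher_z: bool = True
) -> CouplingMatrix:
    """Rank correlation: Pearson on rank-transformed series (ties averaged)."""
    ranks = np.apply_along_axis(stats.rankdata, 0, series.data)
    r = _corr_matrix(ranks)
    return _finish(r, series.subject_id, "spearman", fisher_z)


def partial_corr_fc(
    series: ParcellatedTimeSeries, fisher_z: bool = False
) -> CouplingMatrix:
    """Full partial correlations controlling for all remaining regions.

    Computed from the inverse sample covariance (precision) P as
    -P_xy / sqrt(P_xx P_yy); for three regions this reduces to the
    single-control textbook formula. With two regions the conditioning set
    is empty and the partial equals the Pearson correlation.
    """
    t, n = series.data.shape
    if t <= n:
        warnings.warn(
            f"frames ({t}) <= regions ({n}): partial correlations ill-conditioned",
            stacklevel=2,
        )
    cov = np.cov(series.data, rowvar=False)
    try:
        prec = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        warnings.warn("singular covariance; using pseudo-inverse", stacklevel=2)
        prec = np.linalg.pinv(cov)
    d = np.sqrt(np.abs(np.diag(prec)))
    r = -prec / np.outer(d, d)
    return _finish(r, series.subject_id, "partial", fisher_z)


@dataclass
class GlassoFit:
    precision: np.ndarray
    lam: float
    nonzero_edge_count: int


def glasso_fc(
    series: ParcellatedTimeSeries,
    lam: float,
    fisher_z: bool = False,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    suppress_warnings: bool = False,
) -> tuple[GlassoFit, CouplingMatrix]:
    """Graphical-lasso regularized partial correlations.

    The series is standardized internally and the L1 penalty applies to
    off-diagonal precision entries only. ``lam = 0`` falls back to direct
    inversion of the sample correlation matrix (the unpenalized limit).
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    z = series.data - series.data.mean(axis=0)
    sd = z.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance region; cannot standardize for GLASSO")
    z /= sd
    emp = z.T @ z / z.shape[0]
    if lam == 0:
        prec = np.linalg.inv(emp)
    else:
        try:
            with warnings.catch_warnings():
                if suppress_warnings:
                    warnings.simplefilter("ignore")
                _, prec = graphical_lasso(emp, alpha=lam, tol=tol, max_iter=max_iter)
        except FloatingPointError as exc:  # non-convergence diagnostics
            raise RuntimeError(
                f"graphical lasso failed to converge (lambda={lam}): {exc}"
            ) from exc
    d = np.sqrt(np.diag(prec))
    r = -prec / np.outer(d, d)
    off = ~np.eye(prec.shape[0], dtype=bool)
    nonzero = int((np.abs(prec[off]) > 1e-10).sum() // 2)
    fit = GlassoFit(precision=prec, lam=lam, nonzero_edge_count=nonzero)
    return fit, _finish(r, series.subject_id, "glasso", fisher_z)


def _ebic(
    emp_corr: np.ndarray, prec: np.ndarray, n: int, gamma: float = 0.5
) -> float:
    """Extended BIC of a Gaussian graphical model fit."""
    p = prec.shape[0]
    sign, logdet = np.linalg.slogdet(prec)
    if sign <= 0:
        return np.inf
    loglik = 0.5 * n * (logdet - np.trace(emp_corr @ prec))
    off = ~np.eye(p, dtype=bool)
    k = int((np.abs(prec[off]) > 1e-10).sum() // 2)
    return -2.0 * loglik + k * np.log(n) + 4.0 * k * gamma * np.log(p)


def select_lambda(
    series_subset: list[ParcellatedTimeSeries],
    coarse_grid: np.ndarray | None = None,
    refine_factor: float = 3.0,
    n_refine: int = 10,
    gamma: float = 0.5,
) -> float:
    """Two-stage subset-based lambda selection.

    Stage 1 scores a wide logarithmic grid per subject by extended BIC
    (gamma = 0.5) and takes the median per-subject optimum; stage 2
    re-grids tightly around that median (within a ``refine_factor``
    multiplicative window) and returns the refined median. Deterministic
    given the subject subset.
    """
    if len(series_subset) < 2:
        raise ValueError("need at least 2 subjects for lambda selection")
    if coarse_grid is None:
        coarse_grid = np.logspace(-2, 0, 10)
    coarse_grid = np.asarray(coarse_grid, dtype=float)
    if coarse_grid.size == 0 or np.any(coarse_grid < 0):
        raise ValueError("degenerate lambda grid")
    if coarse_grid.size == 1:
        return float(coarse_grid[0])

    def _best_lambda(ts: ParcellatedTimeSeries, grid: np.ndarray) -> float:
        z = ts.data - ts.data.mean(axis=0)
        z /= z.std(axis=0)
        emp = z.T @ z / z.shape[0]
        scores = []
        for lam in grid:
            try:
                # a capped, looser solve is sufficient to score the eBIC
                fit, _ = glasso_fc(
                    ts, lam, tol=1e-4, max_iter=500, suppress_warnings=True
                )
                scores.append(_ebic(emp, fit.precision, ts.n_frames, gamma))
            except (RuntimeError, np.linalg.LinAlgError):
                scores.append(np.inf)
        return float(grid[int(np.argmin(scores))])

    stage1 = np.median([_best_lambda(ts, coarse_grid) for ts in series_subset])
    lo = max(stage1 / refine_factor, float(coarse_grid.min()))
    hi = min(stage1 * refine_factor, float(coarse_grid.max()))
    fine_grid = np.logspace(np.log10(lo), np.log10(hi), n_refine)
    stage2 = np.median([_best_lambda(ts, fine_grid) for ts in series_subset])
    return float(stage2)
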