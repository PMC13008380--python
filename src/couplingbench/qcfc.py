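"""Motion-sensitivity benchmarking.

Edgewise QC-FC correlations (across subjects, between mean framewise
displacement and edge strength), their distribution summaries, distance
dependence against interregional Euclidean centroid distance, sparsity
matching of dense stacks to graphical-lasso edge counts, and cross-metric
similarity of group-mean edge vectors with average-linkage ordering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .types import CohortEdgeStack

logger = logging.getLogger(__name__)


@dataclass
class QcfcResult:
    metric_name: str
    qcfc: np.ndarray  # per-edge correlation, NaN for degenerate edges
    mean: float  # mu over valid edges
    population_variance: float  # sigma^2 (divisor n_edges)
    correlation_type: str
    n_dropped: int


def qcfc_correlations(
    stack: CohortEdgeStack,
    mean_fd_per_subject: np.ndarray,
    correlation: str = "pearson",
) -> QcfcResult:
    """Per-edge correlation between edge strength and mean FD across
    subjects; summary mean and population variance over valid edges."""
    fd = np.asarray(mean_fd_per_subject, dtype=float)
    if len(fd) != stack.n_subjects:
        raise ValueError("FD vector must align with the stack's subjects")
    if stack.n_subjects < 10:
        raise ValueError("need at least 10 subjects for QC-FC")
    y = stack.values
    if correlation == "spearman":
        y = np.apply_along_axis(stats.rankdata, 0, y)
        fd = stats.rankdata(fd)
    yc = y - y.mean(axis=0)
    sd = yc.std(axis=0)
    fdc = fd - fd.mean()
    fsd = fdc.std()
    if fsd == 0:
        raise ValueError("mean FD has zero variance across subjects")
    bad = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (yc.T @ fdc) / (stack.n_subjects * sd * fsd)
    r[bad] = np.nan
    n_dropped = int(bad.sum())
    if n_dropped:
        logger.info("QC-FC: %d zero-variance edge(s) set to NaN", n_dropped)
    valid = r[~np.isnan(r)]
    return QcfcResult(
        metric_name=stack.metric_name,
        qcfc=r,
        mean=float(np.mean(valid)),
        population_variance=float(np.var(valid)),
        correlation_type=correlation,
        n_dropped=n_dropped,
    )


def edge_distances(
    centroids: np.ndarray, edge_index: list[tuple]
) -> np.ndarray:
    """Euclidean centroid distance per edge (directed edges allowed)."""
    c = np.asarray(centroids, dtype=float)
    out = np.empty(len(edge_index))
    for k, e in enumerate(edge_index):
        i, j = e[0], e[1]
        out[k] = np.linalg.norm(c[i] - c[j])
    return out


@dataclass
class DistanceDependence:
    metric_name: str
    distances: np.ndarray
    spearman_rho: float
    p_value: float


def distance_dependence(
    qcfc_result: QcfcResult,
    centroids: np.ndarray,
    edge_index: list[tuple],
) -> DistanceDependence:
    """Spearman correlation between QC-FC values and edge distances."""
    d = edge_distances(centroids, edge_index)
    mask = ~np.isnan(qcfc_result.qcfc)
    if not np.any(mask):
        raise ValueError("all QC-FC values are NaN")
    rho, p = stats.spearmanr(qcfc_result.qcfc[mask], d[mask])
    return DistanceDependence(qcfc_result.metric_name, d, float(rho), float(p))


def match_sparsity(
    stack: CohortEdgeStack, reference_counts: np.ndarray | int
) -> CohortEdgeStack:
    """Per subject, keep only the top-k edges by absolute weight.

    ``reference_counts`` is the per-subject number of edges retained by the
    graphical lasso (or a single k for all). Ties at the k-th weight are
    broken toward the lower edge index.
    """
    counts = np.broadcast_to(
        np.asarray(reference_counts, dtype=int), (stack.n_subjects,)
    )
    if np.any(counts > stack.n_edges) or np.any(counts < 0):
        raise ValueError("k must lie in [0, n_edges]")
    out = np.zeros_like(stack.values)
    for s in range(stack.n_subjects):
        k = counts[s]
        if k == 0:
            warnings.warn(
                f"k=0 for subject {stack.subjects[s]}: all edges zeroed",
                stacklevel=2,
            )
            continue
        row = stack.values[s]
        order = np.argsort(-np.abs(row), kind="stable")  # ties -> lower index
        keep = order[:k]
        out[s, keep] = row[keep]
    return CohortEdgeStack(
        stack.metric_name,
        list(stack.subjects),
        list(stack.edge_index),
        out,
        stack.covariates,
    )


@dataclass
class MetricSimilarity:
    metric_names: list[str]
    correlation: np.ndarray
    linkage: np.ndarray
    order: list[int]  # dendrogram leaf order


def metric_similarity(group_means: dict[str, np.ndarray]) -> MetricSimilarity:
    """Pairwise Pearson correlations among group-mean edge vectors with
    average-linkage ordering on distance 1 - r."""
    names = list(group_means)
    vecs = np.vstack([group_means[m] for m in names])
    r = np.corrcoef(vecs)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    if len(names) > 1:
        dist = squareform(np.clip(1.0 - r, 0.0, None), checks=False)
        link = hierarchy.linkage(dist, method="average")
        order = hierarchy.leaves_list(link).tolist()
    else:
        link = np.empty((0, 4))
        order = [0]
    return MetricSimilarity(names, r, link, order)


def directed_to_undirected(
    stack: CohortEdgeStack,
) -> CohortEdgeStack:
    """Average the two directions of a directed stack onto undirected edges
    (used for cross-metric comparison against symmetric FC)."""
    pair_map: dict[tuple[int, int], list[int]] = {}
    for k, e in enumerate(stack.edge_index):
        i, j = e[0], e[1]
        key = (max(i, j), min(i, j))
        pair_map.setdefault(key, []).append(k)
    und_idx = sorted(pair_map)
    und_idx.sort(key=lambda t: (t[0], t[1]))
    vals = np.column_stack(
        [stack.values[:, cols].mean(axis=1) for cols in (pair_map[e] for e in und_idx)]
    )
    return CohortEdgeStack(
        stack.metric_name, list(stack.subjects), und_idx, vals, stack.covariates
    )
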