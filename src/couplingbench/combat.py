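"""Parametric empirical-Bayes ComBat harmonization of edge features.

Removes per-site additive (location) and multiplicative (scale) effects
from a subjects x edges matrix while preserving covariate (age, sex)
effects. Site effects are shrunk toward their across-edge priors
(normal prior on the location, inverse-gamma on the scale) with the
standard iterative moment-matching ("it.sol") conditional posterior-mean
solution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import CohortEdgeStack


@dataclass
class CombatModel:
    sites: list[str]
    grand_mean: np.ndarray  # per edge
    beta: np.ndarray  # covariates x edges
    gamma_star: np.ndarray  # sites x edges, EB-shrunk location
    delta_sq_star: np.ndarray  # sites x edges, EB-shrunk scale
    pooled_var: np.ndarray  # per edge
    hyper: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "sites": self.sites,
                "grand_mean": self.grand_mean.tolist(),
                "beta": self.beta.tolist(),
                "gamma_star": self.gamma_star.tolist(),
                "delta_sq_star": self.delta_sq_star.tolist(),
                "pooled_var": self.pooled_var.tolist(),
                "hyper": {k: np.asarray(v).tolist() for k, v in self.hyper.items()},
            }
        )


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = np.mean(delta_hat), np.var(delta_hat)
    return (2 * s2 + m**2) / s2 if s2 > 0 else 100.0


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = np.mean(delta_hat), np.var(delta_hat)
    return (m * s2 + m**3) / s2 if s2 > 0 else 1.0


def _it_sol(
    z_site: np.ndarray,
    g_hat: np.ndarray,
    d_hat: np.ndarray,
    g_bar: float,
    t2: float,
    a: float,
    b: float,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative conditional posterior means for one site's (gamma, delta^2)."""
    n = z_site.shape[0]
    g_new, d_new = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_old, d_old = g_new.copy(), d_new.copy()
        g_new = (n * t2 * g_hat + d_new * g_bar) / (n * t2 + d_new)
        ss = np.sum((z_site - g_new[None, :]) ** 2, axis=0)
        d_new = (0.5 * ss + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        if change < tol:
            break
    return g_new, d_new


def combat_fit_transform(
    stack: CohortEdgeStack,
    site_labels: np.ndarray | None = None,
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> tuple[CohortEdgeStack, CombatModel]:
    """Harmonize a subjects x edges stack across sites.

    ``covariates`` defaults to [age (centered), sex (indicator)] from the
    stack's covariate table. Single-site input is returned unchanged.
    Subject ordering and the edge index are never altered.
    """
    if site_labels is None:
        site_labels = stack.covariates["site"].to_numpy()
    site_labels = np.asarray(site_labels)
    if covariates is None and stack.covariates is not None:
        age = stack.covariates["age"].to_numpy(dtype=float)
        sex = stack.covariates["sex"].to_numpy(dtype=float)
        covariates = np.column_stack([age - age.mean(), sex])
    x_cov = (
        np.asarray(covariates, dtype=float)
        if covariates is not None
        else np.empty((stack.n_subjects, 0))
    )
    if x_cov.ndim == 1:
        x_cov = x_cov[:, None]

    sites = sorted(set(site_labels.tolist()))
    if len(sites) == 1:
        model = CombatModel(
            sites=sites,
            grand_mean=stack.values.mean(axis=0),
            beta=np.zeros((x_cov.shape[1], stack.n_edges)),
            gamma_star=np.zeros((1, stack.n_edges)),
            delta_sq_star=np.ones((1, stack.n_edges)),
            pooled_var=stack.values.var(axis=0),
            hyper={},
        )
        out = CohortEdgeStack(
            stack.metric_name,
            list(stack.subjects),
            list(stack.edge_index),
            stack.values.copy(),
            stack.covariates,
        )
        return out, model

    counts = {s: int(np.sum(site_labels == s)) for s in sites}
    for s, c in counts.items():
        if c < 2:
            raise ValueError(f"site {s!r} has only {c} subject(s); need >= 2")

    y = stack.values
    n, _ = y.shape
    onehot = np.column_stack([(site_labels == s).astype(float) for s in sites])
    design = np.hstack([onehot, x_cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("site + covariate design is rank deficient")
    b_hat, *_ = np.linalg.lstsq(design, y, rcond=None)
    site_coef = b_hat[: len(sites)]
    beta = b_hat[len(sites):]
    frac = np.array([counts[s] / n for s in sites])
    grand_mean = frac @ site_coef
    stand_mean = grand_mean[None, :] + x_cov @ beta
    pooled_var = np.mean((y - design @ b_hat) ** 2, axis=0)
    sd = np.sqrt(np.maximum(pooled_var, 1e-24))
    z = (y - stand_mean) / sd[None, :]

    gamma_star = np.zeros((len(sites), stack.n_edges))
    delta_star = np.zeros((len(sites), stack.n_edges))
    hyper = {"gamma_bar": [], "tau_sq": [], "a_prior": [], "b_prior": []}
    for k, s in enumerate(sites):
        rows = site_labels == s
        zs = z[rows]
        g_hat = zs.mean(axis=0)
        d_hat = zs.var(axis=0, ddof=1)
        g_bar, t2 = float(np.mean(g_hat)), float(np.var(g_hat))
        a, b = _aprior(d_hat), _bprior(d_hat)
        g_star, d_star = _it_sol(zs, g_hat, d_hat, g_bar, max(t2, 1e-12), a, b)
        gamma_star[k], delta_star[k] = g_star, d_star
        hyper["gamma_bar"].append(g_bar)
        hyper["tau_sq"].append(t2)
        hyper["a_prior"].append(a)
        hyper["b_prior"].append(b)

    adjusted = z.copy()
    for k, s in enumerate(sites):
        rows = site_labels == s
        adjusted[rows] = (z[rows] - gamma_star[k][None, :]) / np.sqrt(
            delta_star[k][None, :]
        )
    adjusted = adjusted * sd[None, :] + stand_mean

    model = CombatModel(
        sites=sites,
        grand_mean=grand_mean,
        beta=beta,
        gamma_star=gamma_star,
        delta_sq_star=delta_star,
        pooled_var=pooled_var,
        hyper=hyper,
    )
    out = CohortEdgeStack(
        stack.metric_name,
        list(stack.subjects),
        list(stack.edge_index),
        adjusted,
        stack.covariates,
    )
    return out, model
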