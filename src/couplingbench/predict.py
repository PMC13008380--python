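"""Behavioral prediction by kernel ridge regression.

Family-aware nested cross-validation (20 outer x 20 inner folds, repeated
20 times at full scale), train-fold behavioral confound regression (age,
sex, mean FD), permutation significance with a reduced 10-inner/20-outer
scheme, and Benjamini-Hochberg FDR.

The subject-similarity kernel is the product-moment correlation between
subjects' vectorized coupling features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

DEFAULT_LAMBDA_GRID = np.logspace(-4, 4, 16)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def residualize_behavior(
    behavior: np.ndarray,
    covariates: np.ndarray,
    train_index: np.ndarray,
    test_index: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """OLS of behavior on [1, covariates], fit on the training rows only;
    residuals for train and test both use the train-fold coefficients."""
    y = np.asarray(behavior, dtype=float)
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    x = np.hstack([np.ones((len(y), 1)), c])
    xtr = x[train_index]
    if np.linalg.matrix_rank(xtr) < xtr.shape[1]:
        keep = [0]
        for j in range(1, xtr.shape[1]):
            if np.linalg.matrix_rank(xtr[:, keep + [j]]) > len(keep):
                keep.append(j)
        warnings.warn("dropped collinear covariate column(s)", stacklevel=2)
        x, xtr = x[:, keep], xtr[:, keep]
    beta, *_ = np.linalg.lstsq(xtr, y[train_index], rcond=None)
    resid = y - x @ beta
    return resid[train_index], resid[test_index]


def build_kernel(features: np.ndarray) -> np.ndarray:
    """Correlation kernel: K(i, j) = corr(subject i's edges, subject j's)."""
    f = np.asarray(features, dtype=float)
    if f.shape[0] < 2 or f.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 features")
    sd = f.std(axis=1)
    if np.any(sd == 0):
        bad = np.where(sd == 0)[0]
        raise ValueError(f"zero-variance feature vector for subject index {bad[0]}")
    k = np.corrcoef(f)
    return (k + k.T) / 2.0


def krr_fit_predict(
    k_train: np.ndarray,
    y_train: np.ndarray,
    k_cross: np.ndarray,
    ridge_lambda: float,
) -> np.ndarray:
    """Closed-form KRR: alpha = (K + lambda I)^-1 y; predictions K_cross alpha."""
    if ridge_lambda <= 0:
        raise ValueError("ridge_lambda must be > 0")
    n = k_train.shape[0]
    m = k_train + ridge_lambda * np.eye(n)
    w = np.linalg.eigvalsh(m)
    if w[0] <= 0 or w[-1] / max(w[0], 1e-300) > 1e12:
        warnings.warn("ill-conditioned kernel solve; adding 1e-10 jitter",
                      stacklevel=2)
        m = m + 1e-10 * np.eye(n)
    alpha = np.linalg.solve(m, y_train)
    return k_cross @ alpha


def make_family_folds(
    family_ids: np.ndarray, n_folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Greedy family-blocked fold assignment.

    Families are shuffled, sorted by size (stable, largest first), and each
    is placed in the currently smallest fold, so all members of a family
    always share a fold. Returns per-subject fold labels.
    """
    uniq, inverse = np.unique(np.asarray(family_ids), return_inverse=True)
    order = rng.permutation(len(uniq))
    fam_sizes = np.bincount(inverse, minlength=len(uniq))
    order = order[np.argsort(-fam_sizes[order], kind="stable")]  # largest first
    target = len(family_ids) / n_folds
    sizes = np.zeros(n_folds, dtype=int)
    fold_of_family = np.empty(len(uniq), dtype=int)
    for f in order:
        k = int(np.argmin(sizes))
        if fam_sizes[f] > target:
            warnings.warn(
                f"family {uniq[f]!r} larger than the target fold size; placed alone",
                stacklevel=2,
            )
        fold_of_family[f] = k
        sizes[k] += fam_sizes[f]
    return fold_of_family[inverse]


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.sqrt((ac @ ac) * (bc @ bc))
    if denom == 0:
        return 0.0
    return float(ac @ bc / denom)


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CvSpec:
    outer_folds: int = 20
    inner_folds: int = 20
    repetitions: int = 20
    lambda_grid: np.ndarray = field(
        default_factory=lambda: DEFAULT_LAMBDA_GRID.copy()
    )
    seed: int = 0


@dataclass
class PredictionResult:
    behavior: str
    accuracies: np.ndarray  # repetitions x outer folds
    chosen_lambdas: np.ndarray  # repetitions x outer folds
    mean_accuracy: float
    permutation_p: float | None = None
    fdr_q: float | None = None


def _cv_once(
    kernel: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray,
    family_ids: np.ndarray,
    outer_folds: int,
    inner_folds: int,
    lambda_grid: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One repetition of nested CV; returns per-outer-fold accuracy and
    chosen lambda."""
    n = len(y)
    outer = make_family_folds(family_ids, outer_folds, rng)
    accs = np.empty(outer_folds)
    lams = np.empty(outer_folds)
    for fold in range(outer_folds):
        test = np.flatnonzero(outer == fold)
        train = np.flatnonzero(outer != fold)
        if len(test) == 0 or len(train) < 3:
            accs[fold] = np.nan
            lams[fold] = np.nan
            continue
        y_tr, y_te = residualize_behavior(y, covariates, train, test)
        inner = make_family_folds(family_ids[train], inner_folds, rng)
        scores = np.zeros(len(lambda_grid))
        for ifold in range(inner_folds):
            iva = train[inner == ifold]
            itr = train[inner != ifold]
            if len(iva) == 0 or len(itr) < 3:
                continue
            yi_tr, yi_va = residualize_behavior(y, covariates, itr, iva)
            # one eigendecomposition serves the whole lambda grid
            w, u = np.linalg.eigh(kernel[np.ix_(itr, itr)])
            uty = u.T @ yi_tr
            k_va_u = kernel[np.ix_(iva, itr)] @ u
            for li, lam in enumerate(lambda_grid):
                pred = k_va_u @ (uty / (w + lam))
                scores[li] += _safe_corr(yi_va, pred)
        best = int(np.argmax(scores))  # ties -> smaller lambda (first index)
        lam = float(lambda_grid[best])
        pred = krr_fit_predict(
            kernel[np.ix_(train, train)], y_tr, kernel[np.ix_(test, train)], lam
        )
        accs[fold] = _safe_corr(y_te, pred)
        lams[fold] = lam
    return accs, lams


def nested_cv(
    features: np.ndarray,
    behavior: np.ndarray,
    covariates: np.ndarray,
    family_ids: np.ndarray,
    spec: CvSpec | None = None,
    behavior_name: str = "behavior",
    kernel: np.ndarray | None = None,
) -> PredictionResult:
    """Family-aware repeated nested-CV kernel ridge prediction.

    Per outer fold, the ridge penalty is chosen by mean inner-fold accuracy
    (correlation of true and predicted residualized scores), the model is
    refit on the full training fold, and accuracy is the correlation on the
    held-out fold. The behavior is residualized on the covariates with
    train-fold coefficients only.
    """
    if spec is None:
        spec = CvSpec()
    if kernel is None:
        kernel = build_kernel(features)
    n = kernel.shape[0]
    if n < 2 * spec.outer_folds:
        raise ValueError("need at least 2 subjects per outer fold")
    rng = np.random.default_rng(spec.seed)
    accs = np.empty((spec.repetitions, spec.outer_folds))
    lams = np.empty((spec.repetitions, spec.outer_folds))
    for rep in range(spec.repetitions):
        accs[rep], lams[rep] = _cv_once(
            kernel,
            np.asarray(behavior, dtype=float),
            covariates,
            np.asarray(family_ids),
            spec.outer_folds,
            spec.inner_folds,
            spec.lambda_grid,
            rng,
        )
    return PredictionResult(
        behavior=behavior_name,
        accuracies=accs,
        chosen_lambdas=lams,
        mean_accuracy=float(np.nanmean(accs)),
    )


# ---------------------------------------------------------------------------
# permutation significance and FDR
# ---------------------------------------------------------------------------

def _permute_by_family(
    y: np.ndarray, family_ids: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Permute behavior blockwise: families of equal size exchange their
    members' values jointly; singleton families permute freely."""
    uniq, inverse = np.unique(np.asarray(family_ids), return_inverse=True)
    out = y.copy()
    members = [np.flatnonzero(inverse == f) for f in range(len(uniq))]
    by_size: dict[int, list[np.ndarray]] = {}
    for idx in members:
        by_size.setdefault(len(idx), []).append(idx)
    for size, blocks in by_size.items():
        if size == 1:
            flat = np.concatenate(blocks).ravel()
            out[flat] = y[flat[rng.permutation(len(flat))]]
            continue
        perm = rng.permutation(len(blocks))
        for bi, block in enumerate(blocks):
            src = blocks[perm[bi]]
            out[block] = y[src[rng.permutation(size)]]
    return out


def permutation_test(
    features: np.ndarray,
    behavior: np.ndarray,
    covariates: np.ndarray,
    family_ids: np.ndarray,
    observed_mean_accuracy: float,
    n_perm: int = 1000,
    outer_folds: int = 20,
    inner_folds: int = 10,
    lambda_grid: np.ndarray | None = None,
    seed: int = 0,
    family_blocks: bool = True,
    kernel: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Permutation p for a mean prediction accuracy.

    Behavior labels are permuted (blockwise by family when
    ``family_blocks``), the full reduced-scheme CV is re-run per
    permutation, and p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if lambda_grid is None:
        lambda_grid = DEFAULT_LAMBDA_GRID
    if kernel is None:
        kernel = build_kernel(features)
    rng = np.random.default_rng(seed)
    y = np.asarray(behavior, dtype=float)
    fam = np.asarray(family_ids)
    null = np.empty(n_perm)
    for p in range(n_perm):
        if family_blocks:
            y_perm = _permute_by_family(y, fam, rng)
        else:
            y_perm = y[rng.permutation(len(y))]
        accs, _ = _cv_once(
            kernel, y_perm, covariates, fam, outer_folds, inner_folds,
            lambda_grid, rng,
        )
        null[p] = np.nanmean(accs)
    p_val = (1.0 + np.sum(null >= observed_mean_accuracy)) / (1.0 + n_perm)
    return float(p_val), null


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up rule; returns (reject flags, q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject, q_vals, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, q_vals
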