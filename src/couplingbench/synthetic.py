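"""Synthetic rs-fMRI cohort generator with known ground truth.

The generator plants every structure the downstream benchmark needs to see:

* a stable VAR(1) latent network (known coupling and stationary covariance),
  observed through a canonical double-gamma hemodynamic response plus white
  measurement noise;
* subject-varying head motion built from AR(1) drift, a respiratory sinusoid
  at 0.37 Hz (mid-band of the 0.31-0.43 Hz respiratory notch), and white
  jitter, scaled to a target mean framewise displacement;
* distance-dependent motion contamination of edges (short edges are the most
  susceptible, with susceptibility decaying as exp(-d/L));
* multi-site additive structure in the measured signal and family-clustered
  behavioral noise (family intercept ICC 0.3);
* behaviors correlated with a weighted coupling summary at a controlled
  population effect size, plus loadings on age/sex/FD so confound regression
  has real work to do.

Everything is deterministic given the CohortSpec seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .types import MotionTrace, ParcellatedTimeSeries, stack_matrices

HEAD_RADIUS_MM = 50.0
RESPIRATORY_HZ = 0.37
CUBE_SIDE_MM = 140.0
FAMILY_ICC = 0.3
FD_REFERENCE_MM = 0.1  # typical per-frame FD fluctuation; artifact amplitude unit


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_subjects: int = 200
    n_regions: int = 50
    n_frames: int = 500
    tr_s: float = 0.72
    n_sites: int = 1
    family_sizes: list[int] | None = None
    motion_severity_range: tuple[float, float] = (0.05, 0.3)
    artifact_gain: float = 0.0
    artifact_distance_scale: float = 35.0
    behavior_effect_r: float = 0.0
    n_behaviors: int = 1
    site_offset_sd: float = 0.0
    edge_density: float = 0.1
    noise_sd: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 3:
            raise ValueError("n_regions must be >= 3")
        if self.n_frames < 64:
            raise ValueError("n_frames must be >= 64")
        if not 0.0 <= self.behavior_effect_r <= 0.9:
            raise ValueError("behavior_effect_r must lie in [0, 0.9]")
        if self.family_sizes is None:
            self.family_sizes = [1] * self.n_subjects
        if sum(self.family_sizes) != self.n_subjects:
            raise ValueError("family_sizes must sum to n_subjects")


@dataclass
class TrueNetwork:
    """Ground-truth VAR(1) system and region geometry."""

    coupling_coefficients: np.ndarray  # A, regions x regions
    innovation_covariance: np.ndarray  # Q, SPD
    centroids: np.ndarray  # regions x 3, mm

    def __post_init__(self) -> None:
        rho = np.max(np.abs(np.linalg.eigvals(self.coupling_coefficients)))
        if rho >= 1.0:
            raise ValueError(f"VAR(1) system unstable (spectral radius {rho:.3f})")

    @property
    def n_regions(self) -> int:
        return self.coupling_coefficients.shape[0]

    def stationary_covariance(self) -> np.ndarray:
        """Solve the discrete Lyapunov equation S = A S A' + Q."""
        return linalg.solve_discrete_lyapunov(
            self.coupling_coefficients, self.innovation_covariance
        )


@dataclass
class GroundTruthRecord:
    true_network: TrueNetwork
    edge_susceptibility: np.ndarray  # regions x regions
    behavior_weights: np.ndarray  # n_behaviors x n_edges
    per_subject_motion_severity: np.ndarray  # mm


@dataclass
class Cohort:
    """A fully generated cohort plus its ground truth."""

    spec: CohortSpec
    series: list[ParcellatedTimeSeries]
    clean_series: list[ParcellatedTimeSeries]
    motion: list[MotionTrace]
    behavior: pd.DataFrame
    centroids: np.ndarray
    ground_truth: GroundTruthRecord
    edge_scores: np.ndarray = field(default=None)  # subjects x n_behaviors


def make_true_network(
    n_regions: int, edge_density: float, rng_seed: int | np.random.Generator
) -> TrueNetwork:
    """Draw a stable VAR(1) network with random geometry.

    Off-diagonal couplings are Bernoulli(edge_density) with N(0, 0.25^2)
    weights; diagonal decay is uniform in [0.2, 0.6]. The transition matrix
    is rescaled to spectral radius 0.9 whenever it exceeds 0.9, which
    guarantees stability. Innovations are independent across regions with
    variances in [0.5, 1.5] so the no-coupling case has a diagonal
    stationary covariance.
    """
    if not 0 < edge_density <= 1:
        if edge_density != 0:
            raise ValueError("edge_density must lie in (0, 1] (or exactly 0)")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    a = np.zeros((n_regions, n_regions))
    mask = rng.random((n_regions, n_regions)) < edge_density
    np.fill_diagonal(mask, False)
    a[mask] = rng.normal(0.0, 0.25, size=int(mask.sum()))
    np.fill_diagonal(a, rng.uniform(0.2, 0.6, size=n_regions))
    rho = np.max(np.abs(np.linalg.eigvals(a)))
    if rho >= 0.9:
        a *= 0.9 / rho
    q = np.diag(rng.uniform(0.5, 1.5, size=n_regions))
    centroids = rng.uniform(0.0, CUBE_SIDE_MM, size=(n_regions, 3))
    return TrueNetwork(a, q, centroids)


def canonical_hrf(tr_s: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at the TR (peak 6 s, undershoot
    16 s, peak/undershoot ratio 6), truncated at ``duration_s`` and
    normalized to unit peak."""
    t = np.arange(0.0, duration_s, tr_s)
    peak = stats.gamma.pdf(t, a=6.0, scale=1.0)
    undershoot = stats.gamma.pdf(t, a=16.0, scale=1.0)
    h = peak - undershoot / 6.0
    m = np.max(np.abs(h))
    return h / m if m > 0 else h


def simulate_subject_series(
    true_network: TrueNetwork,
    n_frames: int,
    tr_s: float,
    rng_seed: int | np.random.Generator,
    noise_sd: float = 0.5,
    subject_id: str = "sub-000",
    burn_in: int = 200,
) -> ParcellatedTimeSeries:
    """Simulate a VAR(1) latent process, convolve with the canonical HRF,
    and add white measurement noise."""
    if n_frames < 64:
        raise ValueError("n_frames must be >= 64")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    a = true_network.coupling_coefficients
    q = true_network.innovation_covariance
    n_regions = a.shape[0]
    hrf = canonical_hrf(tr_s)
    total = burn_in + n_frames + len(hrf)
    if not np.any(q):
        chol = np.zeros_like(q)
    else:
        try:
            chol = np.linalg.cholesky(q)
        except np.linalg.LinAlgError:  # PSD but singular innovations
            w, v = np.linalg.eigh(q)
            chol = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    innov = rng.standard_normal((total, n_regions)) @ chol.T
    x = np.zeros((total, n_regions))
    for t in range(1, total):
        x[t] = x[t - 1] @ a.T + innov[t]
    x = x[burn_in:]
    # convolve each region with the HRF, crop to n_frames after edge effects
    bold = np.apply_along_axis(lambda v: np.convolve(v, hrf, mode="full"), 0, x)
    bold = bold[len(hrf) : len(hrf) + n_frames]
    bold = bold + noise_sd * rng.standard_normal(bold.shape)
    return ParcellatedTimeSeries(subject_id=subject_id, data=bold, tr_s=tr_s)


def _raw_motion_components(
    n_frames: int, tr_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Six unscaled displacement traces (mm-equivalent)."""
    t = np.arange(n_frames) * tr_s
    params = np.empty((n_frames, 6))
    for k in range(6):
        drift = np.empty(n_frames)
        drift[0] = 0.0
        eps = rng.standard_normal(n_frames)
        for i in range(1, n_frames):
            drift[i] = 0.95 * drift[i - 1] + eps[i]
        drift /= max(np.std(drift), 1e-12)
        resp = np.sin(2 * np.pi * RESPIRATORY_HZ * t + rng.uniform(0, 2 * np.pi))
        jitter = rng.standard_normal(n_frames)
        params[:, k] = drift + 0.8 * resp + 0.3 * jitter
    return params


def simulate_motion(
    n_frames: int,
    tr_s: float,
    severity_mm: float,
    rng_seed: int | np.random.Generator,
    subject_id: str = "sub-000",
) -> MotionTrace:
    """Six rigid-body traces whose unfiltered mean FD ~= ``severity_mm``.

    Traces are AR(1) drift + 0.37 Hz respiratory sinusoid + white jitter,
    generated in displacement units and rescaled so that the realized
    unnotched mean FD equals the requested severity. Rotations are stored
    in radians (displacement / 50 mm head radius).
    """
    if severity_mm < 0:
        raise ValueError("severity_mm must be >= 0")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    if severity_mm == 0:
        return MotionTrace(subject_id, np.zeros((n_frames, 6)), tr_s)
    disp = _raw_motion_components(n_frames, tr_s, rng)
    fd_raw = np.abs(np.diff(disp, axis=0)).sum(axis=1)
    scale = severity_mm / max(np.mean(fd_raw), 1e-12)
    disp *= scale
    params = disp.copy()
    params[:, 3:] /= HEAD_RADIUS_MM  # store rotations as radians
    return MotionTrace(subject_id, params, tr_s)


def distance_susceptibility(
    centroids: np.ndarray, distance_scale_mm: float
) -> np.ndarray:
    """Edge contamination weights exp(-d_ij / L); unit diagonal."""
    d = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=-1)
    return np.exp(-d / distance_scale_mm)


def _region_weights(edge_susceptibility: np.ndarray) -> np.ndarray:
    """Nonnegative region weights whose outer product tracks the edge
    susceptibility (leading eigenvector, Perron-Frobenius)."""
    vals, vecs = np.linalg.eigh(edge_susceptibility)
    w = np.abs(vecs[:, -1])
    return w / max(w.max(), 1e-12)


def inject_motion_artifact(
    series: ParcellatedTimeSeries,
    fd_trace: np.ndarray,
    edge_susceptibility: np.ndarray,
    artifact_gain: float,
) -> ParcellatedTimeSeries:
    """Add a shared motion regressor with distance-dependent region weights.

    Edge (i, j) contamination scales with w_i * w_j where w is the leading
    eigenvector of the susceptibility matrix, so short (high-susceptibility)
    edges receive the strongest spurious coupling. The regressor is the
    demeaned FD trace scaled against a fixed 0.1 mm reference fluctuation,
    so high-motion subjects receive proportionally stronger contamination —
    the across-subject gradient that QC-FC is designed to detect.
    ``artifact_gain = 0`` (or all-zero susceptibility) returns the input
    unchanged.
    """
    fd = np.asarray(fd_trace, dtype=float)
    if len(fd) != series.n_frames:
        raise ValueError(
            f"FD length {len(fd)} does not match series frames {series.n_frames}"
        )
    if artifact_gain == 0 or not np.any(edge_susceptibility):
        return series
    z = (fd - fd.mean()) / FD_REFERENCE_MM
    w = _region_weights(edge_susceptibility)
    region_sd = series.data.std(axis=0)
    data = series.data + artifact_gain * np.outer(z, w * region_sd)
    return ParcellatedTimeSeries(series.subject_id, data, series.tr_s)


def generate_behavior(
    edge_scores: np.ndarray,
    behavior_effect_r: float,
    covariates: pd.DataFrame,
    rng_seed: int | np.random.Generator,
    covariate_loadings: dict[str, float] | None = None,
    family_icc: float = FAMILY_ICC,
) -> pd.DataFrame:
    """Synthesize behaviors correlated with coupling summaries.

    Each behavior b_k = r * s_k + loadings on (age, sex, mean_fd) + family
    intercept + Gaussian noise, with variances budgeted so the population
    correlation between b_k and the standardized edge score s_k is
    ``behavior_effect_r`` when covariates are independent of the score.

    ``edge_scores`` is subjects x n_behaviors; ``covariates`` must carry
    columns subject_id, site, family_id, age, sex, mean_fd.
    """
    if not 0.0 <= behavior_effect_r < 1.0:
        raise ValueError("behavior_effect_r must lie in [0, 1)")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    if covariate_loadings is None:
        covariate_loadings = {"age": 0.2, "sex": 0.2, "mean_fd": 0.2}
    scores = np.atleast_2d(np.asarray(edge_scores, dtype=float))
    if scores.shape[0] != len(covariates):
        scores = scores.T
    n, n_beh = scores.shape
    scores = (scores - scores.mean(axis=0)) / np.where(
        scores.std(axis=0) > 0, scores.std(axis=0), 1.0
    )

    def _std(v):
        v = np.asarray(v, dtype=float)
        s = v.std()
        return (v - v.mean()) / s if s > 0 else np.zeros_like(v)

    cov_term = sum(
        covariate_loadings.get(c, 0.0) * _std(covariates[c].to_numpy())
        for c in ("age", "sex", "mean_fd")
    )
    load_var = sum(v**2 for v in covariate_loadings.values())
    resid_var = 1.0 - behavior_effect_r**2 - load_var
    if resid_var <= 0:
        raise ValueError("effect size plus covariate loadings exceed unit variance")
    fam_codes, _ = pd.factorize(covariates["family_id"])
    out = covariates.copy()
    for k in range(n_beh):
        fam_u = rng.standard_normal(fam_codes.max() + 1)
        noise = np.sqrt(family_icc) * fam_u[fam_codes] + np.sqrt(
            1 - family_icc
        ) * rng.standard_normal(n)
        out[f"beh_{k:02d}"] = (
            behavior_effect_r * scores[:, k] + cov_term + np.sqrt(resid_var) * noise
        )
    return out


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a full cohort from a CohortSpec; deterministic in the seed."""
    from .prep import compute_fd  # local import to avoid a cycle
    from .covariance import pearson_fc

    root = np.random.SeedSequence(spec.rng_seed)
    net_ss, beh_ss, site_ss, subj_ss = root.spawn(4)
    network = make_true_network(
        spec.n_regions, spec.edge_density, np.random.default_rng(net_ss)
    )
    susceptibility = distance_susceptibility(
        network.centroids, spec.artifact_distance_scale
    )
    site_rng = np.random.default_rng(site_ss)
    site_weights = site_rng.normal(
        0.0, 1.0, size=(spec.n_sites, spec.n_regions)
    )

    # roster: families assigned to sites round-robin, members contiguous
    family_ids, sites = [], []
    for f, size in enumerate(spec.family_sizes):
        family_ids += [f"fam-{f:04d}"] * size
        sites += [f"site-{f % spec.n_sites:02d}"] * size

    subj_seeds = subj_ss.spawn(spec.n_subjects)
    beh_rng = np.random.default_rng(beh_ss)
    severities = beh_rng.uniform(*spec.motion_severity_range, size=spec.n_subjects)
    ages = beh_rng.uniform(9.0, 40.0, size=spec.n_subjects)
    sexes = beh_rng.integers(0, 2, size=spec.n_subjects)

    series, clean, motions, mean_fds = [], [], [], []
    for s in range(spec.n_subjects):
        rng = np.random.default_rng(subj_seeds[s])
        sid = f"sub-{s:04d}"
        ts = simulate_subject_series(
            network, spec.n_frames, spec.tr_s, rng, spec.noise_sd, subject_id=sid
        )
        mot = simulate_motion(
            spec.n_frames, spec.tr_s, severities[s], rng, subject_id=sid
        )
        fd = compute_fd(mot, apply_notch=False)
        clean.append(ts)
        contaminated = inject_motion_artifact(
            ts, fd.fd_mm, susceptibility, spec.artifact_gain
        )
        data = contaminated.data
        if spec.site_offset_sd > 0 and spec.n_sites > 1:
            site_idx = int(sites[s].split("-")[1])
            shared = rng.standard_normal(spec.n_frames)
            data = data + spec.site_offset_sd * np.outer(
                shared, site_weights[site_idx]
            )
        series.append(ParcellatedTimeSeries(sid, data, spec.tr_s))
        motions.append(mot)
        mean_fds.append(fd.mean_fd)

    covs = pd.DataFrame(
        {
            "subject_id": [f"sub-{s:04d}" for s in range(spec.n_subjects)],
            "site": sites,
            "family_id": family_ids,
            "age": ages,
            "sex": sexes,
            "mean_fd": mean_fds,
        }
    )

    # behavior is driven by the clean coupling structure
    n_edges = spec.n_regions * (spec.n_regions - 1) // 2
    weights = np.zeros((spec.n_behaviors, n_edges))
    k = max(1, n_edges // 10)
    for b in range(spec.n_behaviors):
        idx = beh_rng.choice(n_edges, size=k, replace=False)
        weights[b, idx] = beh_rng.normal(0.0, 1.0, size=k)
    clean_stack = stack_matrices([pearson_fc(ts) for ts in clean])
    scores = clean_stack.values @ weights.T
    behavior = generate_behavior(scores, spec.behavior_effect_r, covs, beh_rng)

    gt = GroundTruthRecord(
        true_network=network,
        edge_susceptibility=susceptibility,
        behavior_weights=weights,
        per_subject_motion_severity=severities,
    )
    return Cohort(
        spec=spec,
        series=series,
        clean_series=clean,
        motion=motions,
        behavior=behavior,
        centroids=network.centroids,
        ground_truth=gt,
        edge_scores=scores,
    )


# ---------------------------------------------------------------------------
# on-disk cohort layout
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict:
    """Write a cohort to a directory of plain-text files, with a manifest.

    Per subject: a tab-separated time-series file (header region_001...) and
    a tab-separated motion file; cohort-level: behavior CSV, centroid CSV, a
    ground-truth JSON and a manifest JSON with sha256 checksums.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    region_cols = [f"region_{r + 1:03d}" for r in range(cohort.spec.n_regions)]
    motion_cols = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    for ts, mot in zip(cohort.series, cohort.motion):
        f_ts = out / f"{ts.subject_id}_timeseries.tsv"
        pd.DataFrame(ts.data, columns=region_cols).to_csv(
            f_ts, sep="\t", index=False, float_format="%.17g"
        )
        f_mot = out / f"{mot.subject_id}_motion.tsv"
        pd.DataFrame(mot.params, columns=motion_cols).to_csv(
            f_mot, sep="\t", index=False, float_format="%.17g"
        )
        files += [f_ts, f_mot]
    f_beh = out / "behavior.csv"
    cohort.behavior.to_csv(f_beh, index=False, float_format="%.17g")
    f_cen = out / "centroids.csv"
    pd.DataFrame(
        {
            "region": region_cols,
            "x": cohort.centroids[:, 0],
            "y": cohort.centroids[:, 1],
            "z": cohort.centroids[:, 2],
        }
    ).to_csv(f_cen, index=False, float_format="%.17g")
    gt = cohort.ground_truth
    f_gt = out / "ground_truth.json"
    f_gt.write_text(
        json.dumps(
            {
                "coupling_coefficients": gt.true_network.coupling_coefficients.tolist(),
                "innovation_covariance": gt.true_network.innovation_covariance.tolist(),
                "centroids": gt.true_network.centroids.tolist(),
                "edge_susceptibility": gt.edge_susceptibility.tolist(),
                "behavior_weights": gt.behavior_weights.tolist(),
                "per_subject_motion_severity": gt.per_subject_motion_severity.tolist(),
            },
            indent=1,
        )
    )
    files += [f_beh, f_cen, f_gt]
    manifest = {
        "n_subjects": cohort.spec.n_subjects,
        "tr_s": cohort.spec.tr_s,
        "files": {f.name: _sha256(f) for f in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_cohort_arrays(in_dir: str | Path, verify: bool = True) -> dict:
    """Read a written cohort back; returns dict with series/motion/behavior/
    centroids. Checksums are verified against the manifest by default."""
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    if verify:
        for name, digest in manifest["files"].items():
            actual = _sha256(src / name)
            if actual != digest:
                raise ValueError(f"checksum mismatch for {name}")
    tr_s = manifest["tr_s"]
    series, motion = [], []
    for name in sorted(manifest["files"]):
        if name.endswith("_timeseries.tsv"):
            sid = name[: -len("_timeseries.tsv")]
            data = pd.read_csv(
                src / name, sep="\t", float_precision="round_trip"
            ).to_numpy()
            series.append(ParcellatedTimeSeries(sid, data, tr_s))
        elif name.endswith("_motion.tsv"):
            sid = name[: -len("_motion.tsv")]
            params = pd.read_csv(
                src / name, sep="\t", float_precision="round_trip"
            ).to_numpy()
            motion.append(MotionTrace(sid, params, tr_s))
    behavior = pd.read_csv(src / "behavior.csv", float_precision="round_trip")
    cen = pd.read_csv(src / "centroids.csv", float_precision="round_trip")
    return {
        "series": series,
        "motion": motion,
        "behavior": behavior,
        "centroids": cen[["x", "y", "z"]].to_numpy(),
        "manifest": manifest,
    }
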