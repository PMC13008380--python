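"""Parcellated-level preprocessing tail.

Nuisance regression, Fourier rectangular bandpass (0.008-0.08 Hz),
framewise displacement with respiratory-band filtering, and the three-rule
high-motion participant exclusion.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .types import FDTrace, MotionTrace, ParcellatedTimeSeries

logger = logging.getLogger(__name__)

DEFAULT_BAND = (0.008, 0.08)
RESPIRATORY_BAND = (0.31, 0.43)
HEAD_RADIUS_MM = 50.0

# exclusion thresholds: mean FD, fraction of frames above 0.2 mm, any-frame spike
MEAN_FD_LIMIT = 0.3
FRACTION_LIMIT = 0.2
FRAME_FD_LIMIT = 0.2
SPIKE_LIMIT = 5.0


def expand_motion_24(motion: MotionTrace) -> np.ndarray:
    """24-parameter motion expansion: [p, dp, p^2, dp^2].

    Derivatives are backward differences with a zero first row, matching
    the BIDS-confounds convention.
    """
    p = motion.params
    dp = np.vstack([np.zeros((1, 6)), np.diff(p, axis=0)])
    return np.hstack([p, dp, p**2, dp**2])


def _drop_collinear(x: np.ndarray) -> np.ndarray:
    """Drop columns that add no rank (greedy, left to right)."""
    keep: list[int] = []
    for j in range(x.shape[1]):
        cand = x[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(j)
    if len(keep) < x.shape[1]:
        warnings.warn(
            f"dropped {x.shape[1] - len(keep)} collinear confound column(s)",
            stacklevel=3,
        )
    return x[:, keep]


def regress_confounds(
    series: ParcellatedTimeSeries, confound_matrix: np.ndarray | None
) -> ParcellatedTimeSeries:
    """OLS residuals of each region on [intercept + confounds]."""
    t = series.n_frames
    if confound_matrix is None:
        x = np.ones((t, 1))
    else:
        confound_matrix = np.asarray(confound_matrix, dtype=float)
        if confound_matrix.shape[0] != t:
            raise ValueError("confound matrix must have one row per frame")
        x = np.hstack([np.ones((t, 1)), confound_matrix])
        x = _drop_collinear(x)
    beta, *_ = np.linalg.lstsq(x, series.data, rcond=None)
    resid = series.data - x @ beta
    return ParcellatedTimeSeries(series.subject_id, resid, series.tr_s)


def bandpass_rectangular(
    series: ParcellatedTimeSeries,
    f_lo: float = DEFAULT_BAND[0],
    f_hi: float = DEFAULT_BAND[1],
) -> ParcellatedTimeSeries:
    """Fourier-based rectangular (ideal) bandpass.

    FFT bins with frequency outside [f_lo, f_hi] are zeroed; DC is always
    zeroed, so the output is mean-free per region.
    """
    nyquist = 1.0 / (2.0 * series.tr_s)
    if not f_lo < f_hi < nyquist:
        raise ValueError(
            f"band ({f_lo}, {f_hi}) must satisfy f_lo < f_hi < Nyquist {nyquist:.4f}"
        )
    t = series.n_frames
    freqs = np.fft.rfftfreq(t, d=series.tr_s)
    spec = np.fft.rfft(series.data, axis=0)
    keep = (freqs >= f_lo) & (freqs <= f_hi)
    keep[0] = False
    spec[~keep] = 0.0
    out = np.fft.irfft(spec, n=t, axis=0)
    return ParcellatedTimeSeries(series.subject_id, out, series.tr_s)


def _bandstop_params(
    params: np.ndarray, tr_s: float, band: tuple[float, float], mode: str
) -> np.ndarray:
    """Frequency-domain rectangular band filter of motion parameters."""
    t = params.shape[0]
    freqs = np.fft.rfftfreq(t, d=tr_s)
    spec = np.fft.rfft(params, axis=0)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if mode == "bandstop":
        spec[in_band] = 0.0
    elif mode == "bandpass":
        spec[~in_band] = 0.0
    else:
        raise ValueError("mode must be 'bandstop' or 'bandpass'")
    return np.fft.irfft(spec, n=t, axis=0)


def compute_fd(
    motion: MotionTrace,
    notch_band: tuple[float, float] = RESPIRATORY_BAND,
    head_radius_mm: float = HEAD_RADIUS_MM,
    apply_notch: bool = True,
    notch_mode: str = "bandstop",
) -> FDTrace:
    """Framewise displacement: sum of absolute frame-to-frame differences.

    Rotations are converted to arc displacement on a ``head_radius_mm``
    sphere. When ``apply_notch``, the respiratory band (0.31-0.43 Hz by
    default) is removed from each parameter with a frequency-domain
    band-stop before differencing (``notch_mode="bandpass"`` keeps only the
    band instead, for the literal reading of band-pass filtering). The
    first frame's FD is defined as 0.
    """
    p = motion.params
    if p.shape[0] < 2:
        raise ValueError("need at least 2 frames to compute FD")
    if not np.all(np.isfinite(p)):
        raise ValueError("non-finite motion parameters")
    disp = p.copy()
    if motion.rotation_unit == "degrees":
        disp[:, 3:] = np.deg2rad(disp[:, 3:])
    disp[:, 3:] *= head_radius_mm
    if apply_notch:
        nyquist = 1.0 / (2.0 * motion.tr_s)
        if notch_band[1] >= nyquist:
            warnings.warn(
                f"notch band {notch_band} exceeds Nyquist {nyquist:.3f} Hz; skipped",
                stacklevel=2,
            )
        else:
            disp = _bandstop_params(disp, motion.tr_s, notch_band, notch_mode)
    fd = np.zeros(p.shape[0])
    fd[1:] = np.abs(np.diff(disp, axis=0)).sum(axis=1)
    return FDTrace(motion.subject_id, fd)


def apply_exclusions(fd_traces: list[FDTrace]) -> pd.DataFrame:
    """Three-rule high-motion exclusion.

    A subject is excluded if (a) mean FD > 0.3 mm, (b) more than 20% of
    frames have FD > 0.2 mm, or (c) any frame has FD > 5 mm. All
    inequalities are strict.
    """
    if not fd_traces:
        raise ValueError("no subjects")
    rows = []
    for tr in fd_traces:
        fd = tr.fd_mm
        mean_fd = float(np.mean(fd))
        frac = float(np.mean(fd > FRAME_FD_LIMIT))
        max_fd = float(np.max(fd))
        rules = []
        if mean_fd > MEAN_FD_LIMIT:
            rules.append("a")
        if frac > FRACTION_LIMIT:
            rules.append("b")
        if max_fd > SPIKE_LIMIT:
            rules.append("c")
        rows.append(
            {
                "subject_id": tr.subject_id,
                "mean_fd": mean_fd,
                "fraction_above_0p2": frac,
                "max_fd": max_fd,
                "excluded": bool(rules),
                "triggered_rules": ",".join(rules),
            }
        )
    report = pd.DataFrame(rows)
    logger.info(
        "exclusions: %d of %d subjects flagged",
        int(report["excluded"].sum()),
        len(report),
    )
    return report


def preprocess_series(
    series: ParcellatedTimeSeries,
    motion: MotionTrace | None = None,
    extra_confounds: np.ndarray | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
    include_global_signal: bool = False,
) -> ParcellatedTimeSeries:
    """Standard tail: 24-parameter motion regression (optionally with a
    surrogate global signal and its derivative) followed by the
    rectangular bandpass.

    Global-signal regression removes one dimension of region space; at
    benchmark region counts (tens of regions) this drives the sample
    covariance toward singularity and degenerates full partial
    correlations, so it is off by default and should only be enabled for
    parcellations large enough to absorb it.
    """
    confounds = []
    if motion is not None:
        confounds.append(expand_motion_24(motion))
    if include_global_signal:
        gs = series.data.mean(axis=1, keepdims=True)
        confounds.append(np.hstack([gs, np.vstack([[0.0], np.diff(gs, axis=0)])]))
    if extra_confounds is not None:
        confounds.append(np.asarray(extra_confounds, dtype=float))
    conf = np.hstack(confounds) if confounds else None
    out = regress_confounds(series, conf)
    return bandpass_rectangular(out, *band)
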