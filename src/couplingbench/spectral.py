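"""Frequency-domain coupling estimators.

Magnitude-squared spectral coherence from Welch averaged periodograms,
Morlet wavelet coherence with the standard time/scale smoothing, and a
normalized mutual-information metric derived from the coherence spectrum
(phi = 1 - exp(-2*delta), delta = |(1/2pi) * integral of log(1 - C(Omega))
over the band|, Omega in rad/s).

All estimators are band-averaged over 0.008-0.08 Hz by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal.windows import hann

from .types import CouplingMatrix, ParcellatedTimeSeries

DEFAULT_BAND = (0.008, 0.08)


@dataclass
class CoherenceSpectrum:
    """Per-pair coherence on a frequency grid (regions x regions x freqs)."""

    frequencies: np.ndarray
    coherence: np.ndarray
    method: str

    def __post_init__(self) -> None:
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be strictly increasing")


def _default_window(n_frames: int) -> int:
    """min(frames/4 rounded down to a power of two, 256)."""
    w = 2 ** int(np.floor(np.log2(max(n_frames // 4, 8))))
    return min(w, 256)


def welch_cross_spectra(
    data: np.ndarray,
    tr_s: float,
    window_frames: int | None = None,
    overlap_fraction: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Hann-tapered averaged periodogram auto/cross spectra for all pairs.

    Returns (frequencies, cross-spectral tensor F x R x R, n_segments).
    Each segment is demeaned before tapering.
    """
    t, _ = data.shape
    if window_frames is None:
        window_frames = _default_window(t)
    if window_frames > t:
        raise ValueError("window_frames exceeds series length")
    step = max(1, int(round(window_frames * (1 - overlap_fraction))))
    starts = range(0, t - window_frames + 1, step)
    win = hann(window_frames, sym=False)
    segs = []
    for s in starts:
        seg = data[s : s + window_frames]
        seg = (seg - seg.mean(axis=0)) * win[:, None]
        segs.append(np.fft.rfft(seg, axis=0))
    z = np.stack(segs)  # n_seg x F x R
    freqs = np.fft.rfftfreq(window_frames, d=tr_s)
    s_xy = np.einsum("sfi,sfj->fij", z, np.conj(z)) / z.shape[0]
    return freqs, s_xy, z.shape[0]


def spectral_coherence_spectrum(
    series: ParcellatedTimeSeries,
    window_frames: int | None = None,
    overlap_fraction: float = 0.5,
) -> CoherenceSpectrum:
    """Magnitude-squared coherence C = |S_xy|^2 / (S_xx S_yy) per frequency."""
    freqs, s_xy, _ = welch_cross_spectra(
        series.data, series.tr_s, window_frames, overlap_fraction
    )
    auto = np.real(np.einsum("fii->fi", s_xy))
    denom = auto[:, :, None] * auto[:, None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(s_xy) ** 2 / denom
    coh = np.clip(np.nan_to_num(coh.real), 0.0, 1.0)
    # drop DC: coherence at 0 Hz is meaningless after demeaning
    return CoherenceSpectrum(freqs[1:], np.moveaxis(coh[1:], 0, -1), "welch")


def _band_mask(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if mask.sum() < 2:
        raise ValueError(
            f"fewer than 2 frequency bins inside band {band}; "
            "lengthen the window or widen the band"
        )
    return mask


def spectral_coherence_fc(
    series: ParcellatedTimeSeries,
    band: tuple[float, float] = DEFAULT_BAND,
    window_frames: int | None = None,
    overlap_fraction: float = 0.5,
) -> CouplingMatrix:
    """Welch coherence averaged over the in-band frequency bins."""
    nyquist = 1.0 / (2.0 * series.tr_s)
    if band[0] >= nyquist:
        raise ValueError(f"band {band} lies above Nyquist {nyquist:.4f} Hz")
    spec = spectral_coherence_spectrum(series, window_frames, overlap_fraction)
    mask = _band_mask(spec.frequencies, band)
    vals = spec.coherence[:, :, mask].mean(axis=-1)
    np.fill_diagonal(vals, np.nan)
    vals = (vals + vals.T) / 2.0
    return CouplingMatrix(series.subject_id, "coh_spectral", vals, symmetric=True)


# ---------------------------------------------------------------------------
# Morlet wavelet coherence
# ---------------------------------------------------------------------------

def morlet_scales(
    n_frames: int,
    tr_s: float,
    band: tuple[float, float],
    omega0: float = 6.0,
    voices_per_octave: int = 12,
) -> np.ndarray:
    """Dyadic scale grid covering (a margin beyond) the requested band."""
    fourier_factor = (4 * np.pi) / (omega0 + np.sqrt(2 + omega0**2))
    s_min = 1.0 / (fourier_factor * band[1]) / 2.0
    s_max = 1.0 / (fourier_factor * band[0]) * 2.0
    s_max = min(s_max, n_frames * tr_s)  # scales longer than the record are useless
    n = int(np.ceil(voices_per_octave * np.log2(s_max / s_min)))
    if n < 2:
        raise ValueError("band and record length leave fewer than 2 wavelet scales")
    return s_min * 2.0 ** (np.arange(n + 1) / voices_per_octave)


def morlet_cwt(
    x: np.ndarray, tr_s: float, scales: np.ndarray, omega0: float = 6.0
) -> np.ndarray:
    """Continuous Morlet wavelet transform via FFT (scales x time)."""
    n = len(x)
    xh = np.fft.fft(x - x.mean())
    omega = 2 * np.pi * np.fft.fftfreq(n, d=tr_s)
    out = np.empty((len(scales), n), dtype=complex)
    for k, s in enumerate(scales):
        # L2-normalized Morlet daughter in the frequency domain
        psi = (np.pi**-0.25) * np.sqrt(2 * np.pi * s / tr_s) * np.exp(
            -0.5 * (s * omega - omega0) ** 2
        ) * (omega > 0)
        out[k] = np.fft.ifft(xh * psi)
    return out


def _smooth(
    w: np.ndarray, scales: np.ndarray, tr_s: float, voices_per_octave: int
) -> np.ndarray:
    """Standard wavelet-coherence smoothing: scale-dependent Gaussian in
    time (circular, via the FFT), then a boxcar over 0.6 of an octave in
    scale."""
    n = w.shape[-1]
    omega = 2 * np.pi * np.fft.fftfreq(n)  # radians per sample
    sigma = scales / tr_s  # Morlet envelope e-folding time, samples
    transfer = np.exp(-0.5 * (sigma[:, None] * omega[None, :]) ** 2)
    out = np.fft.ifft(np.fft.fft(w, axis=-1) * transfer, axis=-1)
    if not np.iscomplexobj(w):
        out = out.real
    width = max(1, int(round(0.6 * voices_per_octave)))
    return ndimage.uniform_filter1d(out, size=width, axis=0, mode="nearest")


def wavelet_coherence_pair(
    x: np.ndarray,
    y: np.ndarray,
    tr_s: float,
    band: tuple[float, float] = DEFAULT_BAND,
    omega0: float = 6.0,
    voices_per_octave: int = 12,
) -> tuple[np.ndarray, np.ndarray]:
    """Time-resolved Morlet wavelet coherence for one pair.

    Returns (frequencies ascending, coherence scales x time reordered to
    match). Without smoothing, wavelet coherence degenerates to 1
    identically; the smoothing here is what makes the estimator
    informative.
    """
    scales = morlet_scales(len(x), tr_s, band, omega0, voices_per_octave)
    wx = morlet_cwt(x, tr_s, scales, omega0)
    wy = morlet_cwt(y, tr_s, scales, omega0)
    inv_s = (1.0 / scales)[:, None]
    sxx = _smooth(inv_s * np.abs(wx) ** 2, scales, tr_s, voices_per_octave)
    syy = _smooth(inv_s * np.abs(wy) ** 2, scales, tr_s, voices_per_octave)
    sxy = _smooth(inv_s * wx * np.conj(wy), scales, tr_s, voices_per_octave)
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(sxy) ** 2 / (sxx.real * syy.real)
    coh = np.clip(np.nan_to_num(coh.real), 0.0, 1.0)
    fourier_factor = (4 * np.pi) / (omega0 + np.sqrt(2 + omega0**2))
    freqs = 1.0 / (fourier_factor * scales)
    order = np.argsort(freqs)
    return freqs[order], coh[order]


def wavelet_coherence_spectrum(
    series: ParcellatedTimeSeries,
    band: tuple[float, float] = DEFAULT_BAND,
    omega0: float = 6.0,
    voices_per_octave: int = 12,
) -> CoherenceSpectrum:
    """Time-averaged Morlet wavelet coherence for all pairs.

    The time-resolved coherence is formed from smoothed auto/cross wavelet
    spectra and then averaged over all time points (cone-of-influence
    included); the scale axis is returned as ascending frequency so the
    result is interchangeable with the Welch spectrum.
    """
    n = series.n_regions
    t = series.n_frames
    scales = morlet_scales(t, series.tr_s, band, omega0, voices_per_octave)
    fourier_factor = (4 * np.pi) / (omega0 + np.sqrt(2 + omega0**2))
    freqs = 1.0 / (fourier_factor * scales)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if in_band.sum() < 2:
        raise ValueError("fewer than 2 wavelet scales map into the band")
    inv_s = (1.0 / scales)[:, None]
    w = np.empty((n, len(scales), t), dtype=complex)
    autos = np.empty((n, len(scales), t))
    for r in range(n):
        w[r] = morlet_cwt(series.data[:, r], series.tr_s, scales, omega0)
        autos[r] = _smooth(
            inv_s * np.abs(w[r]) ** 2, scales, series.tr_s, voices_per_octave
        ).real
    tavg = np.full((n, n, len(scales)), np.nan)
    for i in range(n):
        tavg[i, i] = 1.0
        for j in range(i):
            sxy = _smooth(
                inv_s * w[i] * np.conj(w[j]), scales, series.tr_s, voices_per_octave
            )
            with np.errstate(invalid="ignore", divide="ignore"):
                coh = np.abs(sxy) ** 2 / (autos[i] * autos[j])
            coh = np.clip(np.nan_to_num(coh.real), 0.0, 1.0)
            tavg[i, j] = tavg[j, i] = coh.mean(axis=1)
    order = np.argsort(freqs)
    return CoherenceSpectrum(freqs[order], tavg[:, :, order], "wavelet")


def wavelet_coherence_fc(
    series: ParcellatedTimeSeries,
    band: tuple[float, float] = DEFAULT_BAND,
    morlet_omega0: float = 6.0,
    voices_per_octave: int = 12,
    spectrum: CoherenceSpectrum | None = None,
) -> CouplingMatrix:
    """Morlet wavelet coherence averaged over in-band scales and all times.

    A precomputed ``spectrum`` (from :func:`wavelet_coherence_spectrum`)
    can be passed to share work with the frequency-MI metric.
    """
    if spectrum is None:
        spectrum = wavelet_coherence_spectrum(
            series, band, morlet_omega0, voices_per_octave
        )
    mask = _band_mask(spectrum.frequencies, band)
    vals = spectrum.coherence[:, :, mask].mean(axis=-1)
    np.fill_diagonal(vals, np.nan)
    vals = (vals + vals.T) / 2.0
    return CouplingMatrix(series.subject_id, "coh_wavelet", vals, symmetric=True)


# ---------------------------------------------------------------------------
# frequency-domain mutual information
# ---------------------------------------------------------------------------

def mi_from_coherence(
    frequencies: np.ndarray,
    coherence: np.ndarray,
    band: tuple[float, float] = DEFAULT_BAND,
    signed: bool = False,
) -> float:
    """Normalized MI from a coherence spectrum for one pair.

    delta = (1/2pi) * integral over the band of log(1 - C(Omega)) dOmega
    (trapezoidal rule, Omega = 2*pi*f in rad/s), taken in absolute value so
    phi = 1 - exp(-2*delta) lies in [0, 1). ``signed=True`` keeps the
    verbatim (non-positive) sign convention instead.
    """
    mask = _band_mask(np.asarray(frequencies), band)
    c = np.asarray(coherence, dtype=float)[mask]
    if np.any((c < 0) | (c > 1)):
        raise ValueError("coherence must lie in [0, 1]")
    if np.any(c >= 1.0):
        warnings.warn("coherence of 1 clipped to 1 - 1e-10", stacklevel=2)
        c = np.minimum(c, 1.0 - 1e-10)
    omega = 2 * np.pi * np.asarray(frequencies)[mask]
    delta = np.trapezoid(np.log(1.0 - c), omega) / (2 * np.pi)
    if not signed:
        delta = abs(delta)
    return float(1.0 - np.exp(-2.0 * delta))


def mi_frequency_fc(
    series: ParcellatedTimeSeries,
    band: tuple[float, float] = DEFAULT_BAND,
    method: str = "wavelet",
    signed: bool = False,
    spectrum: CoherenceSpectrum | None = None,
    **kwargs,
) -> CouplingMatrix:
    """Frequency-domain MI for all pairs, from a coherence spectrum.

    ``method="wavelet"`` time-averages the Morlet coherence before the
    band integral (the convention of the source estimator);
    ``method="welch"`` uses the averaged-periodogram spectrum instead. A
    precomputed ``spectrum`` overrides ``method``.
    """
    if spectrum is None:
        if method == "welch":
            spectrum = spectral_coherence_spectrum(series, **kwargs)
        elif method == "wavelet":
            spectrum = wavelet_coherence_spectrum(series, band, **kwargs)
        else:
            raise ValueError("method must be 'welch' or 'wavelet'")
    n = series.n_regions
    vals = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i):
            vals[i, j] = vals[j, i] = mi_from_coherence(
                spectrum.frequencies, spectrum.coherence[i, j], band, signed
            )
    return CouplingMatrix(series.subject_id, "mi_freq", vals, symmetric=True)
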