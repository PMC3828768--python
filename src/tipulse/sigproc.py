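"""Pulsation-strength envelope, dominant-frequency estimation and spectra.

The raw abdominal brightness series r(t) is turned into a pulsation-strength
envelope p(t) by smoothing, differentiating, detrending, full-wave rectifying
and low-pass filtering with a zero-lag triangular kernel.  p(t) is large while
the ventilatory oscillation is present and collapses toward zero while it is
suppressed, which is what every downstream suppression statistic measures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .extraction import BrightnessTrace


class NoPulsationError(ValueError):
    """Raised when no spectral peak rises above the in-band noise floor."""


@dataclass
class PulsationStrength:
    """Nonnegative envelope p(t) marking presence/suppression of pulsation."""

    values: np.ndarray
    fps: float
    t0_s: float = 0.0
    source_region: str = "abdomen"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.values.size) / self.fps


@dataclass
class SpectrumResult:
    frequencies: np.ndarray
    power: np.ndarray
    window_s: tuple[float, float]


def moving_average(x: np.ndarray, length: int) -> np.ndarray:
    """Centered moving average with reflected edges; ``length`` must be odd."""
    if length < 1 or length % 2 == 0:
        raise ValueError("moving-average length must be a positive odd integer")
    if length == 1:
        return np.asarray(x, dtype=float).copy()
    x = np.asarray(x, dtype=float)
    half = length // 2
    padded = np.pad(x, half, mode="reflect")
    kernel = np.full(length, 1.0 / length)
    return np.convolve(padded, kernel, mode="valid")


def triangular_filter(x: np.ndarray, length: int) -> np.ndarray:
    """Zero-lag (centered) triangular filter with unit DC gain."""
    if length < 1:
        raise ValueError("kernel length must be positive")
    x = np.asarray(x, dtype=float)
    if x.size <= length:
        raise ValueError("series shorter than the triangular kernel")
    kernel = signal.windows.triang(length)
    kernel /= kernel.sum()
    half = (length - 1) // 2
    padded = np.pad(x, (half, length - 1 - half), mode="reflect")
    return np.convolve(padded, kernel, mode="valid")


def _first_difference(x: np.ndarray, fps: float) -> np.ndarray:
    """First difference scaled to a rate; leading edge replicated to keep length."""
    dx = np.diff(x) * fps
    return np.concatenate(([dx[0]], dx))


def pulsation_strength(
    r: BrightnessTrace, smooth_len: int = 5, tri_len: int = 29
) -> PulsationStrength:
    """Smooth → differentiate → detrend → rectify → triangular low-pass.

    ``smooth_len`` is the centered moving-average length used to kill pixel
    noise (default 5 samples ≈ 0.17 s at ~30 fps, passing the ≤2 Hz
    ventilation band); ``tri_len`` is the triangular-kernel length in taps.
    """
    if r.values.size <= max(smooth_len, tri_len):
        raise ValueError("trace shorter than the filter kernels")
    x = moving_average(r.values, smooth_len)
    dx = _first_difference(x, r.fps)
    dx = signal.detrend(dx, type="linear")
    rect = np.abs(dx)
    p = triangular_filter(rect, tri_len)
    return PulsationStrength(p, fps=r.fps, t0_s=r.t0_s, source_region=r.region)


def _windowed(r: BrightnessTrace, window: tuple[float, float]) -> np.ndarray:
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window end must exceed start")
    i0 = int(round((t0 - r.t0_s) * r.fps))
    i1 = int(round((t1 - r.t0_s) * r.fps))
    if i0 < 0 or i1 > r.values.size:
        raise ValueError(f"window {window} outside trace span")
    return r.values[i0:i1]


def estimate_frequency(
    r: BrightnessTrace,
    window: tuple[float, float],
    band: tuple[float, float] = (0.3, 3.0),
    min_snr: float = 10.0,
) -> float:
    """Dominant frequency (Hz) of the detrended windowed trace.

    Uses a finely zero-padded periodogram restricted to ``band`` with
    parabolic interpolation around the peak bin.  If the peak does not exceed
    ``min_snr`` times the in-band median power, the window is flagged as
    containing no pulsation (:class:`NoPulsationError`) — the anesthetised
    state, where the oscillation is absent.
    """
    x = _windowed(r, window)
    x = signal.detrend(x, type="linear")
    n = x.size
    nfft = 1 << max(14, int(np.ceil(np.log2(8 * n))))
    freqs, power = signal.periodogram(x, fs=r.fps, nfft=nfft, detrend=False)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        raise ValueError("analysis band empty at this sampling rate")
    pb = power[in_band]
    fb = freqs[in_band]
    k = int(np.argmax(pb))
    floor = float(np.median(pb))
    if floor <= 0 or pb[k] < min_snr * floor:
        raise NoPulsationError(
            f"no spectral peak above {min_snr}x the in-band noise floor"
        )
    # parabolic refinement on the zero-padded grid
    if 0 < k < pb.size - 1:
        denom = pb[k - 1] - 2 * pb[k] + pb[k + 1]
        delta = 0.5 * (pb[k - 1] - pb[k + 1]) / denom if denom != 0 else 0.0
    else:
        delta = 0.0
    df = fb[1] - fb[0]
    return float(fb[k] + delta * df)


def spectrum_compare(
    r: BrightnessTrace,
    win1: tuple[float, float],
    win2: tuple[float, float],
    win_len_s: float = 12.0,
    band: tuple[float, float] = (0.3, 3.0),
) -> tuple[SpectrumResult, SpectrumResult, float]:
    """FFT power spectra of two equal windows plus the band-power ratio.

    Used for the anesthesia comparison: a 12 s window before CO2 application
    versus one during anesthesia.  Returns (spectrum1, spectrum2, ratio of
    band power win1/win2 in ``band``).
    """
    if max(win1[0], win2[0]) < min(win1[1], win2[1]):
        warnings.warn("comparison windows overlap", stacklevel=2)
    results = []
    n = int(round(win_len_s * r.fps))
    for w in (win1, win2):
        i0 = int(round((w[0] - r.t0_s) * r.fps))
        if i0 < 0 or i0 + n > r.values.size:
            raise ValueError(f"window starting at {w[0]} s outside trace span")
        x = signal.detrend(r.values[i0: i0 + n], type="linear")
        freqs, power = signal.periodogram(x, fs=r.fps, detrend=False)
        results.append(SpectrumResult(freqs, power, (w[0], w[0] + win_len_s)))
    s1, s2 = results
    sel = (s1.frequencies >= band[0]) & (s1.frequencies <= band[1])
    p1 = float(s1.power[sel].sum())
    p2 = float(s2.power[sel].sum())
    ratio = p1 / p2 if p2 > 0 else np.inf
    return s1, s2, ratio


def envelope_lowpass(
    x: np.ndarray, fs: float, cutoff: float = 3.0, order: int = 2
) -> np.ndarray:
    """Full-wave rectify then causal Butterworth low-pass: a power envelope.

    Applied forward-only (causal) because it feeds onset thresholding, where a
    zero-phase filter would leak the onset backwards in time.
    """
    if cutoff >= fs / 2:
        raise ValueError("cutoff must be below Nyquist")
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return signal.sosfilt(sos, np.abs(np.asarray(x, dtype=float)))
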