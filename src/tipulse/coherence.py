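"""Coherence between the video-derived pulsation and neuro-muscular activity.

The abdominal ventilatory muscles fire in high-frequency bursts once per
pumping cycle.  The field potential is band-passed to 200–1000 Hz, rectified
and smoothed into a power envelope; both the envelope and the smoothed
brightness trace are resampled to 30 Hz and their magnitude-squared coherence
(MSC) is estimated with Welch's averaged periodogram (Hanning window of 256
points, 128-point overlap, 256-point transform).  A coherence peak at the
pulsation frequency confirms that the camera-detected pumping and the muscle
activity are the same rhythm.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .extraction import BrightnessTrace
from .sigproc import moving_average


@dataclass
class FieldPotentialTrace:
    """Single-channel field potential (volts, arbitrary gain)."""

    values: np.ndarray
    fs: float = 5000.0
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("field potential must be single-channel (1-D)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field potential contains non-finite values")


@dataclass
class CoherenceResult:
    frequencies: np.ndarray
    msc: np.ndarray
    nperseg: int
    noverlap: int
    nfft: int
    fs: float

    @property
    def peak_frequency(self) -> float:
        sel = self.frequencies > 0
        return float(self.frequencies[sel][np.argmax(self.msc[sel])])

    @property
    def peak_coherence(self) -> float:
        return float(self.msc[self.frequencies > 0].max())

    def at_frequency(self, f: float) -> float:
        """MSC at the frequency bin nearest ``f``."""
        return float(self.msc[np.argmin(np.abs(self.frequencies - f))])


def fp_power_envelope(
    fp: FieldPotentialTrace,
    band: tuple[float, float] = (200.0, 1000.0),
    order: int = 2,
    smooth_s: float = 0.05,
) -> np.ndarray:
    """Band-pass, rectify and smooth the field potential into a power envelope.

    ``smooth_s`` is the moving-average window (default 50 ms), long enough to
    merge the individual carrier cycles into a burst envelope while passing
    the ≤2 Hz ventilatory modulation.
    """
    if fp.fs <= 2 * band[1]:
        raise ValueError("sampling rate too low for the requested band")
    sos = signal.butter(order, band, btype="bandpass", fs=fp.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, fp.values)
    n = int(round(smooth_s * fp.fs))
    if n % 2 == 0:
        n += 1
    return moving_average(np.abs(filtered), n)


def resample_to(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Anti-aliased polyphase resampling onto an exact ``fs_out`` grid."""
    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    if frac == 1:
        return np.asarray(x, dtype=float).copy()
    return signal.resample_poly(np.asarray(x, dtype=float), frac.numerator,
                                frac.denominator)


def msc(
    pulsation: BrightnessTrace | np.ndarray,
    envelope: np.ndarray,
    envelope_fs: float,
    pulsation_fs: float | None = None,
    fs_out: float = 30.0,
    nperseg: int = 256,
    noverlap: int = 128,
    nfft: int = 256,
) -> CoherenceResult:
    """Magnitude-squared coherence between pulsation and field-potential power.

    Both series are resampled to ``fs_out`` (30 Hz), truncated to their
    common span, linearly detrended per segment, and fed to Welch's averaged
    periodogram with a Hanning window.  MSC lies in [0, 1] at every
    frequency; the estimator has a bias floor of roughly 1/K for K averaged
    segments on independent inputs.
    """
    if isinstance(pulsation, BrightnessTrace):
        x, fs_x = pulsation.values, pulsation.fps
    else:
        if pulsation_fs is None:
            raise ValueError("pulsation_fs required when passing a bare array")
        x, fs_x = np.asarray(pulsation, dtype=float), pulsation_fs
    x30 = resample_to(x, fs_x, fs_out)
    y30 = resample_to(np.asarray(envelope, dtype=float), envelope_fs, fs_out)
    n = min(x30.size, y30.size)
    if n < nperseg:
        raise ValueError(
            f"overlapping span of {n} samples is shorter than one {nperseg}-point segment"
        )
    x30, y30 = x30[:n], y30[:n]
    if np.std(x30) < 1e-12 or np.std(y30) < 1e-12:
        raise ValueError("constant input series; coherence undefined")
    x30 = signal.detrend(x30, type="linear")
    y30 = signal.detrend(y30, type="linear")
    freqs, cxy = signal.coherence(
        x30, y30, fs=fs_out, window="hann", nperseg=nperseg,
        noverlap=noverlap, nfft=nfft, detrend="linear",
    )
    cxy = np.clip(cxy, 0.0, 1.0)
    return CoherenceResult(freqs, cxy, nperseg, noverlap, nfft, fs_out)
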