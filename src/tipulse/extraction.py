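"""ROI brightness and frame-difference movement traces from grayscale frame stacks.

The abdomen's ventilatory pumping modulates the mean brightness of a fixed
rectangular region of the video frame; that mean is the raw pulsation
surrogate ``r(t)``.  Gross body movements are measured by differencing frames
a few samples apart and averaging the absolute difference over limb/mouth
regions, giving an RMS-normalised movement trace ``m(t)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import detrend as _linear_detrend

REGION_NAMES = (
    "abdomen",
    "control",
    "stimulus",
    "midleg",
    "foreleg",
    "mouth",
    "hindlimb",
)


@dataclass
class FrameStack:
    """A uniformly sampled stack of grayscale frames (frame, row, col)."""

    frames: np.ndarray
    fps: float
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D (frame, row, col) array")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass(frozen=True)
class RegionSpec:
    """Named rectangular ROI, 0-based, half-open: rows [row0, row1), cols [col0, col1)."""

    name: str
    row0: int
    col0: int
    row1: int
    col1: int

    def __post_init__(self) -> None:
        if not (self.row0 < self.row1 and self.col0 < self.col1):
            raise ValueError(f"degenerate region {self.name!r}")
        if min(self.row0, self.col0) < 0:
            raise ValueError(f"negative region bounds for {self.name!r}")

    def validate_within(self, shape: tuple[int, int]) -> None:
        h, w = shape
        if self.row1 > h or self.col1 > w:
            raise ValueError(
                f"region {self.name!r} ({self.row0}:{self.row1}, {self.col0}:{self.col1}) "
                f"exceeds frame shape {shape}"
            )

    def slice(self) -> tuple[slice, slice]:
        return slice(self.row0, self.row1), slice(self.col0, self.col1)

    @property
    def area(self) -> int:
        return (self.row1 - self.row0) * (self.col1 - self.col0)


@dataclass
class BrightnessTrace:
    """Scalar per-frame mean-brightness series r(t) for one region."""

    values: np.ndarray
    fps: float
    t0_s: float = 0.0
    region: str = "abdomen"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be 1-D")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")

    @property
    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.values.size) / self.fps

    @property
    def duration_s(self) -> float:
        return self.values.size / self.fps


@dataclass
class MovementTrace:
    """RMS-normalised frame-difference movement series m(t)."""

    values: np.ndarray
    fps: float
    region: str = "hindlimb"
    t0_s: float = 0.0
    blanked_intervals: list[tuple[float, float]] = field(default_factory=list)
    degenerate: bool = False  # True when the pre-normalisation series had zero RMS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.values.size) / self.fps


def roi_brightness(stack: FrameStack, region: RegionSpec) -> BrightnessTrace:
    """Per-frame arithmetic mean of the pixel values inside ``region``."""
    region.validate_within(stack.shape)
    rs, cs = region.slice()
    values = stack.frames[:, rs, cs].astype(float).mean(axis=(1, 2))
    return BrightnessTrace(values, fps=stack.fps, t0_s=stack.start_time_s, region=region.name)


def movement_trace(
    stack: FrameStack, region: RegionSpec, lag_frames: int = 3
) -> MovementTrace:
    """Mean absolute difference between frame n and frame n+lag over ``region``.

    The raw difference series is linearly detrended and divided by its RMS so
    that movement magnitudes are comparable between recordings.  A constant
    stack (zero RMS) yields an all-zero trace with ``degenerate=True`` rather
    than a division failure.
    """
    region.validate_within(stack.shape)
    if stack.n_frames <= lag_frames:
        raise ValueError("stack shorter than the differencing lag")
    rs, cs = region.slice()
    roi = stack.frames[:, rs, cs].astype(float)
    diff = np.abs(roi[lag_frames:] - roi[:-lag_frames]).mean(axis=(1, 2))
    diff = _linear_detrend(diff)
    rms = float(np.sqrt(np.mean(diff**2)))
    if rms < 1e-12:
        return MovementTrace(
            np.zeros_like(diff), fps=stack.fps, region=region.name,
            t0_s=stack.start_time_s, degenerate=True,
        )
    return MovementTrace(diff / rms, fps=stack.fps, region=region.name,
                         t0_s=stack.start_time_s)


def _merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    merged: list[tuple[float, float]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def blank_after_stimuli(
    m: MovementTrace, onsets_s, window_s: float = 3.0
) -> MovementTrace:
    """Replace a window after each stimulus onset with the series baseline.

    The stimulus object physically occludes regions near the head and the
    startle itself contaminates m(t); the affected samples are replaced by the
    median of the unblanked series.  Overlapping windows are merged.
    """
    onsets = np.atleast_1d(np.asarray(onsets_s, dtype=float))
    if onsets.size == 0:
        return MovementTrace(m.values.copy(), m.fps, m.region, m.t0_s,
                             list(m.blanked_intervals), m.degenerate)
    t_end = m.t0_s + m.values.size / m.fps
    for t in onsets:
        if not (m.t0_s <= t < t_end):
            raise ValueError(f"onset {t} s outside trace span")
    intervals = _merge_intervals([(float(t), float(t) + window_s) for t in onsets])
    mask = np.zeros(m.values.size, dtype=bool)
    for start, end in intervals:
        i0 = max(0, int(np.ceil((start - m.t0_s) * m.fps - 1e-9)))
        i1 = min(m.values.size, int(np.ceil((end - m.t0_s) * m.fps - 1e-9)))
        mask[i0:i1] = True
    baseline = float(np.median(m.values[~mask])) if (~mask).any() else 0.0
    values = m.values.copy()
    values[mask] = baseline
    return MovementTrace(values, m.fps, m.region, m.t0_s,
                         _merge_intervals(list(m.blanked_intervals) + intervals),
                         m.degenerate)


def detect_movements(m: MovementTrace, threshold: float = 5.0) -> list[float]:
    """Times (s) where m(t) exceeds ``threshold``; contiguous runs merge to one event."""
    above = m.values > threshold
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([False], above)).astype(int)) == 1)
    return [float(m.t0_s + i / m.fps) for i in edges]


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=2)
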