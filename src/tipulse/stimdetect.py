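"""Stimulus onset/offset detection from video brightness and audio envelope.

Visual stimuli are a dark physical occluder traversing a dedicated frame
region: its passage darkens then re-brightens the region, so onsets/offsets
are threshold crossings of the smoothed derivative of the region brightness.
Sound stimuli are short claps: the rectified, 3 Hz low-passed audio envelope
is thresholded relative to its baseline level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .extraction import BrightnessTrace
from .sigproc import envelope_lowpass, moving_average


@dataclass
class AudioTrack:
    """Mono audio samples at a fixed sampling rate (48 kHz in the recordings)."""

    values: np.ndarray
    fs: float = 48000.0
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("audio must be mono (1-D)")


@dataclass
class StimulusEvents:
    """Detected stimulus events for one modality."""

    modality: str  # "visual" | "sound"
    onsets_s: np.ndarray
    offsets_s: np.ndarray
    threshold: float = np.nan
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        self.offsets_s = np.asarray(self.offsets_s, dtype=float)
        if self.onsets_s.size and np.any(np.diff(self.onsets_s) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if np.any(self.offsets_s < self.onsets_s):
            raise ValueError("offsets must not precede onsets")

    @property
    def durations_s(self) -> np.ndarray:
        return self.offsets_s - self.onsets_s

    @property
    def n_events(self) -> int:
        return int(self.onsets_s.size)


def detect_visual(
    stim_trace: BrightnessTrace,
    threshold_sd: float = 5.0,
    smooth_len: int = 5,
    polarity: str = "dark",
) -> StimulusEvents:
    """Detect occluder passages in the stimulus-region brightness trace.

    The trace is smoothed and differentiated; an onset is the first sample
    where the derivative falls below −k·sd (the occluder darkening the
    region) and the paired offset is the subsequent rise above +k·sd.  The
    spread sd is a robust (MAD-based) estimate over the whole derivative
    series, so detection is invariant to global brightness offset and gain.
    ``polarity="bright"`` flips the convention for objects brighter than the
    background.
    """
    x = moving_average(stim_trace.values, smooth_len)
    if polarity == "bright":
        x = -x
    elif polarity != "dark":
        raise ValueError("polarity must be 'dark' or 'bright'")
    dx = np.diff(x) * stim_trace.fps
    mad = np.median(np.abs(dx - np.median(dx)))
    sd = 1.4826 * mad
    if sd < 1e-12:
        sd = float(np.std(dx))
    if sd < 1e-12:  # perfectly flat trace
        return StimulusEvents("visual", [], [], threshold=np.nan)
    thr = threshold_sd * sd

    # derivative sample i sits between frames i and i+1; each supra-threshold
    # run is localised by the |dx|-weighted centroid of the surrounding
    # derivative hump (down to half threshold), which marks the centre of the
    # brightness edge unbiased by the centred smoothing — a first-crossing
    # time would sit on the leading skirt, a couple of frames early
    def _centroid(sgn: int, i_lo: int, i_hi: int) -> float:
        j0, j1 = i_lo, i_hi
        while j0 > 0 and sgn * dx[j0 - 1] > thr / 2:
            j0 -= 1
        while j1 < dx.size and sgn * dx[j1] > thr / 2:
            j1 += 1
        w = sgn * dx[j0:j1]
        idx = np.arange(j0, j1)
        return stim_trace.t0_s + (float((idx * w).sum() / w.sum()) + 0.5) / stim_trace.fps

    onsets: list[float] = []
    offsets: list[float] = []
    i, n = 0, dx.size
    while i < n:
        if dx[i] < -thr:
            run0 = i
            while i < n and dx[i] < -thr:
                i += 1
            onset_t = _centroid(-1, run0, i)
            while i < n and not (dx[i] > thr):
                i += 1
            if i >= n:
                warnings.warn("unpaired stimulus onset at recording end dropped",
                              stacklevel=2)
                break
            run0 = i
            while i < n and dx[i] > thr:
                i += 1
            onsets.append(onset_t)
            offsets.append(_centroid(1, run0, i))
        else:
            i += 1
    return StimulusEvents("visual", onsets, offsets, threshold=thr)


def detect_sound(
    audio: AudioTrack,
    threshold_mult: float = 10.0,
    refractory_s: float = 5.0,
    nominal_duration_s: float = 0.36,
    cutoff_hz: float = 3.0,
) -> StimulusEvents:
    """Detect clap onsets from the rectified, low-passed audio envelope.

    Onsets are upward crossings of ``threshold_mult`` times the baseline
    envelope median, with a refractory period suppressing re-triggers on
    reverberation.  Claps carry no measurable offset at this bandwidth, so
    each event is assigned the nominal stimulus duration.
    """
    notes: list[str] = []
    # saturation shows up as repeated full-scale hits, not a lone loud sample
    n_ceiling = int(np.count_nonzero(np.abs(audio.values) >= 0.999))
    if n_ceiling > 5:
        notes.append("clipped audio")
        warnings.warn("audio appears clipped", stacklevel=2)
    env = envelope_lowpass(audio.values, audio.fs, cutoff=cutoff_hz)
    baseline = float(np.median(env))
    if baseline <= 0:
        baseline = max(float(np.mean(env)), 1e-12)
    thr = threshold_mult * baseline
    above = env > thr
    crossings = np.flatnonzero(np.diff(np.concatenate(([False], above)).astype(int)) == 1)
    onsets: list[float] = []
    last = -np.inf
    for i in crossings:
        t = audio.t0_s + i / audio.fs
        if t - last >= refractory_s:
            onsets.append(t)
            last = t
    onsets_arr = np.asarray(onsets)
    return StimulusEvents("sound", onsets_arr, onsets_arr + nominal_duration_s,
                          threshold=thr, notes=notes)
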