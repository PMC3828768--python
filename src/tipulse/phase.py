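"""Phase-locked response-onset detection with a random-trigger permutation null.

The pulsation frequency differs between animals and drifts within a
recording, so stimulus-triggered r(t) windows are first resampled to a common
frequency (the mean of the per-trial frequencies), detrended and smoothed to
give s(t).  While the oscillation is undisturbed, s(t) is well approximated
by the sinusoid estimate ŝ(t) — the scaled derivative of s(t) delayed by a
quarter period — so the deviation d(t) = |s(t) − ŝ(t)| stays near zero and
jumps where the waveform stops being sinusoidal, i.e. at the response onset.

If the response begins at a fixed phase of the ventilatory cycle, averaging
s(t) windows aligned on the detected onsets sums the pre-onset sinusoids in
phase, so the amplitude A_m of the cycle immediately preceding the onset is
large.  The null distribution is built from averages of randomly triggered
windows (one uniform trigger per trial per replicate): the reported
probability is the fraction of null averages whose maximum cycle amplitude
reaches A_m.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal
from scipy.interpolate import CubicSpline

from .extraction import BrightnessTrace
from .sigproc import NoPulsationError, estimate_frequency, moving_average


@dataclass
class PhaseWaveforms:
    """Frequency-normalised triggered waveforms on a common time base.

    ``s`` is (trial x time); ``shat`` and ``d`` are filled in by
    :func:`deviation_waveforms`; ``times`` are seconds relative to the
    trigger; ``i_trigger`` is the index of t = 0.
    """

    s: np.ndarray
    times: np.ndarray
    fps: float
    f_common: float
    per_trial_freq: np.ndarray
    i_trigger: int
    shat: np.ndarray | None = None
    d: np.ndarray | None = None
    onsets_idx: np.ndarray | None = None  # -1 where no onset was found
    excluded: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return int(self.s.shape[0])


@dataclass
class PhaseLockResult:
    average: np.ndarray
    times: np.ndarray
    a_m: float
    null_max: np.ndarray
    probability: float
    n_null: int
    seed: int | None
    n_trials: int
    amplitude_definition: str = "half peak-to-trough of the cycle preceding onset"


def extract_windows(
    r: BrightnessTrace, onsets_s, pre_s: float = 3.3, post_s: float = 25.0
) -> list[np.ndarray]:
    """Raw r(t) windows [-pre_s, +post_s] around each onset (edge trials dropped)."""
    onsets = np.atleast_1d(np.asarray(onsets_s, dtype=float))
    n_pre = int(round(pre_s * r.fps))
    n_post = int(round(post_s * r.fps))
    out = []
    for onset in onsets:
        i_on = int(round((onset - r.t0_s) * r.fps))
        if i_on - n_pre < 0 or i_on + n_post > r.values.size:
            warnings.warn(f"trigger at {onset:.2f} s too close to recording edge",
                          stacklevel=2)
            continue
        out.append(r.values[i_on - n_pre: i_on + n_post].astype(float))
    return out


def frequency_normalize(
    trials: list[np.ndarray],
    fps: float,
    pre_s: float = 3.3,
    smooth_len: int = 5,
) -> PhaseWaveforms:
    """Resample each trial so all share the mean pre-stimulus frequency.

    The per-trial frequency is estimated from the pre-stimulus segment by
    periodogram peak; trials whose segment carries no pulsation are excluded.
    Resampling is linear interpolation of the time axis by the factor
    f_common/f_trial about the trigger; the common grid is truncated to the
    span covered by every trial.  Each resampled trial is then linearly
    detrended and smoothed.
    """
    n_pre = int(round(pre_s * fps))
    freqs, kept, excluded = [], [], []
    for j, x in enumerate(trials):
        x = np.asarray(x, dtype=float)
        if x.size <= n_pre:
            excluded.append((j, "trial shorter than the pre-stimulus segment"))
            continue
        try:
            f_j = estimate_frequency(
                BrightnessTrace(x[:n_pre], fps=fps), (0.0, n_pre / fps)
            )
        except NoPulsationError:
            excluded.append((j, "no pulsation in pre-stimulus segment"))
            continue
        freqs.append(f_j)
        kept.append(x)
    if not kept:
        raise NoPulsationError("no trial has a measurable pre-stimulus frequency")
    freqs_arr = np.asarray(freqs)
    f_common = float(freqs_arr.mean())

    # source time of output sample tau is tau * c_j; output frequency is f_common
    scales = f_common / freqs_arr
    post_lens = np.array([x.size - n_pre for x in kept]) / fps
    tau_min = float(np.max(-pre_s / scales))
    tau_max = float(np.min(post_lens / scales))
    i_lo = int(np.ceil(tau_min * fps))
    i_hi = int(np.floor(tau_max * fps))
    grid = np.arange(i_lo, i_hi) / fps
    i_trigger = -i_lo

    rows = []
    for x, c in zip(kept, scales):
        src_t = np.arange(x.size) / fps - pre_s
        y = np.interp(grid * c, src_t, x)
        y = signal.detrend(y, type="linear")
        rows.append(moving_average(y, smooth_len))
    return PhaseWaveforms(
        s=np.asarray(rows), times=grid, fps=fps, f_common=f_common,
        per_trial_freq=freqs_arr, i_trigger=i_trigger, excluded=excluded,
    )


def sinusoid_estimate(
    s: np.ndarray, fps: float, f_common: float
) -> tuple[np.ndarray, np.ndarray, int]:
    """Sinusoid estimate ŝ of a single trial and the deviation d = |s − ŝ|.

    ŝ is ds/dt scaled by 1/(2π f_common) — the cosine of s — delayed by a
    quarter period so that a pure sinusoid maps exactly onto itself.  Returns
    (ŝ, d, trim) where ``trim`` samples at the start (the filter warm-up) are
    invalid and should be discarded from all three series together.
    """
    if f_common <= 0:
        raise ValueError("f_common must be positive")
    q = fps / (4.0 * f_common)  # quarter period, samples (fractional)
    if q < 2:
        raise ValueError("quarter period below 2 samples; fps too low for f_common")
    s = np.asarray(s, dtype=float)
    ds = np.gradient(s) * fps
    # undo the central-difference attenuation sin(w)/w at the target frequency
    w = 2.0 * np.pi * f_common / fps
    scaled = ds / (2.0 * np.pi * f_common) * (w / np.sin(w))
    idx = np.arange(s.size, dtype=float)
    shat = CubicSpline(idx, scaled)(np.clip(idx - q, 0.0, idx[-1]))
    d = np.abs(s - shat)
    return shat, d, int(np.ceil(q)) + 2


def deviation_waveforms(pw: PhaseWaveforms) -> PhaseWaveforms:
    """Apply :func:`sinusoid_estimate` to every trial, trimming edges identically."""
    shats, ds, trim = [], [], 0
    for row in pw.s:
        shat, d, trim = sinusoid_estimate(row, pw.fps, pw.f_common)
        shats.append(shat)
        ds.append(d)
    sl = slice(trim, None)
    return PhaseWaveforms(
        s=pw.s[:, sl], times=pw.times[sl], fps=pw.fps, f_common=pw.f_common,
        per_trial_freq=pw.per_trial_freq, i_trigger=pw.i_trigger - trim,
        shat=np.asarray(shats)[:, sl], d=np.asarray(ds)[:, sl],
        excluded=list(pw.excluded),
    )


def detect_onset(
    d: np.ndarray,
    i_search_start: int,
    baseline: slice,
    k: float = 4.0,
    sustain: int = 3,
) -> int | None:
    """First index after the stimulus where d(t) rises above its baseline
    mean + k·sd for ``sustain`` consecutive samples; None if absent.

    The deviation is thresholded directly (rather than its sample-to-sample
    increments): a genuine departure from the sinusoid drives d(t) up and
    keeps it up over the rise of the suppression, whereas increments of d are
    single-sample spikes for sharp departures and sub-threshold for gradual
    ones, so no sustained increment crossing exists at either extreme.
    """
    d = np.asarray(d, dtype=float)
    base = d[baseline]
    if base.size < 4:
        raise ValueError("baseline window too short")
    thr = float(base.mean() + k * base.std())
    above = d > thr
    start = max(i_search_start, 0)
    for i in range(start, above.size - sustain + 1):
        if above[i: i + sustain].all():
            return i
    return None


def detect_onsets(
    pw: PhaseWaveforms, k: float = 4.0, sustain: int = 3, search_s: float = 3.0
) -> PhaseWaveforms:
    """Per-trial onset detection on d(t); trials without onsets get index -1.

    The search is confined to ``search_s`` seconds after the stimulus: the
    response begins within a latency plus at most one ventilatory cycle,
    whereas the recovery from suppression — which also bends the waveform
    away from a sinusoid — lies several seconds out and must not be mistaken
    for an onset.
    """
    if pw.d is None:
        pw = deviation_waveforms(pw)
    onsets = np.full(pw.n_trials, -1, dtype=int)
    baseline = slice(0, max(pw.i_trigger - 1, 3))
    i_stop = pw.i_trigger + int(round(search_s * pw.fps))
    for j in range(pw.n_trials):
        idx = detect_onset(pw.d[j][:i_stop], pw.i_trigger, baseline,
                           k=k, sustain=sustain)
        if idx is not None:
            onsets[j] = idx
    pw.onsets_idx = onsets
    return pw


def max_cycle_amplitude(x: np.ndarray, period_samples: int) -> float:
    """Maximum over sliding one-period windows of half the peak-to-trough range."""
    x = np.asarray(x, dtype=float)
    if x.size < period_samples:
        raise ValueError("waveform shorter than one period")
    wins = sliding_window_view(x, period_samples)
    return float((wins.max(axis=1) - wins.min(axis=1)).max() / 2.0)


def _included_trials(
    pw: PhaseWaveforms, triggers: np.ndarray, n_pre: int, n_post: int
) -> np.ndarray:
    nt = pw.s.shape[1]
    ok = (triggers >= n_pre) & (triggers + n_post <= nt) & (triggers >= 0)
    return np.flatnonzero(ok)


def response_triggered_average(
    pw: PhaseWaveforms,
    pre_s: float = 2.0,
    post_s: float = 1.0,
    triggers: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Average s(t) windows centred on each trial's onset; A_m of the average.

    A_m is half the peak-to-trough range of the last full cycle (one period
    of f_common) ending at the onset.  Returns (average, window times, A_m,
    indices of the trials included).
    """
    if triggers is None:
        if pw.onsets_idx is None:
            raise ValueError("run detect_onsets first or pass explicit triggers")
        triggers = pw.onsets_idx
    triggers = np.asarray(triggers, dtype=int)
    n_pre = int(round(pre_s * pw.fps))
    n_post = int(round(post_s * pw.fps))
    include = _included_trials(pw, triggers, n_pre, n_post)
    if include.size < 2:
        raise ValueError("need at least 2 trials with usable onsets")
    offsets = np.arange(-n_pre, n_post)
    avg = pw.s[include[:, None], triggers[include][:, None] + offsets[None, :]].mean(axis=0)
    w_times = offsets / pw.fps
    period = int(round(pw.fps / pw.f_common))
    pre_cycle = avg[n_pre - period: n_pre]
    a_m = float((pre_cycle.max() - pre_cycle.min()) / 2.0)
    return avg, w_times, a_m, include


def random_trigger_null(
    pw: PhaseWaveforms,
    n_null: int = 3000,
    seed: int | None = None,
    pre_s: float = 2.0,
    post_s: float = 1.0,
) -> PhaseLockResult:
    """Exceedance probability of A_m under random triggering.

    Each replicate draws one uniform trigger per trial within that trial's
    valid pre-response span, averages the windows across trials, and records
    the maximum cycle amplitude of the average.  The probability is the
    fraction of replicates reaching A_m.
    """
    avg, w_times, a_m, include = response_triggered_average(pw, pre_s, post_s)
    rng = np.random.default_rng(seed)
    n_pre = int(round(pre_s * pw.fps))
    n_post = int(round(post_s * pw.fps))
    onsets = pw.onsets_idx[include]

    lows = np.full(include.size, n_pre)
    highs = onsets - n_post  # window must stay before the response onset
    usable = highs > lows
    if not usable.all():
        warnings.warn(
            f"{int((~usable).sum())} trial(s) lack a pre-response span for null triggers",
            stacklevel=2,
        )
    rows = include[usable]
    lows, highs = lows[usable], highs[usable]
    if rows.size < 2:
        raise ValueError("fewer than 2 trials with a valid pre-response span")

    offsets = np.arange(-n_pre, n_post)
    period = int(round(pw.fps / pw.f_common))
    acc = np.zeros((n_null, offsets.size))
    for row, lo, hi in zip(rows, lows, highs):
        draws = rng.integers(lo, hi + 1, size=n_null)
        acc += pw.s[row][draws[:, None] + offsets[None, :]]
    acc /= rows.size
    wins = sliding_window_view(acc, period, axis=1)
    null_max = (wins.max(axis=2) - wins.min(axis=2)).max(axis=1) / 2.0
    probability = float(np.mean(null_max >= a_m))
    return PhaseLockResult(
        average=avg, times=w_times, a_m=a_m, null_max=null_max,
        probability=probability, n_null=n_null, seed=seed, n_trials=int(rows.size),
    )


def stimulus_phase_check(
    pw: PhaseWaveforms,
    n_null: int = 3000,
    seed: int | None = None,
    pre_s: float = 2.0,
    post_s: float = 1.0,
) -> tuple[float, float, PhaseLockResult]:
    """Amplitude of the cycle before the *stimulus* onset versus the null.

    If the stimulus itself was not applied at a particular phase, this
    amplitude is unremarkable against the randomly triggered maxima.  Returns
    (amplitude, percentile within the null, null result).
    """
    if pw.n_trials < 2:
        raise ValueError("need at least 2 trials")
    if pw.onsets_idx is None:
        pw = detect_onsets(pw)
    triggers = np.full(pw.n_trials, pw.i_trigger, dtype=int)
    avg, w_times, a_stim, _ = response_triggered_average(
        pw, pre_s, post_s, triggers=triggers
    )
    null = random_trigger_null(pw, n_null=n_null, seed=seed, pre_s=pre_s, post_s=post_s)
    percentile = float(np.mean(null.null_max < a_stim))
    return a_stim, percentile, null
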