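"""Synthetic recordings with planted ground truth for every pipeline stage.

No raw video/audio/electrophysiology is distributed with the package, so the
generator plants the study conditions directly: an oscillatory abdominal
brightness signal whose frequency drifts down over the first four minutes,
multiplicative raised-cosine suppression gates after each stimulus (optionally
beginning at a fixed oscillator phase), an occluder darkening the
stimulus region of the frame, clap bursts on the audio track, a habituating
hind-limb startle blob, and a 200–1000 Hz field-potential carrier whose burst
envelope is locked to the ventilatory cycle.  Every artifact is returned with
the :class:`GroundTruth` that produced it, so each downstream operation is a
parameter-recovery test rather than a smoke test.

Presets encode the observed conditions: ``ti_visual`` (pulsation 1.36 Hz
falling to 0.92 Hz at 240 s, 1.05 s visual stimuli every 30 s, 3.33 s
suppression width, phase-locked onsets), ``ti_sound`` (0.36 s claps, 1.2 s
suppression), ``awake_visual`` (1.09 → 0.78 Hz, 2.16 s stimuli, 4.71 s
suppression) and ``anesthetized`` (zero pulsation amplitude).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal

from .coherence import FieldPotentialTrace
from .extraction import BrightnessTrace, FrameStack, RegionSpec
from .stimdetect import AudioTrack

DEFAULT_STIMULUS_TIMES = (30.0, 60.0, 90.0, 120.0, 150.0, 180.0)

#: hind-limb flick amplitudes in pixels, geometric decay across trials
DEFAULT_STARTLE_AMPS = tuple(10.0 * 0.7**k for k in range(6))

#: rendering window of the startle blob displacement, seconds after stimulus
#: onset (inside the analysis windows 0.4-0.7 s visual / 0.0-0.3 s sound)
STARTLE_RENDER_WINDOW = {"visual": (0.45, 0.65), "sound": (0.05, 0.25)}

PRESETS: dict[str, dict] = {
    "ti_visual": dict(
        modality="visual", f_start=1.36, f_end=0.92,
        stimulus_duration_s=1.05, suppression_fwhm_s=3.33,
        suppression_latency_s=0.5, phase_lock=True,
    ),
    "ti_sound": dict(
        modality="sound", f_start=1.36, f_end=0.92,
        stimulus_duration_s=0.36, suppression_fwhm_s=1.2,
        suppression_latency_s=0.1, phase_lock=False,
    ),
    "awake_visual": dict(
        modality="visual", f_start=1.09, f_end=0.78,
        stimulus_duration_s=2.16, suppression_fwhm_s=4.71,
        suppression_latency_s=0.5, phase_lock=False,
        movement_times_s=(12.0, 47.0, 101.0, 158.0, 221.0, 268.0),
    ),
    "anesthetized": dict(
        modality="visual", f_start=1.36, f_end=0.92, pulsation_amplitude=0.0,
        stimulus_times_s=(), stimulus_duration_s=1.05,
        suppression_fwhm_s=3.33, suppression_latency_s=0.5, phase_lock=False,
        startle_amp_series=(),
    ),
}

#: time (s) by which the frequency drift reaches its floor
DRIFT_END_S = 240.0


def default_rois(frame_shape: tuple[int, int] = (96, 128)) -> dict[str, RegionSpec]:
    """Fixed ROI layout of the rendered frames (rows, cols; half-open)."""
    h, w = frame_shape
    if (h, w) != (96, 128):
        raise ValueError("the built-in ROI layout assumes 96x128 frames")
    return {
        "abdomen": RegionSpec("abdomen", 40, 30, 70, 80),
        "control": RegionSpec("control", 5, 5, 25, 45),
        "stimulus": RegionSpec("stimulus", 5, 90, 25, 120),
        "hindlimb": RegionSpec("hindlimb", 72, 60, 94, 124),
        "midleg": RegionSpec("midleg", 72, 4, 94, 56),
    }


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic recording; see module docstring for presets."""

    state_preset: str = "ti_visual"
    modality: str = "visual"
    fps: float = 29.97
    duration_s: float = 300.0
    f_start: float = 1.36  # Hz at t=0
    f_end: float = 0.92  # Hz at t=240 s; linear drift in between, constant after
    baseline_brightness: float = 128.0  # grey levels
    pulsation_amplitude: float = 10.0  # grey levels
    pixel_noise_sd: float = 2.0  # grey levels, i.i.d. per pixel in frames
    trace_noise_sd: float = 0.5  # grey levels, additive on r(t)
    stimulus_times_s: tuple[float, ...] = DEFAULT_STIMULUS_TIMES
    stimulus_duration_s: float = 1.05
    suppression_fwhm_s: float = 3.33  # planted half-depth width of the gate
    suppression_depth: float = 1.0  # 1 = pulsation fully gated off
    suppression_depth_series: tuple[float, ...] = ()  # optional per-event depths
    suppression_edge_s: float = 0.5  # raised-cosine fall/rise time of the gate
    suppression_latency_s: float = 0.5
    phase_lock: bool = True
    phase_lock_phase: float = float(np.pi)  # radians
    startle_amp_series: tuple[float, ...] = DEFAULT_STARTLE_AMPS  # pixels
    movement_times_s: tuple[float, ...] = ()  # spontaneous limb movements (awake)
    frame_shape: tuple[int, int] = (96, 128)
    occlusion_depth: float = 140.0  # grey levels the occluder darkens the stimulus ROI
    audio_fs: float = 48000.0
    clap_amplitude: float = 0.2
    audio_floor_sd: float = 1e-4
    fp_fs: float = 5000.0
    fp_band: tuple[float, float] = (200.0, 1000.0)
    fp_coupling: float = 1.0  # 0 = envelope independent of the pulsation
    fp_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.duration_s <= 0:
            raise ValueError("fps and duration_s must be positive")
        if self.pulsation_amplitude > 0:
            if not (self.f_start >= self.f_end > 0):
                raise ValueError("need f_start >= f_end > 0 when pulsation is present")
        if not 0 <= self.suppression_depth <= 1:
            raise ValueError("suppression_depth must lie in [0, 1]")
        if not 0 < self.suppression_edge_s <= self.suppression_fwhm_s:
            raise ValueError("suppression edge must be positive and not exceed the width")
        if self.suppression_depth_series and not all(
            0 <= v <= 1 for v in self.suppression_depth_series
        ):
            raise ValueError("per-event suppression depths must lie in [0, 1]")
        if not 0 <= self.fp_coupling <= 1:
            raise ValueError("fp_coupling must lie in [0, 1]")
        times = np.asarray(self.stimulus_times_s, dtype=float)
        if times.size:
            if times.min() < 0 or times.max() >= self.duration_s:
                raise ValueError("stimulus times must lie within [0, duration_s)")
            if np.any(np.diff(np.sort(times)) < 2 * self.suppression_fwhm_s):
                raise ValueError(
                    "stimulus events closer than twice the suppression width"
                )
        if 0 < len(self.startle_amp_series) < len(self.stimulus_times_s):
            raise ValueError("startle_amp_series shorter than the stimulus schedule")

    @classmethod
    def preset(cls, name: str, **overrides) -> "SynthConfig":
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        params = dict(PRESETS[name])
        params.update(overrides)
        return cls(state_preset=name, **params)

    def with_(self, **overrides) -> "SynthConfig":
        return replace(self, **overrides)


@dataclass
class GroundTruth:
    """Planted event times and signals accompanying every generated artifact."""

    stimulus_onsets_s: np.ndarray
    stimulus_offsets_s: np.ndarray
    suppression_onsets_s: np.ndarray
    suppression_onset_phase: np.ndarray  # radians, mod 2*pi
    startle_amplitudes: np.ndarray
    startle_windows_s: list[tuple[float, float]]
    frequency_hz: np.ndarray  # instantaneous frequency per sample
    envelope: np.ndarray  # suppression gate g(t) per sample
    r_clean: np.ndarray  # noise-free planted trace
    phi0: float
    fps: float

    def to_json_dict(self) -> dict:
        return {
            "stimulus_onsets_s": self.stimulus_onsets_s.tolist(),
            "stimulus_offsets_s": self.stimulus_offsets_s.tolist(),
            "suppression_onsets_s": self.suppression_onsets_s.tolist(),
            "suppression_onset_phase": self.suppression_onset_phase.tolist(),
            "startle_amplitudes": self.startle_amplitudes.tolist(),
            "startle_windows_s": [list(w) for w in self.startle_windows_s],
            "phi0": self.phi0,
            "fps": self.fps,
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=1))


def _instantaneous_frequency(cfg: SynthConfig, t: np.ndarray) -> np.ndarray:
    frac = np.clip(t, 0.0, DRIFT_END_S) / DRIFT_END_S
    return cfg.f_start + (cfg.f_end - cfg.f_start) * frac


def _oscillator(cfg: SynthConfig, fs: float):
    """Phase, frequency and suppression gate of the planted oscillator at ``fs``."""
    n = int(round(cfg.duration_s * fs))
    t = np.arange(n) / fs
    f = _instantaneous_frequency(cfg, t)
    phi0 = float(np.random.default_rng(cfg.seed).uniform(0.0, 2 * np.pi))
    # trapezoidal phase integration of 2*pi*f
    incr = np.concatenate(([0.0], 0.5 * (f[1:] + f[:-1]) / fs))
    phi = phi0 + 2 * np.pi * np.cumsum(incr)

    onsets_s, phases, depths = [], [], []
    stim_sorted = np.sort(np.asarray(cfg.stimulus_times_s, dtype=float))
    for k, s in enumerate(stim_sorted):
        i_e = int(np.ceil((s + cfg.suppression_latency_s) * fs))
        if i_e >= n:
            continue
        if cfg.phase_lock:
            w = np.mod(phi[i_e:] - cfg.phase_lock_phase, 2 * np.pi)
            wraps = np.flatnonzero(np.diff(w) < 0)
            if wraps.size == 0:
                continue
            i_on = i_e + int(wraps[0]) + 1
        else:
            i_on = i_e
        onsets_s.append(t[i_on])
        phases.append(float(np.mod(phi[i_on], 2 * np.pi)))
        depths.append(
            cfg.suppression_depth_series[k]
            if cfg.suppression_depth_series
            else cfg.suppression_depth
        )

    # Flat-bottomed gate with raised-cosine edges of duration E: the dip falls
    # over [0, E], sits at full depth over [E, F] and recovers over [F, F+E],
    # so the half-depth crossings sit mid-edge and span exactly F = the FWHM.
    fwhm_ = cfg.suppression_fwhm_s
    edge = cfg.suppression_edge_s
    width = fwhm_ + edge
    onsets_arr = np.asarray(onsets_s)
    if onsets_arr.size > 1 and np.any(np.diff(onsets_arr) < width):
        raise ValueError("suppression events would overlap; space stimuli further apart")
    g = np.ones(n)
    for t_on, depth in zip(onsets_arr, depths):
        sel = (t >= t_on) & (t <= t_on + width)
        u = t[sel] - t_on
        dip = np.where(
            u < edge,
            0.5 * (1.0 - np.cos(np.pi * u / edge)),
            np.where(
                u <= fwhm_,
                1.0,
                0.5 * (1.0 + np.cos(np.pi * (u - fwhm_) / edge)),
            ),
        )
        g[sel] -= depth * dip
    np.clip(g, 0.0, None, out=g)
    return t, f, phi, g, onsets_arr, np.asarray(phases), phi0


def _stimulus_windows(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    onsets = np.sort(np.asarray(cfg.stimulus_times_s, dtype=float))
    return onsets, onsets + cfg.stimulus_duration_s


def _startle_windows(cfg: SynthConfig) -> list[tuple[float, float]]:
    if not cfg.startle_amp_series:
        return []
    w0, w1 = STARTLE_RENDER_WINDOW[cfg.modality]
    onsets, _ = _stimulus_windows(cfg)
    return [(float(s + w0), float(s + w1)) for s in onsets]


def _ground_truth(cfg: SynthConfig, t, f, g, sup_on, sup_phase, phi0, r_clean) -> GroundTruth:
    onsets, offsets = _stimulus_windows(cfg)
    return GroundTruth(
        stimulus_onsets_s=onsets,
        stimulus_offsets_s=offsets,
        suppression_onsets_s=sup_on,
        suppression_onset_phase=sup_phase,
        startle_amplitudes=np.asarray(cfg.startle_amp_series, dtype=float),
        startle_windows_s=_startle_windows(cfg),
        frequency_hz=f,
        envelope=g,
        r_clean=r_clean,
        phi0=phi0,
        fps=cfg.fps,
    )


def generate_trace(cfg: SynthConfig) -> tuple[BrightnessTrace, GroundTruth]:
    """Planted abdominal-brightness series r(t) plus its ground truth.

    r(t) = baseline + amplitude * g(t) * sin(phi(t)) + noise, with phi
    integrating the drifting instantaneous frequency and g(t) the
    raised-cosine suppression gate after each stimulus.
    """
    t, f, phi, g, sup_on, sup_phase, phi0 = _oscillator(cfg, cfg.fps)
    r_clean = cfg.baseline_brightness + cfg.pulsation_amplitude * g * np.sin(phi)
    r = r_clean
    if cfg.trace_noise_sd > 0:
        rng = np.random.default_rng([cfg.seed, 0])
        r = r_clean + rng.normal(0.0, cfg.trace_noise_sd, r_clean.size)
    gt = _ground_truth(cfg, t, f, g, sup_on, sup_phase, phi0, r_clean)
    return BrightnessTrace(r, fps=cfg.fps, region="abdomen"), gt


def _occlusion_level(cfg: SynthConfig, t: np.ndarray) -> np.ndarray:
    """Fractional occlusion of the stimulus region over time (0..1, 50 ms ramps)."""
    ramp = 0.05
    occ = np.zeros_like(t)
    onsets, offsets = _stimulus_windows(cfg)
    for s, e in zip(onsets, offsets):
        occ += np.clip((t - s) / ramp, 0.0, 1.0) - np.clip((t - e) / ramp, 0.0, 1.0)
    return np.clip(occ, 0.0, 1.0)


def generate_frames(cfg: SynthConfig) -> tuple[FrameStack, GroundTruth]:
    """8-bit grayscale frame stack rendering the planted scene.

    The abdomen ROI carries the planted r(t); the stimulus ROI darkens during
    visual-stimulus intervals; the control ROI is constant; a bright blob in
    the hindlimb ROI translates by the trial's startle amplitude during the
    startle window (and in the midleg ROI at the spontaneous movement times).
    Per-pixel Gaussian noise is added everywhere and values are clipped to
    [0, 255].
    """
    trace, gt = generate_trace(cfg)
    h, w = cfg.frame_shape
    rois = default_rois(cfg.frame_shape)
    n = trace.values.size
    t = trace.times

    template = np.full((h, w), 100.0, dtype=np.float32)  # body/background grey
    rs, cs = rois["control"].slice()
    template[rs, cs] = 128.0
    for name in ("hindlimb", "midleg"):
        rs, cs = rois[name].slice()
        template[rs, cs] = 80.0

    stim_level = 200.0 - cfg.occlusion_depth * _occlusion_level(cfg, t)

    # per-frame blob column offsets (pixels)
    blob = 200.0
    blob_h = blob_w = 8
    hind_off = np.zeros(n, dtype=int)
    for (w0, w1), amp in zip(gt.startle_windows_s, gt.startle_amplitudes):
        sel = (t >= w0) & (t < w1)
        hind_off[sel] = int(round(amp))
    mid_off = np.zeros(n, dtype=int)
    for tm in cfg.movement_times_s:
        mid_off[(t >= tm) & (t < tm + 0.3)] = 10

    rng = np.random.default_rng([cfg.seed, 1])
    frames = np.empty((n, h, w), dtype=np.uint8)
    abd = rois["abdomen"].slice()
    stim = rois["stimulus"].slice()
    hind = rois["hindlimb"]
    mid = rois["midleg"]
    chunk = 512
    for i0 in range(0, n, chunk):
        i1 = min(i0 + chunk, n)
        block = np.broadcast_to(template, (i1 - i0, h, w)).copy()
        block[:, abd[0], abd[1]] = trace.values[i0:i1, None, None]
        block[:, stim[0], stim[1]] = stim_level[i0:i1, None, None]
        for j in range(i0, i1):
            r0 = hind.row0 + 6
            c0 = hind.col0 + 4 + hind_off[j]
            block[j - i0, r0: r0 + blob_h, c0: c0 + blob_w] = blob
            r0 = mid.row0 + 6
            c0 = mid.col0 + 6 + mid_off[j]
            block[j - i0, r0: r0 + blob_h, c0: c0 + blob_w] = blob
        if cfg.pixel_noise_sd > 0:
            block += rng.normal(0.0, cfg.pixel_noise_sd, block.shape).astype(np.float32)
        frames[i0:i1] = np.clip(np.rint(block), 0, 255).astype(np.uint8)
    return FrameStack(frames, fps=cfg.fps), gt


def generate_audio(cfg: SynthConfig) -> AudioTrack:
    """48 kHz mono track: near-silence plus a band-limited clap at each stimulus."""
    fs = cfg.audio_fs
    n = int(round(cfg.duration_s * fs))
    rng = np.random.default_rng([cfg.seed, 2])
    track = rng.normal(0.0, cfg.audio_floor_sd, n)
    if cfg.stimulus_times_s:
        sos = signal.butter(4, (1000.0, 8000.0), btype="bandpass", fs=fs, output="sos")
        dn = int(round(cfg.stimulus_duration_s * fs))
        attack = int(round(0.002 * fs))
        release = int(round(0.010 * fs))
        env = np.ones(dn)
        env[:attack] = np.linspace(0.0, 1.0, attack)
        env[-release:] = np.linspace(1.0, 0.0, release)
        for s in cfg.stimulus_times_s:
            i0 = int(round(s * fs))
            if i0 + dn > n:
                continue
            burst = signal.sosfilt(sos, rng.normal(0.0, 1.0, dn))
            burst /= np.sqrt(np.mean(burst**2))
            track[i0: i0 + dn] += cfg.clap_amplitude * env * burst
    return AudioTrack(track, fs=fs)


def generate_field_potential(
    cfg: SynthConfig, trace: BrightnessTrace | None = None
) -> FieldPotentialTrace:
    """5000 Hz field potential: 200-1000 Hz carrier noise burst-modulated by
    the planted ventilatory cycle.

    The ventilatory muscles fire one burst per pumping cycle, so the carrier
    envelope is the half-wave-rectified planted oscillation (gated by the
    suppression envelope), mixed with a constant floor according to
    ``fp_coupling``; broadband noise is added on top.  ``trace`` is accepted
    for interface symmetry and only used to cross-check the duration.
    """
    if trace is not None and abs(trace.duration_s - cfg.duration_s) > 1.0 / cfg.fps:
        raise ValueError("trace duration does not match the configuration")
    _, _, phi, g, _, _, _ = _oscillator(cfg, cfg.fp_fs)
    env = np.maximum(np.sin(phi), 0.0) * g
    mod = cfg.fp_coupling * env + (1.0 - cfg.fp_coupling) / np.pi
    rng = np.random.default_rng([cfg.seed, 3])
    n = env.size
    sos = signal.butter(2, cfg.fp_band, btype="bandpass", fs=cfg.fp_fs, output="sos")
    carrier = signal.sosfiltfilt(sos, rng.normal(0.0, 1.0, n))
    carrier /= np.sqrt(np.mean(carrier**2))
    fp = carrier * mod
    if cfg.fp_noise_sd > 0:
        fp = fp + rng.normal(0.0, cfg.fp_noise_sd, n)
    return FieldPotentialTrace(fp, fs=cfg.fp_fs)
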