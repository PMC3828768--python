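"""Generator correctness: determinism, planted oscillator, round trips."""

import hashlib

import numpy as np
import pytest

from tipulse import (
    SynthConfig,
    generate_audio,
    generate_field_potential,
    generate_frames,
    generate_trace,
    roi_brightness,
)
from scipy.signal import periodogram


def _digest(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def test_identical_seeds_reproduce_identical_artifacts():
    cfg = SynthConfig.preset("ti_visual", seed=11, duration_s=40.0,
                             stimulus_times_s=(12.0,))
    t1, _ = generate_trace(cfg)
    t2, _ = generate_trace(cfg)
    assert _digest(t1.values) == _digest(t2.values)
    f1, _ = generate_frames(cfg)
    f2, _ = generate_frames(cfg)
    assert _digest(f1.frames) == _digest(f2.frames)
    a1 = generate_audio(cfg)
    a2 = generate_audio(cfg)
    assert _digest(a1.values) == _digest(a2.values)
    fp1 = generate_field_potential(cfg)
    fp2 = generate_field_potential(cfg)
    assert _digest(fp1.values) == _digest(fp2.values)
    t3, _ = generate_trace(cfg.with_(seed=12))
    assert _digest(t3.values) != _digest(t1.values)


def test_anesthetized_trace_has_no_oscillatory_power():
    cfg = SynthConfig.preset("anesthetized", seed=5, duration_s=60.0)
    trace, _ = generate_trace(cfg)
    freqs, power = periodogram(trace.values - trace.values.mean(), fs=cfg.fps)
    band = (freqs > 0.3) & (freqs < 3.0)
    # no peak: in-band max comparable to the in-band median (pure noise)
    assert power[band].max() < 20 * np.median(power[band])


def test_planted_oscillator_period_matches_f_start():
    """Zero crossings of the noise-free trace are spaced by half the period."""
    cfg = SynthConfig.preset("ti_visual", seed=7, duration_s=20.0,
                             stimulus_times_s=(), trace_noise_sd=0.0)
    trace, gt = generate_trace(cfg)
    x = trace.values - cfg.baseline_brightness
    crossings = np.flatnonzero(np.diff(np.sign(x)) != 0)
    spacings = np.diff(crossings) / cfg.fps
    expected = 1.0 / (2.0 * cfg.f_start)
    assert abs(np.median(spacings) - expected) < 1.5 / cfg.fps
    np.testing.assert_allclose(trace.values, gt.r_clean)


def test_phase_locked_suppression_starts_at_lock_phase():
    phi_lock = np.pi / 2
    cfg = SynthConfig.preset(
        "ti_visual", seed=9, duration_s=60.0, stimulus_times_s=(20.0,),
        phase_lock=True, phase_lock_phase=phi_lock,
    )
    _, gt = generate_trace(cfg)
    assert gt.suppression_onsets_s.size == 1
    # onset phase equals the lock phase within one sample's phase step
    step = 2 * np.pi * cfg.f_start / cfg.fps
    diff = np.angle(np.exp(1j * (gt.suppression_onset_phase[0] - phi_lock)))
    assert abs(diff) <= 1.5 * step
    assert gt.suppression_onsets_s[0] >= 20.0 + cfg.suppression_latency_s


def test_suppression_gate_half_depth_width_equals_fwhm():
    cfg = SynthConfig.preset("ti_visual", seed=1, duration_s=60.0,
                             stimulus_times_s=(20.0,), phase_lock=False)
    _, gt = generate_trace(cfg)
    t = np.arange(gt.envelope.size) / cfg.fps
    below = gt.envelope < 0.5
    width = (below.sum()) / cfg.fps
    assert abs(width - cfg.suppression_fwhm_s) < 2.5 / cfg.fps
    assert gt.envelope.min() < 1e-9  # dips to ~0 at full depth
    sel = (t < 19.0)
    assert np.all(gt.envelope[sel] == 1.0)


def test_overlapping_suppression_events_rejected():
    with pytest.raises(ValueError):
        SynthConfig.preset("ti_visual", seed=0, duration_s=60.0,
                           stimulus_times_s=(20.0, 22.0))


def test_frames_round_trip_recovers_planted_trace(ti_frames, rois):
    cfg, stack, gt = ti_frames
    trace, _ = generate_trace(cfg)
    extracted = roi_brightness(stack, rois["abdomen"])
    r = np.corrcoef(extracted.values, trace.values)[0, 1]
    assert r > 0.99
    # noise-free frames recover the planted trace to quantisation accuracy
    cfg0 = cfg.with_(pixel_noise_sd=0.0, trace_noise_sd=0.0, duration_s=20.0,
                     stimulus_times_s=())
    stack0, gt0 = generate_frames(cfg0)
    e0 = roi_brightness(stack0, rois["abdomen"])
    assert np.corrcoef(e0.values, gt0.r_clean)[0, 1] > 0.999  # 8-bit quantisation only
    assert np.max(np.abs(e0.values - gt0.r_clean)) < 0.5  # rounding only


def test_control_region_is_flat(ti_frames, rois):
    _, stack, _ = ti_frames
    ctl = roi_brightness(stack, rois["control"])
    assert ctl.values.std() < 0.5  # only pixel noise, beaten down by ROI averaging


def test_stimulus_region_darkens_by_occlusion_depth(ti_frames, rois):
    cfg, stack, gt = ti_frames
    stim = roi_brightness(stack, rois["stimulus"])
    t = stim.times
    on, off = gt.stimulus_onsets_s[0], gt.stimulus_offsets_s[0]
    inside = stim.values[(t > on + 0.2) & (t < off - 0.2)].mean()
    outside = stim.values[t < on - 1.0].mean()
    assert abs((outside - inside) - cfg.occlusion_depth) < 2.0


def test_audio_bursts_at_stimulus_times():
    cfg = SynthConfig.preset("ti_sound", seed=2, duration_s=100.0,
                             stimulus_times_s=(30.0, 60.0))
    audio = generate_audio(cfg)
    n = audio.values.size
    assert n == int(round(100.0 * cfg.audio_fs))
    rms = lambda lo, hi: np.sqrt(np.mean(
        audio.values[int(lo * cfg.audio_fs): int(hi * cfg.audio_fs)] ** 2))
    assert rms(30.0, 30.3) > 100 * rms(20.0, 25.0)
    assert rms(60.0, 60.3) > 100 * rms(20.0, 25.0)
    silent = generate_audio(cfg.with_(stimulus_times_s=()))
    assert np.max(np.abs(silent.values)) < 10 * cfg.audio_floor_sd


def test_field_potential_power_concentrated_in_band():
    cfg = SynthConfig.preset("ti_visual", seed=6, duration_s=60.0,
                             stimulus_times_s=(), fp_noise_sd=0.0)
    fp = generate_field_potential(cfg)
    freqs, power = periodogram(fp.values, fs=cfg.fp_fs)
    in_band = power[(freqs >= 150) & (freqs <= 1100)].sum()
    assert in_band / power.sum() > 0.95  # 2nd-order skirts leak a little power


def test_ground_truth_accompanies_every_artifact(ti_frames):
    cfg, _, gt = ti_frames
    assert gt.stimulus_onsets_s.size == len(cfg.stimulus_times_s)
    assert gt.suppression_onsets_s.size == gt.suppression_onset_phase.size
    assert gt.envelope.size == gt.r_clean.size == gt.frequency_hz.size
    assert len(gt.startle_windows_s) == gt.stimulus_onsets_s.size
    d = gt.to_json_dict()
    assert set(d) >= {"stimulus_onsets_s", "suppression_onsets_s", "phi0"}
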