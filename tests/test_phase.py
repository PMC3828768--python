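"""Frequency normalisation, the sinusoid-deviation identity, onset detection
and the random-trigger null."""

import numpy as np
import pytest

from tipulse import (
    SynthConfig,
    detect_onset,
    detect_onsets,
    deviation_waveforms,
    extract_windows,
    frequency_normalize,
    generate_trace,
    random_trigger_null,
    response_triggered_average,
    sinusoid_estimate,
    stimulus_phase_check,
)
from tipulse.phase import max_cycle_amplitude

FPS = 29.97


def _sine_trials(freqs, duration_s=28.3, amplitude=10.0, phase=0.0):
    t = np.arange(int(duration_s * FPS)) / FPS
    return [amplitude * np.sin(2 * np.pi * f * t + phase) for f in freqs]


def _locked_waveforms(n_animals=4, seed0=100, phase_lock=True):
    trials = []
    for k in range(n_animals):
        cfg = SynthConfig.preset("ti_visual", seed=seed0 + k, phase_lock=phase_lock)
        trace, gt = generate_trace(cfg)
        trials += extract_windows(trace, gt.stimulus_onsets_s)
    return detect_onsets(deviation_waveforms(frequency_normalize(trials, FPS)))


class TestFrequencyNormalize:
    def test_equal_frequency_trials_pass_through(self):
        pw = frequency_normalize(_sine_trials([1.0, 1.0, 1.0]), FPS)
        assert pw.f_common == pytest.approx(1.0, abs=0.02)
        # resampling at unit scale is the identity up to interpolation error
        ref = pw.s[0]
        for row in pw.s[1:]:
            np.testing.assert_allclose(row, ref, atol=0.05)

    def test_two_tones_meet_at_mean_frequency(self):
        """0.8 and 1.2 Hz trials both end up at 1.0 Hz with equal crossings."""
        pw = frequency_normalize(_sine_trials([0.8, 1.2]), FPS)
        assert pw.f_common == pytest.approx(1.0, abs=0.03)
        spacings = []
        for row in pw.s:
            crossings = np.flatnonzero(np.diff(np.sign(row)) != 0)
            spacings.append(np.median(np.diff(crossings)) / FPS)
        assert spacings[0] == pytest.approx(spacings[1], abs=1.5 / FPS)
        assert np.mean(spacings) == pytest.approx(0.5, abs=0.05)

    def test_planted_drift_lands_within_2pct_of_common(self, ti_trace):
        from scipy.signal import periodogram
        _, trace, gt = ti_trace
        pw = frequency_normalize(extract_windows(trace, gt.stimulus_onsets_s), FPS)
        for row in pw.s:
            freqs, power = periodogram(row, fs=FPS, nfft=1 << 14)
            sel = (freqs > 0.3) & (freqs < 3.0)
            peak = freqs[sel][np.argmax(power[sel])]
            assert abs(peak - pw.f_common) / pw.f_common < 0.05

    def test_silent_trial_excluded(self):
        rng = np.random.default_rng(0)
        trials = _sine_trials([1.0, 1.1]) + [rng.normal(0, 0.3, int(28.3 * FPS))]
        pw = frequency_normalize(trials, FPS)
        assert pw.n_trials == 2
        assert len(pw.excluded) == 1


class TestSinusoidEstimate:
    def test_pure_sinusoid_maps_to_itself(self):
        """The defining identity: d(t) vanishes for a pure tone at f_common."""
        t = np.arange(int(40 * FPS)) / FPS
        s = 10.0 * np.sin(2 * np.pi * 1.0 * t + 0.7)
        shat, d, trim = sinusoid_estimate(s, FPS, 1.0)
        assert np.max(d[trim:-2]) < 0.1  # < 1% of the 10-unit amplitude

    def test_step_discontinuity_raises_deviation_locally(self):
        t = np.arange(int(40 * FPS)) / FPS
        s = 10.0 * np.sin(2 * np.pi * t)
        i_step = int(20 * FPS)
        s[i_step:] += 6.0
        _, d, trim = sinusoid_estimate(s, FPS, 1.0)
        near = np.abs(np.arange(s.size) - i_step) < 10
        before = (np.arange(s.size) > trim) & (np.arange(s.size) < i_step - 10)
        assert d[near].max() > 10 * np.median(d[before])

    def test_quarter_period_too_short_rejected(self):
        with pytest.raises(ValueError):
            sinusoid_estimate(np.zeros(100), 4.0, 1.0)


class TestDetectOnset:
    def test_pure_sinusoid_has_no_onset(self):
        t = np.arange(int(30 * FPS)) / FPS
        s = 10.0 * np.sin(2 * np.pi * t)
        _, d, trim = sinusoid_estimate(s, FPS, 1.0)
        d = d[trim:]
        assert detect_onset(d, 99, slice(0, 95)) is None

    def test_planted_gate_edge_found_within_two_samples(self):
        """An abrupt amplitude gate is located to ±2 samples regardless of phase."""
        t = np.arange(int(30 * FPS)) / FPS
        i_gate = int(15 * FPS)
        for phase in np.linspace(0, 2 * np.pi, 8, endpoint=False):
            s = 10.0 * np.sin(2 * np.pi * t + phase)
            s[i_gate:] = 0.0
            _, d, trim = sinusoid_estimate(s, FPS, 1.0)
            onset = detect_onset(d, trim + 5, slice(trim, i_gate - 10))
            assert onset is not None
            assert abs(onset - i_gate) <= 2

    def test_infinite_threshold_finds_nothing(self):
        t = np.arange(int(30 * FPS)) / FPS
        s = 10.0 * np.sin(2 * np.pi * t)
        s[int(15 * FPS):] = 0.0
        _, d, trim = sinusoid_estimate(s, FPS, 1.0)
        assert detect_onset(d, trim + 5, slice(trim, 300), k=1e9) is None

    def test_synthetic_trials_onsets_near_planted(self):
        cfg = SynthConfig.preset("ti_visual", seed=55)
        trace, gt = generate_trace(cfg)
        pw = detect_onsets(deviation_waveforms(
            frequency_normalize(extract_windows(trace, gt.stimulus_onsets_s), FPS)))
        found = pw.onsets_idx >= 0
        assert found.sum() >= 4
        rel_true = gt.suppression_onsets_s - gt.stimulus_onsets_s
        for j in np.flatnonzero(found):
            t_detected = pw.times[pw.onsets_idx[j]]
            # detection fires on the rise of the deviation, within ~0.5 s
            assert -0.1 < t_detected - rel_true[j] < 0.6


class TestPhaseLockNull:
    def test_locked_onsets_give_coherent_preonset_cycle(self):
        pw = _locked_waveforms(n_animals=6)
        avg, times, a_m, include = response_triggered_average(pw)
        assert include.size >= 24  # most of the 36 trials yield a detected onset
        # coherent averaging keeps a large fraction of the single-trial amplitude
        assert a_m > 2.5

    def test_random_phase_onsets_shrink_the_average(self):
        locked = _locked_waveforms(n_animals=4, seed0=100, phase_lock=True)
        unlocked = _locked_waveforms(n_animals=4, seed0=200, phase_lock=False)
        _, _, a_locked, _ = response_triggered_average(locked)
        _, _, a_unlocked, _ = response_triggered_average(unlocked)
        assert a_unlocked < 0.6 * a_locked

    def test_null_probability_extreme_only_when_locked(self):
        locked = _locked_waveforms(n_animals=6, seed0=100, phase_lock=True)
        res = random_trigger_null(locked, n_null=400, seed=3)
        assert res.probability <= 1.0 / 400
        unlocked = _locked_waveforms(n_animals=6, seed0=200, phase_lock=False)
        res0 = random_trigger_null(unlocked, n_null=400, seed=3)
        pct = float(np.mean(res0.null_max < res0.a_m))
        assert 0.05 <= pct <= 0.95

    def test_single_null_replicate_probability_is_zero_or_one(self):
        pw = _locked_waveforms(n_animals=3, seed0=100)
        res = random_trigger_null(pw, n_null=1, seed=9)
        assert res.probability in (0.0, 1.0)

    def test_same_seed_reproduces_null(self):
        pw = _locked_waveforms(n_animals=3, seed0=100)
        r1 = random_trigger_null(pw, n_null=50, seed=21)
        r2 = random_trigger_null(pw, n_null=50, seed=21)
        np.testing.assert_array_equal(r1.null_max, r2.null_max)

    def test_stimulus_not_applied_at_fixed_phase(self):
        pw = _locked_waveforms(n_animals=6, seed0=100)
        a_stim, pct, _ = stimulus_phase_check(pw, n_null=400, seed=17)
        assert 0.05 <= pct <= 0.95


class TestMaxCycleAmplitude:
    def test_pure_tone_amplitude(self):
        t = np.arange(300) / FPS
        x = 4.0 * np.sin(2 * np.pi * 1.0 * t)
        assert max_cycle_amplitude(x, int(FPS / 1.0)) == pytest.approx(4.0, rel=0.02)

    def test_shorter_than_period_rejected(self):
        with pytest.raises(ValueError):
            max_cycle_amplitude(np.zeros(10), 30)
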