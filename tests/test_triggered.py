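"""Triggered windows, medians, suppression statistics, FWHM, habituation, startle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tipulse import (
    PulsationStrength,
    SynthConfig,
    build_triggered,
    fwhm,
    generate_trace,
    habituation_pulsation,
    kruskal_with_posthoc,
    median_waveform,
    period_means,
    pulsation_strength,
    startle_series,
    suppression_test,
)

FPS = 29.97


def _pstrength(values, fps=FPS):
    return PulsationStrength(np.asarray(values, dtype=float), fps=fps)


class TestBuildTriggered:
    def test_constant_envelope_normalises_to_one(self):
        p = _pstrength(np.full(3000, 7.7))
        ts = build_triggered(p, [40.0, 70.0], n_trials=6)
        assert ts.n_trials == 2
        np.testing.assert_allclose(ts.windows, 1.0)
        np.testing.assert_allclose(ts.norms, 7.7)

    def test_edge_trial_excluded(self):
        p = _pstrength(np.full(3000, 1.0))
        with pytest.warns(UserWarning):
            ts = build_triggered(p, [1.0, 50.0])
        assert ts.n_trials == 1
        assert ts.excluded[0][0] == 0

    def test_only_first_n_trials_used(self):
        p = _pstrength(np.full(12000, 1.0))
        onsets = [30.0 + 30.0 * k for k in range(8)]
        ts = build_triggered(p, onsets, n_trials=6)
        assert ts.n_trials == 6

    def test_normalisation_is_idempotent(self, ti_trace):
        _, trace, gt = ti_trace
        p = pulsation_strength(trace)
        ts = build_triggered(p, gt.stimulus_onsets_s)
        renorm = ts.windows / ts.windows[:, ts.times < 0].mean(axis=1, keepdims=True)
        np.testing.assert_allclose(renorm, ts.windows, rtol=1e-12)


class TestMedianWaveform:
    def test_identical_trials_reproduce_any_trial(self):
        p = _pstrength(np.full(3000, 2.0))
        ts = build_triggered(p, [40.0, 70.0])
        np.testing.assert_array_equal(median_waveform(ts), ts.windows[0])

    def test_pointwise_median_of_three(self):
        p = _pstrength(np.full(6000, 1.0))
        ts = build_triggered(p, [40.0, 80.0, 120.0])
        ts.windows = np.array([np.ones(ts.times.size),
                               np.ones(ts.times.size),
                               np.zeros(ts.times.size)])
        assert np.all(median_waveform(ts) == 1.0)

    def test_median_dip_tracks_planted_depth(self, ti_trace):
        cfg, trace, gt = ti_trace
        p = pulsation_strength(trace)
        ts = build_triggered(p, gt.stimulus_onsets_s)
        med = median_waveform(ts)
        planted_floor = 1.0 - cfg.suppression_depth
        assert med.min() < planted_floor + 0.2


class TestFwhm:
    def test_symmetric_v_dip_geometry(self):
        times = np.linspace(-1.0, 3.0, 4001)
        wave = np.ones_like(times)
        sel = (times >= 0) & (times <= 2)
        wave[sel] = np.abs(times[sel] - 1.0)  # V from 1 down to 0 and back
        assert fwhm(wave, times) == pytest.approx(1.0, abs=2e-3)

    def test_flat_waveform_undefined(self):
        times = np.linspace(0, 10, 300)
        with pytest.warns(UserWarning):
            assert np.isnan(fwhm(np.ones(300), times))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(width=st.floats(0.8, 6.0), depth=st.floats(0.3, 1.0), centre=st.floats(3.0, 12.0))
    def test_recovers_raised_cosine_dip_width(self, width, depth, centre):
        """Half-depth width of an analytic raised-cosine dip equals its FWHM."""
        times = np.arange(-3.3, 25.0, 1 / FPS)
        wave = np.ones_like(times)
        u = times - centre
        sel = np.abs(u) <= width
        wave[sel] -= depth * 0.5 * (1 + np.cos(np.pi * u[sel] / width))
        assert fwhm(wave, times) == pytest.approx(width, abs=0.05)

    def test_recovers_planted_suppression_width(self, ti_trace):
        cfg, trace, gt = ti_trace
        p = pulsation_strength(trace)
        ts = build_triggered(p, gt.stimulus_onsets_s)
        assert fwhm(median_waveform(ts), ts.times) == pytest.approx(
            cfg.suppression_fwhm_s, abs=0.3)


def _animal_period_data(preset, seeds, **overrides):
    summaries, trial_means = [], []
    for seed in seeds:
        cfg = SynthConfig.preset(preset, seed=seed, **overrides)
        trace, gt = generate_trace(cfg)
        p = pulsation_strength(trace)
        ts = build_triggered(p, gt.stimulus_onsets_s)
        med = median_waveform(ts)
        summaries.append(period_means(med, ts.times, cfg.modality))
        trial_means.append([
            period_means(ts.windows[k], ts.times, cfg.modality)["response"]
            for k in range(ts.n_trials)
        ])
    return summaries, np.asarray(trial_means)


class TestSuppressionTest:
    def test_identical_periods_not_significant(self):
        flat = [{"pre": 1.0, "response": 1.0, "post": 1.0} for _ in range(8)]
        res = suppression_test(flat)
        assert res.pvalue == pytest.approx(1.0)
        assert res.significant_pairs() == []

    def test_planted_suppression_detected_across_16_animals(self):
        summaries, _ = _animal_period_data("ti_visual", range(1, 17))
        res = suppression_test(summaries)
        assert res.pvalue < 0.001
        sig = res.significant_pairs()
        assert ("pre", "response") in sig and ("response", "post") in sig
        # pre and post sit at the same level up to the planted frequency drift
        pre = np.mean([s["pre"] for s in summaries])
        post = np.mean([s["post"] for s in summaries])
        assert abs(pre - post) < 0.05 * pre

    def test_permuted_labels_give_uniform_pvalues(self):
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(200):
            vals = rng.normal(1.0, 0.05, size=(16, 3))
            groups = {"pre": vals[:, 0], "response": vals[:, 1], "post": vals[:, 2]}
            pvals.append(kruskal_with_posthoc(groups).pvalue)
        # null p-values roughly uniform: median near 0.5, ~5% below 0.05
        assert 0.3 < np.median(pvals) < 0.7

    def test_fewer_than_three_animals_rejected(self):
        with pytest.raises(ValueError):
            suppression_test([{"pre": 1, "response": 0, "post": 1}] * 2)


class TestHabituation:
    def test_constant_planted_depth_not_significant(self):
        _, trial_means = _animal_period_data("ti_visual", range(1, 9))
        res = habituation_pulsation(trial_means)
        assert res.pvalue > 0.05

    def test_decaying_planted_depth_detected(self):
        depths = tuple(0.7**k for k in range(6))
        _, trial_means = _animal_period_data(
            "ti_visual", range(101, 109), suppression_depth_series=depths)
        res = habituation_pulsation(trial_means)
        assert res.pvalue < 0.01

    def test_single_animal_rejected(self):
        with pytest.raises(ValueError):
            habituation_pulsation(np.ones((1, 6)))


class TestStartleSeries:
    def test_constant_amplitudes_not_significant(self):
        rng = np.random.default_rng(11)
        mags = {f"a{k}": 8.0 + rng.normal(0, 0.5, 6) for k in range(6)}
        res = startle_series(mags)
        assert res.trial_pvalue > 0.05
        assert not res.habituated

    def test_decaying_amplitudes_detected_with_trial6_below_trial1(self):
        rng = np.random.default_rng(12)
        decay = 10.0 * 0.7 ** np.arange(6)
        mags = {f"a{k}": decay + rng.normal(0, 0.3, 6) for k in range(6)}
        res = startle_series(mags)
        assert res.trial_pvalue < 0.01
        assert res.habituated

    def test_animal_without_startle_excluded(self):
        rng = np.random.default_rng(13)
        decay = 10.0 * 0.7 ** np.arange(6)
        mags = {f"a{k}": decay + rng.normal(0, 0.3, 6) for k in range(4)}
        mags["quiet"] = np.full(6, 0.2)
        peaks = {k: (30.0 if k != "quiet" else 0.4) for k in mags}
        res = startle_series(mags, peak_amplitudes=peaks)
        assert res.excluded_animals == ["quiet"]
        assert "quiet" not in set(res.table["animal"])
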