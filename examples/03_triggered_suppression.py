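"""Stimulus-triggered suppression: median waveform, period test and FWHM.

Builds baseline-normalised p(t) windows around the first six visual stimuli
for 8 simulated animals, summarises each animal by the pointwise median,
compares pre / response / post periods with a Kruskal-Wallis test and
Tukey-Kramer post hoc comparisons, and reports the response duration as the
full width at half depth of the median dip.
"""

import numpy as np

from tipulse import (
    SynthConfig, build_triggered, fwhm, generate_trace, median_waveform,
    period_means, pulsation_strength, suppression_test,
)

summaries, widths = [], []
for seed in range(1, 9):
    cfg = SynthConfig.preset("ti_visual", seed=seed)
    trace, truth = generate_trace(cfg)
    p = pulsation_strength(trace)
    ts = build_triggered(p, truth.stimulus_onsets_s)
    med = median_waveform(ts)
    summaries.append(period_means(med, ts.times, "visual"))
    widths.append(fwhm(med, ts.times))

res = suppression_test(summaries)
print("period means across animals:")
for name in ("pre", "response", "post"):
    print(f"  {name:9s} {np.mean([s[name] for s in summaries]):.3f}")
print(f"Kruskal-Wallis H = {res.statistic:.1f}, p = {res.pvalue:.2e}")
print(f"significant pairs: {res.significant_pairs()}")
print(f"mean FWHM = {np.mean(widths):.2f} s (planted {cfg.suppression_fwhm_s} s)")
# The response period collapses to ~0.1 of baseline while pre and post stay
# near 1; the recovered suppression duration matches the planted width.
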