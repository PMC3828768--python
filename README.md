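# tipulse

Quantifying stimulus-evoked suppression of insect abdominal pulsation from
behavioral video, audio and neuro-muscular field potentials.

Tonic immobility (TI) is a prolonged, reversible immobile state that
restraint can induce in many animals, including grasshoppers.  Even while
immobile, the animal keeps pumping its abdomen — the ventilatory rhythm —
and that rhythm responds to the outside world: a moving visual stimulus or a
clap transiently shuts the pumping down.  `tipulse` is a library for
measuring this paradigm end to end, for behavioral physiologists working
with video of restrained insects:

- **r(t)** — mean brightness of an abdomen region of interest per frame, the
  surrogate of the ventilatory movement (29.97 fps video);
- **p(t)** — pulsation strength: r(t) smoothed, differentiated, detrended,
  full-wave rectified and low-pass filtered with a zero-lag triangular
  filter (29 taps); large while pumping, near 0 while suppressed;
- stimulus events from the video (occluder darkening a stimulus region) or
  the 48 kHz audio track (rectified, 2nd-order Butterworth low-pass at 3 Hz,
  thresholded);
- stimulus-triggered, baseline-normalised p(t) windows; per-animal pointwise
  medians; Kruskal–Wallis + Tukey–Kramer comparison of pre / response / post
  periods; response duration as full width at half depth (FWHM);
- habituation tests: Kruskal–Wallis over trials for the suppression,
  two-way (animal × trial) ANOVA for the hind-limb startle measured from
  frame-difference movement traces m(t);
- phase-locking of the response onset: stimulus-triggered r(t) windows are
  frequency-normalised to s(t), the deviation d(t) = |s(t) − ŝ(t)| from the
  sinusoid estimate ŝ (scaled, quarter-period-shifted derivative) marks the
  onset, and the amplitude A_m of the cycle preceding the onset is tested
  against 3000 averages of randomly triggered windows;
- magnitude-squared coherence between the pulsation and the 200–1000 Hz
  field-potential power envelope (Welch, Hanning 256 / overlap 128 /
  256-point transform at 30 Hz).

No raw recordings ship with the package.  A synthetic generator
(`tipulse.synthio`) plants all of these phenomena — the drifting oscillation,
phase-locked suppression gates, occluder events, claps, a habituating
startle blob, burst-modulated field potentials — with full ground truth, so
every stage of the pipeline is testable as parameter recovery.

## Worked example

Recover the suppression of pulsation across 8 simulated TI animals
(`examples/03_triggered_suppression.py`):

```bash
$ python examples/03_triggered_suppression.py
period means across animals:
  pre       1.000
  response  0.222
  post      0.969
Kruskal-Wallis H = 20.5, p = 3.57e-05
significant pairs: [('pre', 'response')]
mean FWHM = 3.26 s (planted 3.33 s)
```

Pulsation collapses to ~0.2 of baseline in the response window and recovers
by 20 s; the median-waveform dip width recovers the planted 3.33 s
suppression duration.  The other examples cover frame simulation and ROI
extraction, p(t) and frequency drift, the phase-locked onset test
(`P(null ≥ A_m) = 0.0000` over 3000 random-trigger averages), coherence with
the field potential (MSC ≈ 1.0 at the 0.5 Hz pulsation frequency, bias floor
when uncoupled), and movement/startle habituation.

A thin CLI wraps the end-to-end pipeline:

```bash
tipulse simulate --outdir out/sim --preset ti_visual --seed 1
tipulse run --outdir out/run --preset ti_visual --seed 1
tipulse run --outdir out/rec --frames out/sim/frames.tiff \
    --fp out/sim/field_potential.csv --rois rois.yaml
```

`run` writes tidy CSVs (traces, events, median waveform, coherence curve), a
`report.json` with the headline numbers (pulsation frequency, period means,
FWHM, phase-lock probability, peak coherence), a `manifest.json` echoing
every parameter and seed, and a median ± IQR figure.

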