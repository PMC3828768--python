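# Methods

`tipulse` quantifies the ventilatory abdominal pumping of a restrained
grasshopper from behavioral video and measures how visual and auditory
stimuli suppress it.  This note describes the signal model, every processing
stage with its parameters, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Signal model

The abdomen's dorso-ventral pumping modulates the mean brightness of a fixed
rectangular region of the frame.  The raw surrogate is

    r(t) = mean pixel value of the abdomen ROI, per frame (29.97 fps).

The working model of r(t) is a narrowband oscillation around a slowly
moving baseline:

    r(t) = b + A · g(t) · sin φ(t) + ε(t),      φ̇(t) = 2π f(t),

with instantaneous frequency f(t) drifting from its initial value to a lower
one over the first 240 s (constant after), a multiplicative suppression gate
g(t) ∈ [0, 1] that closes after a stimulus, and measurement noise ε.  The
ventilatory band is taken as 0.3–3 Hz throughout.

## Pulsation strength p(t)

`pulsation_strength` maps r(t) to a nonnegative envelope:

1. centered moving average, `smooth_len` = 5 samples (~0.17 s) — removes
   pixel noise while passing the ≤ 2 Hz band;
2. first difference × fps (leading edge replicated, length preserved) —
   removes the DC baseline and converts to a rate;
3. linear detrend;
4. full-wave rectification;
5. zero-lag (centered) triangular filter, 29 taps, unit DC gain.

For a pure tone A·sin(2πft) this chain converges to A·2πf·(2/π), the mean of
the rectified derivative, so p(t) is proportional to both amplitude and
frequency; all triggered analyses normalise per-trial against a pre-stimulus
baseline, which cancels that scale.  All kernels are centered, so p(t) dips
are aligned with the underlying gate to within a sample.  Edge samples are
computed on reflected padding.

## Frequency estimation and spectra

`estimate_frequency` detrends the requested window and reads the dominant
frequency from a finely zero-padded periodogram (≥ 2^14 points) restricted
to 0.3–3 Hz, with parabolic refinement around the peak bin; the error on
pure tones in 0.5–2 Hz at 30 s windows is below 0.02 Hz.  If the peak does
not exceed 10× the in-band median power, the window is flagged as carrying
no pulsation (`NoPulsationError`) — this is the anesthetised state, where
the in-band maximum of white noise sits around 6× the median.  The
anesthesia comparison itself (`spectrum_compare`) uses plain FFT power
spectra of two 12 s windows plus the ratio of 0.3–3 Hz band power.

## Stimulus detection

Visual: the occluder darkens a dedicated stimulus ROI.  The region trace is
smoothed (same 5-sample average), differentiated, and thresholded at
±5 robust standard deviations (1.4826·MAD of the whole derivative series, so
detection is invariant to brightness offset and gain).  Each event time is
the |derivative|-weighted centroid of its derivative hump (down to half
threshold): the centroid marks the centre of the brightness edge and is
unbiased by the centred smoothing, whereas a first-crossing time sits on the
leading skirt about two frames early.  Onset–offset pairs give per-event
durations; an unpaired onset at the recording end is dropped with a warning.

Sound: the 48 kHz track is rectified and passed through a causal 2nd-order
Butterworth low-pass at 3 Hz (causal because a zero-phase filter would leak
the onset backwards).  Onsets are upward crossings of 10× the envelope
median, with a 5 s refractory period against reverberation; claps carry no
measurable offset at this bandwidth, so events take the nominal 0.36 s
duration.  Saturation is flagged when repeated full-scale samples occur.

## Triggered analysis

Windows of p(t) spanning −3.3 s to +25 s around each of the first six
stimulus onsets are normalised by the mean of their own first 3.3 s (the
baseline pulsation strength); trials whose window leaves the recording or
whose baseline is not positive are excluded and logged.  Each animal is
summarised by the pointwise median across trials — the response distribution
is bimodal (pulsation present or suppressed), so the mean is not
representative.

Period statistics use fixed windows relative to onset: pre (−3.3, −2.3] s,
response 1.2–2.2 s (visual) or 0.2–1.2 s (sound), post 20–21 s.  Across
animals the three periods are compared with a Kruskal–Wallis omnibus test
followed by Tukey–Kramer comparisons on mean ranks (tie-corrected variance,
studentized-range reference with infinite degrees of freedom, α = 0.05).
Habituation of the suppression is a Kruskal–Wallis test across trial index
of the per-animal response-period means.

Response duration is the full width at half depth of the median dip: the
crossing level sits halfway between the normalised baseline (1) and the
waveform minimum, crossings are linearly interpolated, and a waveform that
never dips below baseline returns NaN with a warning.  "Half depth" is used
rather than "half of the minimum value" because the latter level is
unreachable for a dip that starts at baseline.  Because the measured dip is
an affine map of the planted gate (rectified noise lifts the floor
uniformly), the half-depth width is insensitive to the noise floor; the only
bias is the ~0.5 s filter support, which widens recovered widths by well
under 0.1 s.

The startle is the mean of the hind-limb movement trace m(t) in 0.4–0.7 s
(visual) or 0.0–0.3 s (sound) after onset.  m(t) is the mean absolute
difference between frames n and n+3 over the region, linearly detrended and
divided by its RMS; a 3 s window after each visual onset is replaced by the
series median before movement analysis, because the occluder passes near the
head and the startle itself contaminates the trace.  Movement events are
supra-threshold (> 5 units) runs.  Startle habituation is a two-way
(animal × trial) ANOVA; only animals whose m(t) exceeds the movement
threshold in at least one startle window are included.

## Phase-locked onset detection

Per-trial frequency is estimated from the 3.3 s pre-stimulus segment; trials
flagged as non-pulsating are excluded.  Each stimulus-triggered r(t) window
is resampled (linear interpolation about the trigger) by f_common/f_trial,
where f_common is the mean of the per-trial frequencies; the common grid is
truncated to the span covered by every trial, then each trial is detrended
and smoothed, giving s(t).

The sinusoid estimate ŝ(t) is the derivative of s(t) scaled by
1/(2π f_common) — corrected for the central-difference attenuation
sin(ω)/ω at the target frequency — and delayed by an exact quarter period
via cubic-spline interpolation.  For a pure tone at f_common the identity
ŝ = s holds to < 0.1 % of amplitude, so the deviation d(t) = |s − ŝ| is a
specific detector of departures from sinusoidal pumping.

The onset is the first index after the stimulus where d(t) exceeds its
pre-stimulus mean + 4 sd for 3 consecutive samples, searched only within 3 s
of the stimulus: the response begins within the latency plus at most one
cycle, whereas the *recovery* from suppression — which also bends the
waveform — lies several seconds out and must not be mistaken for an onset.
Thresholding d(t) directly (rather than its increments) is the only version
that fires both on abrupt departures (single-sample increment spikes can
never sustain a crossing) and on smooth ones (whose increments stay inside
any reasonable band).

The phase-lock statistic A_m is half the peak-to-trough range of the last
full cycle of the onset-triggered average ending at the onset (window
−2 s…+1 s).  The null repeats 3000 times: one uniformly random trigger per
trial within that trial's pre-response span, average the windows, record the
maximum sliding one-cycle amplitude of the average.  The reported
probability is the fraction of null maxima reaching A_m.  Triggering on the
stimulus instead of the response onset, with the same null, checks that the
stimulus itself was not phase-locked.

## Coherence with the field potential

The 5000 Hz field potential is band-passed to 200–1000 Hz (2nd-order
Butterworth, zero-phase), rectified, and smoothed with a 50 ms moving
average into a power envelope — long enough to merge carrier cycles, short
enough to pass the ventilatory modulation.  Envelope and smoothed r(t) are
both resampled to exactly 30 Hz by anti-aliased polyphase resampling
(29.97 fps → 30 Hz is the rational factor 1000/999), truncated to their
common span, linearly detrended, and compared with Welch magnitude-squared
coherence: Hanning window of 256 points, 128-point overlap, 256-point
transform.  MSC is clipped to [0, 1]; on independent inputs the estimator
sits at its bias floor of roughly 1/K for K averaged segments.

## The synthetic generator

`synthio` plants the study conditions directly, so every downstream stage is
a parameter-recovery test.  Presets (each with per-seed random initial
oscillator phase, which is what decorrelates stimulus phases across
animals):

| preset        | f(0) → f(240 s) Hz | stimulus | duration | suppression FWHM | phase lock |
|---------------|--------------------|----------|----------|------------------|------------|
| ti_visual     | 1.36 → 0.92        | occluder | 1.05 s   | 3.33 s           | yes (φ = π)|
| ti_sound      | 1.36 → 0.92        | clap     | 0.36 s   | 1.2 s            | no         |
| awake_visual  | 1.09 → 0.78        | occluder | 2.16 s   | 4.71 s           | no         |
| anesthetized  | amplitude 0        | —        | —        | —                | —          |

Stimuli repeat every 30 s from t = 30 s.  Defaults chosen once as realistic
8-bit-video conditions: baseline 128 grey levels, pulsation amplitude 10,
trace noise sd 0.5, per-pixel noise sd 2.0, occluder depth 140 grey levels
with 50 ms ramps, suppression latency 0.5 s (visual) / 0.1 s (sound).

The suppression gate is flat-bottomed with raised-cosine edges: it falls
over `suppression_edge_s` (default 0.5 s), sits at full depth, and recovers
over the same edge, so the half-depth crossings span exactly the configured
FWHM.  A smooth-edged but flat gate matches how the real pulsation behaves —
it stops within about a cycle and stays suppressed — and makes both FWHM
recovery and onset detection well-posed; a gate that is one long raised
cosine would fade the oscillation so gradually that no onset is detectable
even in principle.  With `phase_lock` the gate begins at the first crossing
of the lock phase after stimulus onset + latency.  Per-event depths
(`suppression_depth_series`) allow planting habituation of the suppression.

Frames (default 96×128, a scaled-down stand-in for the 720×480 recordings)
render the trace into the abdomen ROI, a constant control ROI, the darkening
stimulus ROI, and bright 8×8 blobs in the hind-limb and midleg ROIs that
translate by the trial's startle amplitude (default geometric decay, ratio
0.7 from 10 px) during the startle window, or at configured spontaneous
movement times for the awake preset.  Audio is a near-silent 48 kHz track
with band-limited (1–8 kHz) noise bursts at each stimulus.  The field
potential is 200–1000 Hz carrier noise whose envelope is the half-wave
rectified planted cycle times the gate: half-wave, because the muscles burst
once per pumping cycle — a full-wave envelope would oscillate at twice the
pulsation frequency and move the coherence peak away from it.

What the generator does **not** emulate: body translation and rotation,
lighting drift, occluder shadows on the animal, non-sinusoidal pumping
waveforms, inter-animal variability of pulsation frequency and amplitude,
and electrode artifacts.  Passing tests therefore demonstrate that the
analysis chain recovers its parameters under the stated signal model, not
that it is robust to every nuisance of real video.

## Numerical choices and degenerate inputs

- All moving-average/triangular kernels are odd-length, centered, unit-DC,
  applied on reflected padding.
- Zero-RMS movement regions return an all-zero flagged trace, not an error.
- Constant inputs to coherence raise; spans shorter than one Welch segment
  raise.
- Trials with incomplete baselines or windows leaving the recording are
  excluded and logged, never silently truncated.
- Random draws all come from `numpy.random.default_rng` seeded explicitly;
  identical (config, seed) pairs reproduce byte-identical artifacts, and the
  null's seed is recorded in its result object.

## Problem sizes

The test suite and the reproduction script use the study's group sizes
(16 / 9 / 5 animals for the suppression-duration recoveries, 14 animals ×
6 trials with 3000 null averages for the phase test, 300 s recordings at
29.97 fps) — these run in seconds to a couple of minutes.  Frame-stack
fixtures use shortened schedules (3 stimuli, 130–210 s) where full-length
video adds nothing to the property under test.

## Known limitations

- The onset detector has a small positive latency (a few samples) on noisy
  realistic trials because the deviation must clear the 4σ band; the bias is
  common across trials and leaves phase relationships intact.
- FWHM of the median waveform mildly widens (< 0.1 s) from filter support
  and narrows when trial-to-trial onset jitter (phase locking) misaligns
  dips; both effects sit well inside the ±0.3 s recovery tolerance.
- The Kruskal–Wallis post hoc comparison can flag the small but perfectly
  consistent pre-vs-post difference induced by the planted frequency drift
  when many animals share identical drift; real animals vary.
- Real-video container decoding (MP4/AVC) is out of scope; any reader that
  produces a `FrameStack` can feed the pipeline.
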