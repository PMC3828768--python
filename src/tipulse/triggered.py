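"""Stimulus-triggered analysis of the pulsation-strength envelope.

Windows of p(t) around each stimulus onset are normalised to their own
pre-stimulus baseline, summarised by a pointwise median per animal, and
compared across pre / response / post periods with a Kruskal-Wallis test and
Tukey-Kramer post hoc comparisons on rank sums.  Response duration is the
full width at half depth of the median suppression dip; habituation is tested
across the first six trials; the hind-limb startle is quantified from the
movement trace and tested with a two-way (animal x trial) ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import studentized_range

from .extraction import MovementTrace
from .sigproc import PulsationStrength
from .stimdetect import StimulusEvents

#: period windows, seconds relative to stimulus onset
PRE_PERIOD = (-3.3, -2.3)
RESPONSE_PERIOD = {"visual": (1.2, 2.2), "sound": (0.2, 1.2)}
POST_PERIOD = (20.0, 21.0)

#: startle-magnitude windows, seconds after stimulus onset
STARTLE_WINDOW = {"visual": (0.4, 0.7), "sound": (0.0, 0.3)}


@dataclass
class TriggeredSet:
    """Baseline-normalised p(t) windows aligned to stimulus onsets (trial x time)."""

    windows: np.ndarray
    times: np.ndarray  # seconds relative to trigger
    norms: np.ndarray  # per-trial baseline means (pre-normalisation)
    trigger_times_s: np.ndarray
    animal: str = ""
    excluded: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return int(self.windows.shape[0])


@dataclass
class KruskalResult:
    statistic: float
    pvalue: float
    group_labels: tuple[str, ...] = ()
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)

    def significant_pairs(self, alpha: float = 0.05) -> list[tuple[str, str]]:
        return [pair for pair, p in self.pairwise.items() if p < alpha]


@dataclass
class StartleSeries:
    """Per-animal, per-trial startle magnitudes and the habituation ANOVA."""

    table: pd.DataFrame  # columns: animal, trial, magnitude
    trial_pvalue: float
    animal_pvalue: float
    trial_means: pd.Series
    excluded_animals: list[str] = field(default_factory=list)

    @property
    def habituated(self) -> bool:
        return bool(
            self.trial_pvalue < 0.05
            and self.trial_means.iloc[-1] < self.trial_means.iloc[0]
        )


def build_triggered(
    p: PulsationStrength,
    events: StimulusEvents | np.ndarray,
    n_trials: int = 6,
    pre_s: float = 3.3,
    post_s: float = 25.0,
    animal: str = "",
) -> TriggeredSet:
    """Extract and baseline-normalise windows around the first ``n_trials`` onsets.

    Each window spans [-pre_s, +post_s] around its onset and is divided by
    the mean of its first ``pre_s`` seconds (the baseline pulsation
    strength).  Trials whose window leaves the recording, or whose baseline
    mean is not positive, are excluded and logged.
    """
    onsets = np.asarray(
        events.onsets_s if isinstance(events, StimulusEvents) else events, dtype=float
    )[:n_trials]
    if onsets.size == 0:
        raise ValueError("no usable stimulus events")
    n_pre = int(round(pre_s * p.fps))
    n_post = int(round(post_s * p.fps))
    times = (np.arange(n_pre + n_post) - n_pre) / p.fps
    base_sel = times < 0

    rows, norms, kept, excluded = [], [], [], []
    for k, onset in enumerate(onsets):
        i_on = int(round((onset - p.t0_s) * p.fps))
        i0, i1 = i_on - n_pre, i_on + n_post
        if i0 < 0 or i1 > p.values.size:
            excluded.append((k, "window outside recording"))
            continue
        w = p.values[i0:i1].astype(float)
        base = float(w[base_sel].mean())
        if base <= 0:
            excluded.append((k, "non-positive baseline"))
            continue
        rows.append(w / base)
        norms.append(base)
        kept.append(onset)
    for k, reason in excluded:
        warnings.warn(f"trial {k} excluded: {reason}", stacklevel=2)
    windows = np.asarray(rows) if rows else np.empty((0, times.size))
    return TriggeredSet(windows, times, np.asarray(norms), np.asarray(kept),
                        animal=animal, excluded=excluded)


def median_waveform(ts: TriggeredSet) -> np.ndarray:
    """Pointwise median across trials (the response distribution is bimodal:
    pulsation present or suppressed, so the mean is not representative)."""
    if ts.n_trials < 2:
        raise ValueError("median waveform needs at least 2 trials")
    return np.median(ts.windows, axis=0)


def period_means(
    waveform: np.ndarray, times: np.ndarray, modality: str = "visual"
) -> dict[str, float]:
    """Mean of the waveform over the pre, response and post periods."""
    if modality not in RESPONSE_PERIOD:
        raise ValueError("modality must be 'visual' or 'sound'")
    out = {}
    for name, (t0, t1) in (
        ("pre", PRE_PERIOD),
        ("response", RESPONSE_PERIOD[modality]),
        ("post", POST_PERIOD),
    ):
        sel = (times > t0) & (times <= t1)
        if not sel.any():
            raise ValueError(f"{name} period {t0}-{t1} s outside window")
        out[name] = float(waveform[sel].mean())
    return out


def _tukey_kramer_on_ranks(groups: list[np.ndarray]) -> dict[tuple[int, int], float]:
    """Pairwise comparison of mean ranks with Tukey-Kramer (studentized range)
    adjustment, as applied after a Kruskal-Wallis omnibus test."""
    k = len(groups)
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)  # midpoint ranks for ties
    # tie-corrected variance of ranks
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    var = (n_total * (n_total + 1) / 12.0) * (1.0 - tie_term / (n_total**3 - n_total))
    mean_ranks, sizes, idx = [], [], 0
    for g in groups:
        mean_ranks.append(float(ranks[idx: idx + g.size].mean()))
        sizes.append(g.size)
        idx += g.size
    pvals: dict[tuple[int, int], float] = {}
    for i, j in combinations(range(k), 2):
        se = np.sqrt(var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0:
            pvals[(i, j)] = 1.0
            continue
        q = abs(mean_ranks[i] - mean_ranks[j]) / se * np.sqrt(2.0)
        pvals[(i, j)] = float(studentized_range.sf(q, k, np.inf))
    return pvals


def kruskal_with_posthoc(
    groups: dict[str, np.ndarray] | list[np.ndarray],
    labels: tuple[str, ...] | None = None,
) -> KruskalResult:
    """Kruskal-Wallis omnibus test plus Tukey-Kramer post hoc on rank sums."""
    if isinstance(groups, dict):
        labels = tuple(groups.keys())
        arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        arrays = [np.asarray(v, dtype=float) for v in groups]
        labels = labels or tuple(f"g{i}" for i in range(len(arrays)))
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if all(np.allclose(a, arrays[0][0]) for a in arrays):
        # identical constant groups: no evidence of any difference
        return KruskalResult(0.0, 1.0, labels,
                             {(a, b): 1.0 for a, b in combinations(labels, 2)})
    h, p = stats.kruskal(*arrays)
    raw = _tukey_kramer_on_ranks(arrays)
    pairwise = {(labels[i], labels[j]): v for (i, j), v in raw.items()}
    return KruskalResult(float(h), float(p), labels, pairwise)


def suppression_test(
    summaries: list[dict[str, float]],
) -> KruskalResult:
    """Across-animal test that the response period differs from pre and post.

    ``summaries`` holds one pre/response/post period-mean dict per animal
    (from that animal's median triggered waveform).
    """
    if len(summaries) < 3:
        raise ValueError("need period means from at least 3 animals")
    groups = {
        name: np.array([s[name] for s in summaries]) for name in ("pre", "response", "post")
    }
    return kruskal_with_posthoc(groups)


def fwhm(waveform: np.ndarray, times: np.ndarray, baseline: float = 1.0) -> float:
    """Full width at half depth of the suppression dip, in seconds.

    The crossing level is halfway between the (normalised) baseline and the
    waveform minimum; the width runs from the last crossing before the
    minimum to the first crossing after it, with linear interpolation between
    samples.  Returns NaN when the waveform never dips below baseline.
    """
    waveform = np.asarray(waveform, dtype=float)
    i_min = int(np.argmin(waveform))
    v_min = waveform[i_min]
    if v_min >= baseline:
        warnings.warn("no suppression dip below baseline; FWHM undefined", stacklevel=2)
        return float("nan")
    level = baseline - (baseline - v_min) / 2.0

    def _cross(i0: int, i1: int) -> float:
        # linear interpolation of the crossing time between samples i0, i1
        v0, v1 = waveform[i0], waveform[i1]
        frac = (level - v0) / (v1 - v0)
        return float(times[i0] + frac * (times[i1] - times[i0]))

    left = waveform[: i_min + 1]
    above_l = np.flatnonzero(left > level)
    right = waveform[i_min:]
    above_r = np.flatnonzero(right > level)
    if above_l.size == 0 or above_r.size == 0:
        warnings.warn("suppression dip does not recover within the window", stacklevel=2)
        return float("nan")
    i_left = int(above_l[-1])
    i_right = i_min + int(above_r[0])
    return _cross(i_right - 1, i_right) - _cross(i_left, i_left + 1)


def habituation_pulsation(trial_means: np.ndarray) -> KruskalResult:
    """Kruskal-Wallis across trial index of per-animal response-period means.

    ``trial_means`` is (animals x trials); rows with missing (NaN) trials are
    excluded.  A non-significant result means the suppression magnitude does
    not habituate over the repeated stimuli.
    """
    trial_means = np.asarray(trial_means, dtype=float)
    if trial_means.ndim != 2:
        raise ValueError("trial_means must be (animals x trials)")
    ok = ~np.isnan(trial_means).any(axis=1)
    trial_means = trial_means[ok]
    if trial_means.shape[0] < 2:
        raise ValueError("need at least 2 animals with complete trials")
    groups = [trial_means[:, j] for j in range(trial_means.shape[1])]
    labels = tuple(f"trial{j + 1}" for j in range(len(groups)))
    return kruskal_with_posthoc(groups, labels)


def startle_magnitudes(
    m: MovementTrace,
    events: StimulusEvents | np.ndarray,
    modality: str = "visual",
    n_trials: int = 6,
) -> np.ndarray:
    """Per-trial mean of m(t) inside the modality-specific startle window."""
    if modality not in STARTLE_WINDOW:
        raise ValueError("modality must be 'visual' or 'sound'")
    w0, w1 = STARTLE_WINDOW[modality]
    onsets = np.asarray(
        events.onsets_s if isinstance(events, StimulusEvents) else events, dtype=float
    )[:n_trials]
    out = np.full(onsets.size, np.nan)
    for k, onset in enumerate(onsets):
        i0 = int(round((onset + w0 - m.t0_s) * m.fps))
        i1 = int(round((onset + w1 - m.t0_s) * m.fps))
        if i0 < 0 or i1 > m.values.size or i1 <= i0:
            continue
        out[k] = float(m.values[i0:i1].mean())
    return out


def startle_series(
    magnitudes: dict[str, np.ndarray],
    peak_amplitudes: dict[str, float] | None = None,
    startle_threshold: float = 5.0,
) -> StartleSeries:
    """Two-way (animal x trial) ANOVA of startle magnitude across trials.

    ``magnitudes`` maps animal label -> per-trial startle magnitudes.  Only
    animals that showed a startle to at least one trial are included: when
    ``peak_amplitudes`` (animal -> max m(t) within any startle window) is
    given, animals whose peak never exceeds ``startle_threshold`` are
    excluded.  A significant trial effect with later trials below trial 1 is
    habituation.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    excluded = []
    rows = []
    for animal, mags in magnitudes.items():
        if peak_amplitudes is not None and peak_amplitudes.get(animal, np.inf) <= startle_threshold:
            excluded.append(animal)
            continue
        for trial, mag in enumerate(np.asarray(mags, dtype=float), start=1):
            if np.isfinite(mag):
                rows.append({"animal": animal, "trial": trial, "magnitude": mag})
    table = pd.DataFrame(rows)
    if table.empty or table["animal"].nunique() < 2 or table["trial"].nunique() < 2:
        raise ValueError("need at least 2 animals and 2 trials after exclusion")
    model = ols("magnitude ~ C(animal) + C(trial)", data=table).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    trial_means = table.groupby("trial")["magnitude"].mean()
    return StartleSeries(
        table=table,
        trial_pvalue=float(anova.loc["C(trial)", "PR(>F)"]),
        animal_pvalue=float(anova.loc["C(animal)", "PR(>F)"]),
        trial_means=trial_means,
        excluded_animals=excluded,
    )
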