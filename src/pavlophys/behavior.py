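"""Licking behavior: detection, power analysis, and learning criteria.

Anticipatory licking (between cue onset and the jittered US delivery) is
compared against licking in a duration-matched window taken from the
inter-trial interval immediately preceding each cue.  Learning is assessed
per session: during acquisition via a paired t-test of anticipatory vs ITI
lick counts, during discrimination via a two-sample t-test of per-trial
difference scores (anticipatory minus ITI) between reward and punishment
trials, over first-20 / last-20 / random-20 trial subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import spike_counts_in_windows

__all__ = [
    "detect_licks",
    "per_trial_lick_counts",
    "bootstrap_power",
    "assess_learning",
    "classify_trial_outcomes",
    "LearningOutcome",
    "PowerCurve",
]


@dataclass
class PowerCurve:
    trial_counts: np.ndarray
    power: np.ndarray
    n_iterations: int
    alpha: float


@dataclass
class LearningOutcome:
    mode: str  # "acquisition" or "discrimination"
    subset_p: dict[str, float]
    subset_pass: dict[str, bool]
    anticipatory_response_rate: float
    learned: bool
    alpha: float = 0.01
    random_subset_seed: int | None = None


def detect_licks(voltage: np.ndarray, fs_hz: float, threshold: float,
                 refractory_s: float = 0.030) -> np.ndarray:
    """Lick events from an IR beam-break voltage trace.

    One event per downward threshold crossing (voltage drops below the
    threshold); crossings closer than ``refractory_s`` are merged, which
    removes sensor chatter without masking real licks (mouse licking tops
    out near 10 Hz).
    """
    v = np.asarray(voltage, dtype=float)
    if v.size == 0:
        raise ValueError("empty voltage trace")
    below = v < threshold
    crossings = np.flatnonzero(below[1:] & ~below[:-1]) + 1
    if v[0] < threshold:
        crossings = np.concatenate([[0], crossings])
    times = crossings / fs_hz
    if times.size == 0:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory_s:
            kept.append(t)
    return np.asarray(kept)


def per_trial_lick_counts(licks: np.ndarray, trials: pd.DataFrame) -> pd.DataFrame:
    """Per-trial lick counts in the anticipatory window ``[cs, us)`` and the
    duration-matched ITI window ``[cs - (us - cs), cs)`` immediately before
    cue onset, plus the difference score (anticipatory - ITI)."""
    licks = np.sort(np.asarray(licks, dtype=float))
    cs = trials["cs_onset_s"].to_numpy(dtype=float)
    us = trials["us_onset_s"].to_numpy(dtype=float)
    dur = us - cs
    anticip = spike_counts_in_windows(licks, cs, us)
    iti = spike_counts_in_windows(licks, cs - dur, cs)
    return pd.DataFrame(
        {
            "trial": trials["trial"].to_numpy(),
            "cs_type": trials["cs_type"].to_numpy(),
            "anticipatory": anticip,
            "iti": iti,
            "difference": anticip - iti,
        }
    )


def _paired_t_p(a: np.ndarray, b: np.ndarray) -> float:
    """Paired t-test p-value; degenerate (zero-variance) differences give 1."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if d.size < 2 or np.all(d == d[0]) and d[0] == 0:
        return 1.0
    if np.std(d, ddof=1) == 0:
        # constant nonzero difference: t is infinite, call it significant
        return 0.0
    return float(sps.ttest_rel(a, b).pvalue)


def bootstrap_power(counts: pd.DataFrame, trial_range=range(1, 51),
                    n_iter: int = 1000, alpha: float = 0.05,
                    seed: int = 0) -> PowerCurve:
    """Detection probability as a function of the number of trials tested.

    For each candidate trial count n, resample n trials with replacement
    ``n_iter`` times and record the fraction of resamples in which the
    paired t-test of anticipatory vs ITI counts is significant at ``alpha``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if len(counts) < 2:
        raise ValueError("need at least 2 trials")
    rng = np.random.default_rng(seed)
    anticip = counts["anticipatory"].to_numpy(dtype=float)
    iti = counts["iti"].to_numpy(dtype=float)
    n_total = anticip.size
    ns = np.asarray(list(trial_range), dtype=int)
    power = np.empty(ns.size)
    for i, n in enumerate(ns):
        idx = rng.integers(0, n_total, size=(n_iter, n))
        d = anticip[idx] - iti[idx]
        if n < 2:
            power[i] = 0.0
            continue
        mean = d.mean(axis=1)
        sd = d.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(n))
        p = 2 * sps.t.sf(np.abs(t), df=n - 1)
        sig = np.isfinite(p) & (p < alpha)
        # zero-variance nonzero-mean resamples are trivially significant
        sig |= (sd == 0) & (mean != 0)
        power[i] = sig.mean()
    return PowerCurve(ns, power, n_iter, alpha)


def _subsets(n: int, n_subset: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    return {
        "first": np.arange(n_subset),
        "last": np.arange(n - n_subset, n),
        "random": np.sort(rng.choice(n, size=n_subset, replace=False)),
    }


def assess_learning(counts_E: pd.DataFrame, counts_A: pd.DataFrame | None,
                    mode: str, n_subset: int = 20, alpha: float = 0.01,
                    seed: int = 0) -> LearningOutcome:
    """Apply the session learning criterion.

    acquisition: paired t-test of anticipatory vs ITI counts on the first
    and last ``n_subset`` reward trials; a subset passes iff p < alpha AND
    the anticipatory mean exceeds the ITI mean; learned if either passes.

    discrimination: two-sample t-test of difference scores, reward vs
    punishment trials, on first / last / seeded-random subsets of
    ``n_subset`` trials per condition; a subset passes iff p < alpha AND
    the raw reward lick count exceeds the punishment lick count.  Learning
    additionally requires anticipatory licking on more than half of the
    reward trials.
    """
    if mode not in ("acquisition", "discrimination"):
        raise ValueError(f"unknown mode {mode!r}")
    e_anticip = counts_E["anticipatory"].to_numpy(dtype=float)
    e_iti = counts_E["iti"].to_numpy(dtype=float)
    if e_anticip.size < n_subset:
        raise ValueError(f"need >= {n_subset} reward trials")
    rng = np.random.default_rng(seed)
    rate = float(np.mean(e_anticip >= 1))
    subset_p: dict[str, float] = {}
    subset_pass: dict[str, bool] = {}
    if mode == "acquisition":
        for name in ("first", "last"):
            idx = _subsets(e_anticip.size, n_subset, rng)[name]
            p = _paired_t_p(e_anticip[idx], e_iti[idx])
            subset_p[name] = p
            subset_pass[name] = bool(
                p < alpha and e_anticip[idx].mean() > e_iti[idx].mean()
            )
        learned = any(subset_pass.values())
        return LearningOutcome(mode, subset_p, subset_pass, rate, learned, alpha)
    if counts_A is None:
        raise ValueError("discrimination mode requires punishment-trial counts")
    a_diff = counts_A["difference"].to_numpy(dtype=float)
    a_anticip = counts_A["anticipatory"].to_numpy(dtype=float)
    e_diff = counts_E["difference"].to_numpy(dtype=float)
    if a_diff.size < n_subset:
        raise ValueError(f"need >= {n_subset} punishment trials")
    e_subs = _subsets(e_diff.size, n_subset, rng)
    a_subs = _subsets(a_diff.size, n_subset, rng)
    for name in ("first", "last", "random"):
        ei, ai = e_subs[name], a_subs[name]
        de, da = e_diff[ei], a_diff[ai]
        if np.std(de, ddof=1) == 0 and np.std(da, ddof=1) == 0:
            p = 0.0 if de.mean() != da.mean() else 1.0
        else:
            p = float(sps.ttest_ind(de, da).pvalue)
        subset_p[name] = p
        subset_pass[name] = bool(
            p < alpha and e_anticip[ei].sum() > a_anticip[ai].sum()
        )
    learned = any(subset_pass.values()) and rate > 0.5
    return LearningOutcome(mode, subset_p, subset_pass, rate, learned, alpha,
                           random_subset_seed=seed)


def classify_trial_outcomes(licks: np.ndarray, trials: pd.DataFrame) -> pd.Series:
    """Signal-detection trial labels from anticipatory licking.

    Reward (E) trials: >= 1 anticipatory lick -> hit, else miss.
    Punishment (A) trials: >= 1 anticipatory lick -> false_alarm, else
    correct_rejection.
    """
    counts = per_trial_lick_counts(licks, trials)
    licked = counts["anticipatory"].to_numpy() >= 1
    is_e = counts["cs_type"].to_numpy() == "E"
    labels = np.where(
        is_e,
        np.where(licked, "hit", "miss"),
        np.where(licked, "false_alarm", "correct_rejection"),
    )
    return pd.Series(labels, index=counts["trial"].to_numpy(), name="outcome")
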