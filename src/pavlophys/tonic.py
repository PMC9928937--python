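"""Between-trial tonic-change detection.

Trial averaging obscures slow drifts in background firing that develop
over the course of a session.  This module works trial-by-trial instead:
spikes are counted per trial in three fixed windows around cue onset — an
ITI baseline [-3, -2) s, a pre-cue window [-1, 0) s, and a response window
[0, 1) s — separately for reward (E) and punishment (A) trials.  Pre-cue
and response counts are z-scored against the baseline window's across-trial
statistics, smoothed over trials, and the four per-unit series (E-pre,
E-response, A-pre, A-response) are concatenated and Ward-clustered.  A
cluster shows a tonic change when the confidence interval around the slope
of an ordinary least-squares regression of its mean per-trial count on
trial number excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import SpikeTrain, causal_smooth, spike_counts_in_windows
from .clustering import ClusterResult, ward_cut, CUTOFF_PRESETS
from .stats import ols_slope_ci

__all__ = [
    "WINDOWS",
    "TrialCountSeries",
    "TonicTestResult",
    "trial_window_counts",
    "normalize_trial_series",
    "smoothing_window",
    "cluster_trial_series",
    "detect_tonic_change",
    "tonic_change_report",
]

#: Analysis windows in seconds relative to cue onset (half-open).
WINDOWS = {"baseline": (-3.0, -2.0), "pre_cue": (-1.0, 0.0), "response": (0.0, 1.0)}

SERIES_ORDER = ("E_pre", "E_response", "A_pre", "A_response")


@dataclass
class TrialCountSeries:
    """Per-trial spike counts per window and CS condition for one unit."""

    unit_id: str
    counts: dict[str, dict[str, np.ndarray]]  # condition -> window -> counts
    trial_indices: dict[str, np.ndarray]  # condition -> original trial ids


@dataclass
class TonicTestResult:
    cluster: int
    condition: str
    window: str
    slope: float
    ci_low: float
    ci_high: float
    ci_level: float
    change: bool


def trial_window_counts(unit: SpikeTrain, trials: pd.DataFrame,
                        tone_duration_s: float = 4.0) -> TrialCountSeries:
    """Integer spike counts in the three analysis windows, per CS condition.

    Validates that the windows stay inside the inter-trial interval: the
    earliest window start (-3 s) must not reach back into the previous
    trial's tone/US epoch.
    """
    cs = trials["cs_onset_s"].to_numpy(dtype=float)
    if len(trials) > 1:
        prev_end = np.maximum(
            trials["us_onset_s"].to_numpy(dtype=float)[:-1] + 1.0,
            cs[:-1] + tone_duration_s,
        )
        bad = np.flatnonzero(cs[1:] - 3.0 < prev_end)
        if bad.size:
            raise ValueError(
                "analysis windows overlap the previous trial's US epoch on "
                f"trials {list(trials['trial'].to_numpy()[bad + 1])}"
            )
    counts: dict[str, dict[str, np.ndarray]] = {}
    idx: dict[str, np.ndarray] = {}
    for cond in ("E", "A"):
        sel = trials["cs_type"] == cond
        onsets = trials.loc[sel, "cs_onset_s"].to_numpy(dtype=float)
        idx[cond] = trials.loc[sel, "trial"].to_numpy()
        counts[cond] = {
            w: spike_counts_in_windows(unit.times, onsets + lo, onsets + hi)
            for w, (lo, hi) in WINDOWS.items()
        }
    return TrialCountSeries(unit.unit_id, counts, idx)


def smoothing_window(factor: float, n_trials: int) -> int:
    """Map a qualitative smoothing factor in [0, 1] to a trailing-window
    width in trials: ``max(3, ceil(factor * n_trials / 2))``."""
    if not (0 <= factor <= 1):
        raise ValueError("smoothing factor must be in [0, 1]")
    return max(3, int(np.ceil(factor * n_trials / 2)))


def normalize_trial_series(series_list: list[TrialCountSeries],
                           smoothing_factor: float = 0.85,
                           baseline_mode: str = "window",
                           n_habituation: int = 10,
                           ) -> tuple[np.ndarray, list[str], list[str], dict[str, slice]]:
    """Baseline z-scoring and across-trial smoothing of per-trial counts.

    For each unit and condition, pre-cue and response counts are z-scored
    against a baseline reference, smoothed over trials with a
    Gaussian-weighted moving average, and the four series are concatenated
    in the order E-pre, E-response, A-pre, A-response.

    ``baseline_mode`` selects the normalization reference: ``"window"``
    (default) uses the across-trial mean/SD of the within-trial baseline
    window [-3, -2) s; ``"first_trials"`` uses the mean/SD of the series'
    own first ``n_habituation`` trials (the habituation-period reference,
    which does not absorb a session-long drift into the SD and therefore
    displays drifts at higher contrast).

    Returns ``(matrix, kept_unit_ids, removed_unit_ids, block_slices)``.
    Units with a zero reference SD in any condition are removed.
    """
    if not series_list:
        raise ValueError("no trial-count series supplied")
    if baseline_mode not in ("window", "first_trials"):
        raise ValueError(f"unknown baseline_mode {baseline_mode!r}")
    for s in series_list:
        for cond in ("E", "A"):
            if s.counts[cond]["baseline"].size < 5:
                raise ValueError(
                    f"unit {s.unit_id}: need >= 5 trials per condition"
                )
    kept: list[str] = []
    removed: list[str] = []
    rows = []
    slices: dict[str, slice] = {}
    for s in series_list:
        blocks = []
        ok = True
        for key in SERIES_ORDER:
            cond, win = key.split("_", 1)
            win = "pre_cue" if win == "pre" else "response"
            raw = s.counts[cond][win].astype(float)
            if baseline_mode == "window":
                base = s.counts[cond]["baseline"].astype(float)
            else:
                base = raw[:n_habituation]
            mu, sd = base.mean(), base.std(ddof=0)
            if sd == 0:
                ok = False
                break
            z = (raw - mu) / sd
            w = smoothing_window(smoothing_factor, z.size)
            blocks.append(causal_smooth(z, w))
        if not ok:
            removed.append(s.unit_id)
            continue
        if not slices:
            start = 0
            for key, blk in zip(SERIES_ORDER, blocks):
                slices[key] = slice(start, start + blk.size)
                start += blk.size
        rows.append(np.concatenate(blocks))
        kept.append(s.unit_id)
    matrix = np.vstack(rows) if rows else np.empty((0, 0))
    return matrix, kept, removed, slices


def cluster_trial_series(zseries: np.ndarray, unit_ids: list[str],
                         cutoff_fraction: float = CUTOFF_PRESETS["tonic"],
                         min_cluster_size: int = 3) -> ClusterResult:
    """Ward clustering of concatenated trial series (Euclidean metric,
    cutoff at 20% of the maximum merge height by default)."""
    return ward_cut(zseries, cutoff_fraction, min_cluster_size,
                    unit_ids=unit_ids)


def detect_tonic_change(mean_counts: np.ndarray, cluster: int = -1,
                        condition: str = "", window: str = "",
                        ci_level: float = 0.95,
                        trial_index: np.ndarray | None = None) -> TonicTestResult:
    """Regression-slope tonic-change test on a cluster's mean per-trial
    counts: OLS of count vs trial number with a t-based confidence
    interval; a change is flagged iff the CI excludes zero."""
    y = np.asarray(mean_counts, dtype=float)
    if y.size < 5:
        raise ValueError("need >= 5 trials for the slope test")
    slope, lo, hi = ols_slope_ci(y, trial_index, ci_level)
    return TonicTestResult(cluster, condition, window, slope, lo, hi,
                           ci_level, not (lo <= 0.0 <= hi))


def tonic_change_report(result: ClusterResult,
                        series_by_unit: dict[str, TrialCountSeries],
                        ci_level: float = 0.95,
                        use_smoothed: bool = False,
                        smoothing_factor: float = 0.85) -> pd.DataFrame:
    """Per-cluster slope tests, one per condition x window (4 per cluster).

    The regression is fit to the cluster's mean raw per-trial counts by
    default; ``use_smoothed`` fits the smoothed series instead (smoothing
    induces serial correlation, so the default keeps the t-based CI exact).
    """
    rows = []
    for lab, members in result.clusters.items():
        uids = [result.unit_ids[i] for i in members]
        for cond in ("E", "A"):
            for win in ("pre_cue", "response"):
                stack = np.vstack(
                    [series_by_unit[u].counts[cond][win] for u in uids]
                ).astype(float)
                mean_series = stack.mean(axis=0)
                if use_smoothed:
                    w = smoothing_window(smoothing_factor, mean_series.size)
                    mean_series = causal_smooth(mean_series, w)
                r = detect_tonic_change(mean_series, lab, cond, win, ci_level)
                rows.append(
                    {
                        "cluster": lab,
                        "n_units": len(uids),
                        "condition": cond,
                        "window": win,
                        "slope": r.slope,
                        "ci_low": r.ci_low,
                        "ci_high": r.ci_high,
                        "ci_level": ci_level,
                        "change": r.change,
                    }
                )
    return pd.DataFrame(rows)
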