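"""PSTHs, baseline z-normalization, and a-priori response categorization.

Trial-averaged peri-stimulus time histograms are z-scored against each
unit's own pre-cue baseline and smoothed with a causal Gaussian kernel.
Task responsiveness uses a Wilcoxon signed-rank test of per-trial spike
counts in the 0-100 ms post-stimulus window against a duration-matched
baseline window taken 3 s back in the preceding inter-trial interval;
the excited/inhibited sign comes from the mean z-score of the response.
Valence categories cross the per-cue significance and sign into the nine
labels E+A+, E+A-, E-A+, E-A-, E+, E-, A+, A-, none: same-sign responses
to both cues indicate arousal/salience coding, mixed-sign valence coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import SpikeTrain, causal_smooth, spike_counts_in_windows
from .stats import proportion_test, kruskal_with_posthoc, signed_rank

__all__ = [
    "PSTHMatrix",
    "ResponsivenessCall",
    "compute_psth",
    "zscore_smooth",
    "classify_responsiveness",
    "classify_valence_category",
    "category_statistics",
    "VALENCE_LABELS",
]

VALENCE_LABELS = ("E+A+", "E+A-", "E-A+", "E-A-", "E+", "E-", "A+", "A-", "none")


@dataclass
class PSTHMatrix:
    """Units x time-bins event-aligned matrix (rate in Hz, or z-score)."""

    unit_ids: list[str]
    edges: np.ndarray  # bin edges, seconds relative to the alignment event
    values: np.ndarray  # (n_units, n_bins)
    bin_width_s: float
    alignment: str = ""
    condition: str = ""
    kind: str = "rate"  # "rate" or "zscore"
    removed_units: list[str] = field(default_factory=list)

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0

    def bins_in(self, window: tuple[float, float]) -> np.ndarray:
        """Boolean mask of bins whose left edge lies in ``[lo, hi)``."""
        lo, hi = window
        left = self.edges[:-1]
        return (left >= lo) & (left < hi)


def compute_psth(units: list[SpikeTrain], events: np.ndarray,
                 bin_width_s: float = 0.05,
                 window: tuple[float, float] = (-2.0, 6.0),
                 alignment: str = "", condition: str = "") -> PSTHMatrix:
    """Trial-averaged event-aligned firing rate per unit, half-open bins.

    50 ms bins are the default for trajectory analyses; clustering input
    uses 100 ms.
    """
    events = np.asarray(events, dtype=float)
    if events.size == 0:
        raise ValueError("need at least one alignment event")
    lo, hi = window
    n_bins = int(round((hi - lo) / bin_width_s))
    if n_bins < 1 or not np.isclose(lo + n_bins * bin_width_s, hi):
        raise ValueError("window must be an integer number of bins")
    edges = lo + bin_width_s * np.arange(n_bins + 1)
    values = np.empty((len(units), n_bins))
    for i, u in enumerate(units):
        aligned = np.concatenate([u.times - e for e in events])
        hist, _ = np.histogram(aligned, bins=edges)
        values[i] = hist / (events.size * bin_width_s)
    return PSTHMatrix([u.unit_id for u in units], edges, values, bin_width_s,
                      alignment, condition, kind="rate")


def zscore_smooth(psth: PSTHMatrix, baseline_window: tuple[float, float] = (-2.0, 0.0),
                  smooth_bins: int = 10) -> PSTHMatrix:
    """Per-unit baseline z-score followed by causal Gaussian smoothing.

    Each unit is normalized by the mean and SD of its own bins inside
    ``baseline_window``, then smoothed over the current and ``smooth_bins``
    previous bins.  Units whose baseline SD is zero (z undefined, NaN) are
    removed and reported in ``removed_units``.
    """
    lo, hi = baseline_window
    if lo < psth.edges[0] - 1e-9 or hi > psth.edges[-1] + 1e-9:
        raise ValueError("baseline window outside the PSTH window")
    mask = psth.bins_in(baseline_window)
    if not mask.any():
        raise ValueError("baseline window contains no bins")
    mu = psth.values[:, mask].mean(axis=1, keepdims=True)
    sd = psth.values[:, mask].std(axis=1, ddof=0, keepdims=True)
    ok = (sd[:, 0] > 0) & np.isfinite(psth.values).all(axis=1)
    removed = [uid for uid, good in zip(psth.unit_ids, ok) if not good]
    z = (psth.values[ok] - mu[ok]) / sd[ok]
    smoothed = causal_smooth(z, smooth_bins, axis=1) if z.size else z
    return PSTHMatrix(
        [uid for uid, good in zip(psth.unit_ids, ok) if good],
        psth.edges, smoothed, psth.bin_width_s, psth.alignment,
        psth.condition, kind="zscore", removed_units=removed,
    )


@dataclass
class ResponsivenessCall:
    unit_id: str
    p_cs: float
    p_us: float
    z_cs: float
    z_us: float
    cs_responsive: bool
    us_responsive: bool
    cs_sign: str  # "excited" / "inhibited" / "" (not responsive or tied)
    us_sign: str
    label: str  # "CS" / "US" / "both" / "none"


def _window_test(unit: SpikeTrain, events: np.ndarray, cs_ref: np.ndarray,
                 baseline_s: float, window_s: float) -> tuple[float, float]:
    """Signed-rank p and mean response z for one stimulus.

    Response: per-trial counts in ``[event, event + window_s)``.  Baseline:
    counts in a duration-matched window taken ``baseline_s`` back in the
    ITI preceding the trial's cue (``[cs - baseline_s, cs - baseline_s +
    window_s)``); matching the durations keeps the paired signed-rank test
    calibrated (both samples are counts over the same interval length).
    """
    resp = spike_counts_in_windows(unit.times, events, events + window_s)
    base = spike_counts_in_windows(
        unit.times, cs_ref - baseline_s, cs_ref - baseline_s + window_s
    )
    p = signed_rank(resp, base)
    sd = base.std(ddof=0)
    z = float((resp.mean() - base.mean()) / sd) if sd > 0 else float("nan")
    return p, z


def classify_responsiveness(unit: SpikeTrain, cs_events: np.ndarray,
                            us_events: np.ndarray, baseline_s: float = 3.0,
                            window_ms: float = 100.0,
                            alpha: float = 0.01) -> ResponsivenessCall:
    """Task-responsiveness call for one unit (CS / US / both / none)."""
    cs_events = np.asarray(cs_events, dtype=float)
    us_events = np.asarray(us_events, dtype=float)
    if cs_events.size < 10 or us_events.size < 10:
        raise ValueError("need >= 10 trials per stimulus")
    w = window_ms / 1000.0
    p_cs, z_cs = _window_test(unit, cs_events, cs_events, baseline_s, w)
    p_us, z_us = _window_test(unit, us_events, cs_events, baseline_s, w)
    cs_resp = p_cs < alpha
    us_resp = p_us < alpha

    def sign(responsive: bool, z: float) -> str:
        if not responsive or not np.isfinite(z) or z == 0:
            return ""
        return "excited" if z > 0 else "inhibited"

    label = {
        (True, True): "both",
        (True, False): "CS",
        (False, True): "US",
        (False, False): "none",
    }[(cs_resp, us_resp)]
    return ResponsivenessCall(unit.unit_id, p_cs, p_us, z_cs, z_us,
                              cs_resp, us_resp, sign(cs_resp, z_cs),
                              sign(us_resp, z_us), label)


def classify_valence_category(unit: SpikeTrain, csE_events: np.ndarray,
                              csA_events: np.ndarray, baseline_s: float = 3.0,
                              window_ms: float = 100.0,
                              alpha: float = 0.01) -> str:
    """A-priori valence category from per-cue signed-rank significance and
    response sign (z threshold 0), one of the nine decision-tree labels."""
    csE_events = np.asarray(csE_events, dtype=float)
    csA_events = np.asarray(csA_events, dtype=float)
    if csE_events.size < 10 or csA_events.size < 10:
        raise ValueError("need >= 10 trials per cue")
    w = window_ms / 1000.0
    p_e, z_e = _window_test(unit, csE_events, csE_events, baseline_s, w)
    p_a, z_a = _window_test(unit, csA_events, csA_events, baseline_s, w)

    def part(prefix: str, p: float, z: float) -> str:
        if p >= alpha or not np.isfinite(z) or z == 0:
            return ""
        return prefix + ("+" if z > 0 else "-")

    label = part("E", p_e, z_e) + part("A", p_a, z_a)
    return label or "none"


def category_statistics(count_tables: dict[str, np.ndarray],
                        loo_counts_by_subject: pd.DataFrame | None = None,
                        alpha: float = 0.05) -> dict:
    """Category-level statistics.

    ``count_tables`` maps a comparison name to a contingency table of
    category counts between populations; each is tested with chi-squared or
    Fisher's exact test as appropriate.  ``loo_counts_by_subject`` (rows =
    left-out subjects, columns = categories) feeds a Kruskal-Wallis
    prevalence comparison with largest-vs-rest rank-sum post hocs at a
    Bonferroni-adjusted alpha.
    """
    report: dict = {"proportions": {}, "prevalence": None}
    for name, table in count_tables.items():
        report["proportions"][name] = proportion_test(table)
    if loo_counts_by_subject is not None and loo_counts_by_subject.shape[1] >= 2:
        groups = {c: loo_counts_by_subject[c].to_numpy(dtype=float)
                  for c in loo_counts_by_subject.columns}
        report["prevalence"] = kruskal_with_posthoc(groups, alpha=alpha)
    return report
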