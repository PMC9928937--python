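"""Shared containers and numeric helpers used across the pipeline.

The pipeline operates on sorted extracellular spike trains recorded from the
medial geniculate nucleus (MGN) and basolateral amygdala (BLA) of head-fixed
mice performing a Pavlovian reward/punishment discrimination task.  Sessions
bundle spikes with the trial event table, lick events, and laser pulse epochs
used for optogenetic phototagging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Closed vocabulary of circuit subpopulations.
SUBPOPULATIONS = ("MGN_untagged", "MGN_to_BLA", "BLA_out", "BLA_in")

#: Trial-outcome labels from crossing CS type with anticipatory licking.
OUTCOME_LABELS = ("hit", "miss", "false_alarm", "correct_rejection")

TRIAL_COLUMNS = ("trial", "cs_type", "cs_onset_s", "us_onset_s")


@dataclass
class SpikeTrain:
    """One sorted unit's spike times (seconds from session start)."""

    unit_id: str
    subject: str
    region: str  # "MGN" or "BLA"
    times: np.ndarray
    channel: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("spike times must be a 1-D array")
        if self.times.size and not np.all(np.isfinite(self.times)):
            raise ValueError(f"unit {self.unit_id}: non-finite spike times")
        self.times = np.sort(self.times)

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)


@dataclass
class Session:
    """One recording session: trials, spikes, licks, and laser pulses."""

    subject_id: str
    trials: pd.DataFrame
    spikes: list[SpikeTrain]
    licks: np.ndarray = field(default_factory=lambda: np.empty(0))
    laser: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["onset_s", "width_s", "freq_hz"]
        )
    )
    voltage: Optional[tuple[np.ndarray, float]] = None  # (trace, fs)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.licks = np.sort(np.asarray(self.licks, dtype=float))
        validate_trials(self.trials)

    def units_in_region(self, region: str) -> list[SpikeTrain]:
        return [u for u in self.spikes if u.region == region]

    def cs_onsets(self, cs_type: Optional[str] = None) -> np.ndarray:
        t = self.trials
        if cs_type is not None:
            t = t[t["cs_type"] == cs_type]
        return t["cs_onset_s"].to_numpy(dtype=float)

    def tag_pulses(self, width_s: float = 0.005, freq_hz: float = 1.0) -> np.ndarray:
        """Onsets of the phototagging pulses (5 ms, 1 Hz by default)."""
        m = np.isclose(self.laser["width_s"], width_s) & np.isclose(
            self.laser["freq_hz"], freq_hz
        )
        return self.laser.loc[m, "onset_s"].to_numpy(dtype=float)


def validate_trials(trials: pd.DataFrame) -> None:
    """Check the trial-table contract: ordering, jitter, non-overlap."""
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    if len(trials) == 0:
        return
    cs = trials["cs_onset_s"].to_numpy(dtype=float)
    us = trials["us_onset_s"].to_numpy(dtype=float)
    if not np.all(np.isfinite(cs)) or not np.all(np.isfinite(us)):
        raise ValueError("non-finite trial event times")
    if np.any(cs < 0):
        raise ValueError("trial onsets must be non-negative")
    if np.any(us <= cs):
        raise ValueError("US onset must follow CS onset on every trial")
    if np.any(np.diff(cs) <= 0):
        raise ValueError("trials must be strictly time-ordered")
    bad = set(trials["cs_type"]) - {"E", "A"}
    if bad:
        raise ValueError(f"unknown cs_type values: {sorted(bad)}")


def causal_gaussian_kernel(n_prev: int, sigma: Optional[float] = None) -> np.ndarray:
    """Trailing Gaussian weights over the current and ``n_prev`` previous bins.

    Weight j (j = 0 is the current bin) is ``exp(-j^2 / (2 sigma^2))`` with
    ``sigma = n_prev / 5`` unless given; weights are normalized to sum to 1.
    """
    if n_prev < 0:
        raise ValueError("n_prev must be >= 0")
    if n_prev == 0:
        return np.ones(1)
    if sigma is None:
        sigma = n_prev / 5.0
    j = np.arange(n_prev + 1, dtype=float)
    w = np.exp(-(j**2) / (2.0 * sigma**2))
    return w / w.sum()


def causal_smooth(x: np.ndarray, n_prev: int, sigma: Optional[float] = None,
                  axis: int = -1) -> np.ndarray:
    """Gaussian-weighted moving average over the current and previous bins.

    Strictly causal: output at bin t depends only on bins <= t.  Near the
    start of the series the kernel is truncated and renormalized so a
    constant input maps to the same constant.
    """
    x = np.asarray(x, dtype=float)
    w = causal_gaussian_kernel(n_prev, sigma)

    def smooth_1d(v: np.ndarray) -> np.ndarray:
        n = v.size
        out = np.empty(n)
        for t in range(n):
            k = min(t, n_prev)
            ww = w[: k + 1]
            out[t] = float(np.dot(ww, v[t - k : t + 1][::-1]) / ww.sum())
        return out

    return np.apply_along_axis(smooth_1d, axis, x)


def spike_counts_in_windows(times: np.ndarray, starts: np.ndarray,
                            stops: np.ndarray) -> np.ndarray:
    """Spike counts in half-open windows ``[start, stop)`` (vectorized)."""
    times = np.asarray(times, dtype=float)
    lo = np.searchsorted(times, np.asarray(starts, dtype=float), side="left")
    hi = np.searchsorted(times, np.asarray(stops, dtype=float), side="left")
    return (hi - lo).astype(int)
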