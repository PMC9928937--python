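"""Shared fixtures: small simulated studies and hand-built sessions."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pavlophys.core import SpikeTrain
from pavlophys.synthetic import SimConfig, generate_trial_table, simulate_study


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        n_subjects=1,
        units_per_subpop={
            "MGN_untagged": 4,
            "MGN_to_BLA": 3,
            "BLA_out": 3,
            "BLA_in": 2,
        },
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def default_trials() -> pd.DataFrame:
    return generate_trial_table(SimConfig(), seed=1)


def regular_trials(n_e: int, n_a: int, spacing_s: float = 30.0,
                   anticip_s: float = 1.25) -> pd.DataFrame:
    """Deterministic alternating trial table for hand-built tests."""
    types = (["E", "A"] * max(n_e, n_a))
    out = []
    e = a = 0
    t = spacing_s
    i = 0
    for ty in types:
        if ty == "E" and e < n_e:
            e += 1
        elif ty == "A" and a < n_a:
            a += 1
        else:
            continue
        out.append({"trial": i, "cs_type": ty, "cs_onset_s": t,
                    "us_onset_s": t + anticip_s})
        t += spacing_s
        i += 1
    return pd.DataFrame(out)


def unit_from_per_trial_counts(trials: pd.DataFrame, baseline_counts,
                               resp_counts_e, resp_counts_a,
                               unit_id: str = "u0") -> SpikeTrain:
    """Spike train with exact per-trial counts in the duration-matched
    baseline window [-3, -2.9) and the 100 ms response window [0, 0.1)
    (spikes evenly placed)."""
    times = []
    occ = {"E": 0, "A": 0}
    for row in trials.itertuples():
        k = occ[row.cs_type]
        occ[row.cs_type] += 1
        b = baseline_counts[k % len(baseline_counts)]
        times.extend(row.cs_onset_s - 3.0 + 0.1 * (np.arange(b) + 0.5) / max(b, 1))
        if row.cs_type == "E":
            r = resp_counts_e[k % len(resp_counts_e)]
        else:
            r = resp_counts_a[k % len(resp_counts_a)]
        times.extend(row.cs_onset_s + 0.1 * (np.arange(r) + 0.5) / max(r, 1))
    return SpikeTrain(unit_id, "sub00", "MGN", np.asarray(sorted(times)))
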