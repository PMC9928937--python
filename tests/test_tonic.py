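"""Between-trial tonic analysis: counting, normalization, slope test."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from pavlophys.core import SpikeTrain, causal_smooth
from pavlophys.synthetic import SimConfig, generate_trial_table, simulate_unit, ResponseTemplate
from pavlophys.tonic import (
    SERIES_ORDER,
    cluster_trial_series,
    detect_tonic_change,
    normalize_trial_series,
    smoothing_window,
    tonic_change_report,
    trial_window_counts,
)

from conftest import regular_trials


def _unit_with_window_spikes(trials, per_window):
    """per_window: {'baseline'|'pre_cue'|'response': count per trial}."""
    offsets = {"baseline": -2.5, "pre_cue": -0.5, "response": 0.5}
    times = []
    for row in trials.itertuples():
        for w, n in per_window.items():
            for k in range(n):
                times.append(row.cs_onset_s + offsets[w] + 1e-3 * k)
    return SpikeTrain("u", "s", "MGN", np.asarray(sorted(times)))


class TestTrialWindowCounts:
    def test_disjoint_windows(self):
        trials = regular_trials(5, 5)
        u = _unit_with_window_spikes(trials, {"baseline": 2})
        ts = trial_window_counts(u, trials)
        for cond in ("E", "A"):
            assert np.all(ts.counts[cond]["baseline"] == 2)
            assert np.all(ts.counts[cond]["pre_cue"] == 0)
            assert np.all(ts.counts[cond]["response"] == 0)

    def test_hand_tally(self):
        trials = regular_trials(1, 0)
        cs = trials.loc[0, "cs_onset_s"]
        u = SpikeTrain(
            "u", "s", "MGN",
            np.array([cs - 2.9, cs - 2.1, cs - 0.7, cs - 0.2, cs + 0.1,
                      cs + 0.5, cs + 0.9]),
        )
        ts = trial_window_counts(u, trials)
        assert ts.counts["E"]["baseline"][0] == 2
        assert ts.counts["E"]["pre_cue"][0] == 2
        assert ts.counts["E"]["response"][0] == 3

    def test_window_collision_reported(self):
        trials = pd.DataFrame(
            {
                "trial": [0, 1],
                "cs_type": ["E", "E"],
                "cs_onset_s": [10.0, 16.0],  # only 2 s after prev tone end
                "us_onset_s": [11.2, 17.2],
            }
        )
        with pytest.raises(ValueError, match="trials"):
            trial_window_counts(SpikeTrain("u", "s", "MGN", np.array([1.0])),
                                trials)

    def test_window_accounting(self):
        """baseline+pre_cue+response counts never exceed spikes in [-3, 1)."""
        cfg = SimConfig()
        trials = generate_trial_table(cfg, seed=3)
        u = SpikeTrain(
            "u", "s", "MGN",
            simulate_unit(ResponseTemplate("flat"), 10.0, 0.0, trials, seed=4),
        )
        ts = trial_window_counts(u, trials)
        for cond in ("E", "A"):
            onsets = trials.loc[trials["cs_type"] == cond,
                                "cs_onset_s"].to_numpy()
            total = np.array([
                ((u.times >= c - 3.0) & (u.times < c + 1.0)).sum()
                for c in onsets
            ])
            summed = (ts.counts[cond]["baseline"] + ts.counts[cond]["pre_cue"]
                      + ts.counts[cond]["response"])
            assert np.all(summed <= total)


class TestNormalize:
    def test_zero_deviation_gives_zero_z(self):
        trials = regular_trials(10, 10)
        # baseline counts alternate 1/3 (mean 2, sd 1); pre_cue/response = 2
        times = []
        for i, row in enumerate(trials.itertuples()):
            n_b = 1 if i % 4 < 2 else 3
            times.extend(row.cs_onset_s - 2.5 + 1e-3 * np.arange(n_b))
            times.extend(row.cs_onset_s - 0.5 + 1e-3 * np.arange(2))
            times.extend(row.cs_onset_s + 0.5 + 1e-3 * np.arange(2))
        u = SpikeTrain("u", "s", "MGN", np.asarray(sorted(times)))
        ts = trial_window_counts(u, trials)
        Z, kept, removed, slices = normalize_trial_series([ts],
                                                          smoothing_factor=0.0)
        assert kept == ["u"]
        assert np.allclose(Z, 0.0)

    def test_block_order_and_sizes(self):
        trials = regular_trials(8, 6)
        u = _unit_with_window_spikes(trials, {"baseline": 1, "response": 2})
        # add variability so baseline SD > 0
        extra = [trials.loc[0, "cs_onset_s"] - 2.4,
                 trials.loc[1, "cs_onset_s"] - 2.4]
        u = SpikeTrain("u", "s", "MGN", np.sort(np.concatenate([u.times, extra])))
        ts = trial_window_counts(u, trials)
        Z, kept, _, slices = normalize_trial_series([ts])
        assert list(slices) == list(SERIES_ORDER)
        assert slices["E_pre"].stop - slices["E_pre"].start == 8
        assert slices["A_pre"].stop - slices["A_pre"].start == 6
        assert Z.shape == (1, 2 * 8 + 2 * 6)

    def test_zero_baseline_sd_unit_removed(self):
        trials = regular_trials(6, 6)
        u = _unit_with_window_spikes(trials, {"baseline": 2, "response": 1})
        ts = trial_window_counts(u, trials)
        Z, kept, removed, _ = normalize_trial_series([ts])
        assert removed == ["u"]
        assert kept == []

    def test_smoothing_preserves_constants(self):
        x = np.full(40, 3.7)
        w = smoothing_window(0.85, x.size)
        assert np.allclose(causal_smooth(x, w), 3.7, atol=1e-9)

    def test_too_few_trials_rejected(self):
        trials = regular_trials(3, 3)
        u = _unit_with_window_spikes(trials, {"baseline": 1})
        ts = trial_window_counts(u, trials)
        with pytest.raises(ValueError):
            normalize_trial_series([ts])


class TestSlopeTest:
    def test_exact_increasing_line(self):
        r = detect_tonic_change(np.arange(1.0, 21.0))
        assert r.slope == pytest.approx(1.0)
        assert r.change

    def test_constant_series(self):
        r = detect_tonic_change(np.full(20, 4.0))
        assert r.slope == pytest.approx(0.0)
        assert not r.change

    def test_coverage_quick(self):
        """95% CI covers a true slope of 0.05 spikes/trial at ~95%."""
        rng = np.random.default_rng(0)
        slope = 0.05
        n_trials = 75
        covered = 0
        n_seeds = 300
        for _ in range(n_seeds):
            y = rng.poisson(5.0 + slope * np.arange(n_trials))
            r = detect_tonic_change(y.astype(float))
            covered += r.ci_low <= slope <= r.ci_high
        assert 0.91 <= covered / n_seeds <= 0.985

    def test_too_few_trials(self):
        with pytest.raises(ValueError):
            detect_tonic_change(np.array([1.0, 2.0, 3.0]))


class TestClusterTrialSeries:
    def _drift_population(self, n_flat=15, n_drift=15, seed=0):
        cfg = SimConfig()
        trials = generate_trial_table(cfg, seed=seed)
        sseq = np.random.SeedSequence(seed + 1)
        series, by_unit, truth = [], {}, []
        flat = ResponseTemplate("flat")
        for i in range(n_flat + n_drift):
            drift = i >= n_flat
            s = int(sseq.spawn(1)[0].generate_state(1)[0])
            times = simulate_unit(flat, 8.0, 0.6 if drift else 0.0, trials,
                                  seed=s)
            u = SpikeTrain(f"u{i}", f"sub{i % 3}", "MGN", times)
            ts = trial_window_counts(u, trials)
            series.append(ts)
            by_unit[u.unit_id] = ts
            truth.append(int(drift))
        return series, by_unit, np.asarray(truth), trials

    def test_flat_vs_drift_split_recovered(self):
        """Drifting units separate cleanly from flat units: the induced
        drift-vs-rest partition of retained units matches ground truth."""
        series, _, truth, _ = self._drift_population(seed=1)
        Z, kept, _, _ = normalize_trial_series(series)
        res = cluster_trial_series(Z, kept)
        keep_mask = np.isin([f"u{i}" for i in range(len(truth))], kept)
        retained = res.labels >= 0
        t = truth[keep_mask][retained]
        labs = res.labels[retained]
        # the cluster holding drifters must hold all of them and nothing else
        drift_labels = {int(l) for l, d in zip(labs, t) if d}
        assert len(drift_labels) == 1
        binary = (labs == drift_labels.pop()).astype(int)
        assert adjusted_rand_score(t, binary) >= 0.9
        # a sizeable share of flat units must survive discard
        assert (t == 0).sum() >= 10

    def test_habituation_reference_gives_clean_two_way_split(self):
        """Normalizing to the first-10-trial habituation period keeps the
        drift out of the SD, so the flat/drift split is exact."""
        series, _, truth, _ = self._drift_population(seed=3)
        Z, kept, _, _ = normalize_trial_series(series,
                                               baseline_mode="first_trials")
        res = cluster_trial_series(Z, kept)
        keep_mask = np.isin([f"u{i}" for i in range(len(truth))], kept)
        retained = res.labels >= 0
        ari = adjusted_rand_score(truth[keep_mask][retained],
                                  res.labels[retained])
        assert ari >= 0.9

    def test_identical_series_single_cluster(self):
        Z = np.tile(np.linspace(0, 1, 30), (8, 1))
        res = cluster_trial_series(Z, [f"u{i}" for i in range(8)])
        assert res.n_clusters == 1

    def test_report_flags_drifting_cluster(self):
        series, by_unit, truth, _ = self._drift_population(seed=2)
        Z, kept, _, _ = normalize_trial_series(series)
        res = cluster_trial_series(Z, kept)
        report = tonic_change_report(res, by_unit)
        assert set(report.columns) >= {"cluster", "condition", "window",
                                       "slope", "ci_low", "ci_high", "change"}
        assert len(report) == 4 * res.n_clusters
        # at least one cluster flagged in the pre-cue window, and flagged
        # clusters should be drift-enriched
        pre = report[(report["window"] == "pre_cue") & report["change"]]
        assert len(pre) >= 1
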