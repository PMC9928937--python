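"""Ward clustering: oracle equivalence, cutoff/discard rules, prevalence."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from pavlophys.clustering import (
    CUTOFF_PRESETS,
    build_feature_matrix,
    cluster_prevalence_stats,
    ward_cut,
)
from pavlophys.synthetic import (
    PhasicEffect,
    ResponseTemplate,
    SimConfig,
    generate_trial_table,
    simulate_unit,
)
from pavlophys.core import SpikeTrain


def brute_force_ward(X):
    """O(n^3) agglomerative Ward linkage via the Lance-Williams update.

    Returns a linkage-style list of merges: (cluster_i, cluster_j, height,
    size), with new clusters numbered n, n+1, ... as in scipy.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    # squared Euclidean distances between singletons
    d2 = {}
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = float(np.sum((X[i] - X[j]) ** 2))
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    merges = []
    next_id = n

    def key(a, b):
        return (a, b) if a < b else (b, a)

    for _ in range(n - 1):
        (a, b) = min(
            ((i, j) for i in active for j in active if i < j),
            key=lambda p: d2[key(*p)],
        )
        h2 = d2[key(a, b)]
        merges.append((a, b, np.sqrt(h2), size[a] + size[b]))
        # Lance-Williams (Ward, squared distances)
        for k in active - {a, b}:
            sa, sb, sk = size[a], size[b], size[k]
            dak, dbk, dab = d2[key(a, k)], d2[key(b, k)], h2
            d_new = (
                (sa + sk) * dak + (sb + sk) * dbk - sk * dab
            ) / (sa + sb + sk)
            d2[key(next_id, k)] = d_new
        size[next_id] = size[a] + size[b]
        active -= {a, b}
        active.add(next_id)
        next_id += 1
    return merges


def _leaves(merges, cluster_id, n):
    if cluster_id < n:
        return frozenset([cluster_id])
    a, b, _, _ = merges[cluster_id - n]
    return _leaves(merges, int(a), n) | _leaves(merges, int(b), n)


class TestWardOracle:
    @pytest.mark.parametrize("seed", range(50))
    def test_linkage_matches_brute_force(self, seed):
        """Merge sequence and heights identical to the O(n^3) oracle on
        random instances of <= 10 points."""
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 11)
        X = rng.normal(size=(n, rng.integers(2, 5)))
        res = ward_cut(X, cutoff_fraction=1.0, min_cluster_size=1)
        oracle = brute_force_ward(X)
        Z = res.linkage
        o_merges = [(int(a), int(b), h, s) for a, b, h, s in oracle]
        for step in range(n - 1):
            za, zb, zh, zs = Z[step]
            oa, ob, oh, os_ = o_merges[step]
            assert zh == pytest.approx(oh, abs=1e-9)
            assert int(zs) == os_
            assert {
                _leaves(o_merges, int(za), n), _leaves(o_merges, int(zb), n)
            } == {
                _leaves(o_merges, oa, n), _leaves(o_merges, ob, n)
            }


class TestWardCut:
    def test_two_blob_recovery(self):
        rng = np.random.default_rng(1)
        X = np.vstack(
            [rng.normal(0, 0.1, (20, 4)), rng.normal(20, 0.1, (20, 4))]
        )
        res = ward_cut(X, cutoff_fraction=0.23)
        assert res.n_clusters == 2
        assert len(set(res.labels[:20])) == 1
        assert len(set(res.labels[20:])) == 1
        assert res.labels[0] != res.labels[-1]

    def test_small_cluster_discarded(self):
        rng = np.random.default_rng(2)
        X = np.vstack(
            [
                rng.normal(0, 0.1, (10, 3)),
                rng.normal(10, 0.1, (10, 3)),
                rng.normal(40, 0.1, (2, 3)),  # 2-member outlier group
            ]
        )
        res = ward_cut(X, cutoff_fraction=0.23, min_cluster_size=3)
        assert res.discarded == [20, 21]
        assert np.all(res.labels[20:] == -1)
        assert res.n_clusters == 2

    def test_identical_points_single_cluster(self):
        X = np.ones((6, 3))
        res = ward_cut(X, cutoff_fraction=0.5)
        assert res.n_clusters == 1
        assert np.all(res.linkage[:, 2] == 0.0)

    def test_invalid_cutoff_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 2))
        for bad in (0.0, -1.0, 1.5):
            with pytest.raises(ValueError):
                ward_cut(X, cutoff_fraction=bad)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        X = np.vstack(
            [rng.normal(i * 10, 0.5, (8, 3)) for i in range(3)]
        )
        ids = [f"u{i}" for i in range(len(X))]
        res = ward_cut(X, 0.23, unit_ids=ids)
        perm = rng.permutation(len(X))
        res_p = ward_cut(X[perm], 0.23, unit_ids=[ids[i] for i in perm])
        mapping = {}
        for uid, lab in zip(res_p.unit_ids, res_p.labels):
            mapping[uid] = lab
        for uid, lab in zip(res.unit_ids, res.labels):
            # same partition: units sharing a label in one result share in the other
            peers = {u for u, l in zip(res.unit_ids, res.labels) if l == lab}
            peers_p = {u for u, l in mapping.items() if l == mapping[uid]}
            assert peers == peers_p


TEMPLATES = [
    ResponseTemplate("exc_both", cue_e=PhasicEffect(40, 0.01, 0.5),
                     cue_a=PhasicEffect(40, 0.01, 0.5)),
    ResponseTemplate("inh_both", cue_e=PhasicEffect(-7, 0.01, 1.0),
                     cue_a=PhasicEffect(-7, 0.01, 1.0)),
    ResponseTemplate("e_only", cue_e=PhasicEffect(40, 0.01, 0.5)),
    ResponseTemplate("sustained",
                     sustained_e_hz=15.0, sustained_a_hz=15.0),
]


def _template_population(n_per=12, seed=0):
    cfg = SimConfig(n_reward_trials=40, n_punish_trials=30)
    trials = generate_trial_table(cfg, seed=seed)
    units, labels, subjects = [], [], []
    sseq = np.random.SeedSequence(seed + 99)
    for t_idx, tpl in enumerate(TEMPLATES):
        for j in range(n_per):
            s = int(sseq.spawn(1)[0].generate_state(1)[0])
            times = simulate_unit(tpl, 8.0, 0.0, trials, seed=s)
            subject = f"sub{j % 4}"
            units.append(SpikeTrain(f"t{t_idx}_u{j}", subject, "MGN", times))
            labels.append(t_idx)
            subjects.append(subject)
    return units, np.asarray(labels), subjects, trials


class TestTemplateRecovery:
    def test_feature_matrix_shape_and_baseline(self):
        units, _, _, trials = _template_population(n_per=3)
        ev = {
            "E": trials.loc[trials["cs_type"] == "E", "cs_onset_s"].to_numpy(),
            "A": trials.loc[trials["cs_type"] == "A", "cs_onset_s"].to_numpy(),
        }
        fm = build_feature_matrix(units, ev, bin_width_s=0.1,
                                  window=(-2.0, 6.0))
        n_bins = 80
        assert fm.values.shape == (len(units) - len(fm.removed_units),
                                   2 * n_bins)
        assert set(fm.condition_slices) == {"E", "A"}

    def test_four_templates_recovered(self):
        units, truth, _, trials = _template_population(n_per=12, seed=5)
        ev = {
            "E": trials.loc[trials["cs_type"] == "E", "cs_onset_s"].to_numpy(),
            "A": trials.loc[trials["cs_type"] == "A", "cs_onset_s"].to_numpy(),
        }
        fm = build_feature_matrix(units, ev)
        res = ward_cut(fm, CUTOFF_PRESETS["two_condition"])
        kept = [i for i, u in enumerate(units)
                if u.unit_id in set(fm.unit_ids)]
        ari = adjusted_rand_score(truth[kept], res.labels)
        assert ari >= 0.9


class TestPrevalence:
    def test_loo_counts_and_dominance(self):
        rng = np.random.default_rng(7)
        # one dominant blob (30 units) vs two small blobs (6 each)
        X = np.vstack(
            [
                rng.normal(0, 0.3, (30, 4)),
                rng.normal(10, 0.3, (6, 4)),
                rng.normal(-10, 0.3, (6, 4)),
            ]
        )
        ids = [f"u{i}" for i in range(len(X))]
        subjects = {u: f"sub{i % 6}" for i, u in enumerate(ids)}
        regions = {u: "MGN" for u in ids}
        res = ward_cut(X, 0.5, unit_ids=ids)
        report = cluster_prevalence_stats(res, subjects, regions)
        loo = report["loo_counts"]["MGN"]
        assert loo.shape[0] == 6  # k subjects -> k leave-one-out counts
        prev = report["regions"]["MGN"]
        assert prev.significant and prev.reference_group == 0

    def test_equal_clusters_ns(self):
        rng = np.random.default_rng(8)
        X = np.vstack(
            [rng.normal(i * 10, 0.3, (8, 3)) for i in range(3)]
        )
        ids = [f"u{i}" for i in range(len(X))]
        subjects = {u: f"sub{i % 4}" for i, u in enumerate(ids)}
        regions = {u: "BLA" for u in ids}
        res = ward_cut(X, 0.5, unit_ids=ids)
        report = cluster_prevalence_stats(res, subjects, regions)
        assert not report["regions"]["BLA"].significant

    def test_single_cluster_region_reports_ns(self):
        rng = np.random.default_rng(9)
        X = rng.normal(0, 0.3, (12, 3))
        ids = [f"u{i}" for i in range(len(X))]
        subjects = {u: f"sub{i % 4}" for i, u in enumerate(ids)}
        regions = {u: "MGN" for u in ids}
        res = ward_cut(X, 0.9, unit_ids=ids)
        report = cluster_prevalence_stats(res, subjects, regions)
        assert not report["regions"]["MGN"].significant
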