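"""Population neural-trajectory geometry in principal-component space.

Per-condition smoothed z-PSTHs (bins as observations, units as features)
are concatenated along time and a single PCA basis is fit per region; each
condition's projection through that shared basis is its neural trajectory.
Geometry statistics use a leave-one-subject-out scheme: the basis and
trajectories are refit k times (k = number of subjects), yielding k values
of each trajectory's length (summed Euclidean steps in the first
``n_components`` PCs) and of per-bin inter-trajectory distances, which are
then compared with rank-sum / Kruskal-Wallis tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.decomposition import PCA

from .core import causal_smooth
from .stats import kruskal_with_posthoc, ranksum

__all__ = [
    "TrajectorySet",
    "GeometryStats",
    "compute_trajectories",
    "trajectory_length",
    "trajectory_geometry",
    "compare_geometry",
]


@dataclass
class TrajectorySet:
    components: np.ndarray  # (n_components_kept, n_units) loadings
    explained_variance_ratio: np.ndarray
    trajectories: dict[str, np.ndarray]  # condition -> (n_bins, n_comp)
    n_components: int
    smooth_bins: int
    unit_ids: list[str] = field(default_factory=list)
    mean_: np.ndarray | None = None


@dataclass
class GeometryStats:
    """Leave-one-out trajectory lengths and pairwise distances."""

    lengths: dict[str, np.ndarray]  # condition -> (k,) lengths
    distance_series: dict[tuple[str, str], np.ndarray]  # pair -> (k, n_bins)
    pre_window_distance: dict[tuple[str, str], np.ndarray]  # pair -> (k,)
    post_window_distance: dict[tuple[str, str], np.ndarray]
    subjects: list[str]
    n_components: int


def _orient(components: np.ndarray) -> np.ndarray:
    """Fix PCA sign so each component's largest-magnitude loading is
    positive (the sign of a principal axis is otherwise arbitrary)."""
    out = components.copy()
    for i, row in enumerate(out):
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            out[i] = -row
    return out


def compute_trajectories(zpsths: dict[str, np.ndarray], n_components: int = 3,
                         smooth_bins: int = 0,
                         unit_ids: list[str] | None = None) -> TrajectorySet:
    """Fit one PCA basis across conditions and project each condition.

    ``zpsths`` maps condition -> (n_units, n_bins) z-scored matrix; all
    conditions must share the unit set and bin grid.  Bins are the PCA
    observations and units the features (features centered by the fit).
    ``smooth_bins`` applies causal Gaussian smoothing along time before the
    fit (25 previous bins for the two-condition CS analysis, 10 for the
    four-condition outcome analysis).
    """
    if not zpsths:
        raise ValueError("need at least one condition")
    shapes = {v.shape for v in zpsths.values()}
    if len(shapes) != 1:
        raise ValueError("all conditions must share the unit set and bin grid")
    mats = {}
    for cond, m in zpsths.items():
        m = np.asarray(m, dtype=float)
        mats[cond] = causal_smooth(m, smooth_bins, axis=1) if smooth_bins else m
    X = np.vstack([mats[c].T for c in mats])  # (total_bins, n_units)
    n_keep = min(X.shape[0], X.shape[1])
    pca = PCA(n_components=n_keep)
    pca.fit(X)
    comps = _orient(pca.components_)
    Xc = X - pca.mean_
    proj = Xc @ comps.T
    trajectories = {}
    start = 0
    for cond, m in mats.items():
        nb = m.shape[1]
        trajectories[cond] = proj[start : start + nb]
        start += nb
    return TrajectorySet(comps, pca.explained_variance_ratio_, trajectories,
                         n_components, smooth_bins,
                         unit_ids or [], pca.mean_)


def trajectory_length(traj: np.ndarray, n_components: int = 3) -> float:
    """Polyline length: sum of Euclidean distances between consecutive
    time points in the first ``n_components`` coordinates."""
    t = np.asarray(traj, dtype=float)[:, :n_components]
    return float(np.linalg.norm(np.diff(t, axis=0), axis=1).sum())


def distance_series(a: np.ndarray, b: np.ndarray, n_components: int = 3) -> np.ndarray:
    """Per-bin Euclidean distance between two trajectories."""
    a = np.asarray(a, dtype=float)[:, :n_components]
    b = np.asarray(b, dtype=float)[:, :n_components]
    if a.shape != b.shape:
        raise ValueError("trajectories must share the time grid")
    return np.linalg.norm(a - b, axis=1)


def trajectory_geometry(data_by_subject: dict[str, dict[str, np.ndarray]],
                        bin_edges: np.ndarray, n_components: int = 3,
                        smooth_bins: int = 0,
                        pre_window: tuple[float, float] = (-1.0, 0.0),
                        post_window: tuple[float, float] = (0.0, 1.0)
                        ) -> GeometryStats:
    """Leave-one-subject-out trajectory lengths and distances.

    ``data_by_subject`` maps subject -> {condition -> (units, bins) z-PSTH}.
    For each left-out subject, trajectories are recomputed from the
    remaining subjects' units (PCA refit for internal consistency), giving
    k length values per condition and k distance series per condition pair;
    window averages are taken over 1 s pre-cue and 1 s post-cue windows.
    """
    subjects = sorted(data_by_subject)
    if len(subjects) < 3:
        raise ValueError("need >= 3 subjects for leave-one-out geometry")
    conds = list(next(iter(data_by_subject.values())))
    edges = np.asarray(bin_edges, dtype=float)
    left = edges[:-1]
    pre_mask = (left >= pre_window[0]) & (left < pre_window[1])
    post_mask = (left >= post_window[0]) & (left < post_window[1])
    lengths = {c: [] for c in conds}
    pairs = list(combinations(conds, 2))
    dists = {p: [] for p in pairs}
    pre_d = {p: [] for p in pairs}
    post_d = {p: [] for p in pairs}
    for left_out in subjects:
        stacked = {
            c: np.vstack([data_by_subject[s][c] for s in subjects if s != left_out])
            for c in conds
        }
        ts = compute_trajectories(stacked, n_components, smooth_bins)
        for c in conds:
            lengths[c].append(trajectory_length(ts.trajectories[c], n_components))
        for p in pairs:
            d = distance_series(ts.trajectories[p[0]], ts.trajectories[p[1]],
                                n_components)
            dists[p].append(d)
            pre_d[p].append(float(d[pre_mask].mean()))
            post_d[p].append(float(d[post_mask].mean()))
    return GeometryStats(
        {c: np.asarray(v) for c, v in lengths.items()},
        {p: np.vstack(v) for p, v in dists.items()},
        {p: np.asarray(v) for p, v in pre_d.items()},
        {p: np.asarray(v) for p, v in post_d.items()},
        subjects, n_components,
    )


def compare_geometry(stats: GeometryStats, alpha: float = 0.05) -> dict:
    """Statistical comparison of trajectory geometry.

    Lengths: rank-sum for two conditions, Kruskal-Wallis with
    Bonferroni-corrected largest-vs-rest post hocs for more.  Distances:
    pre-cue vs post-cue window rank-sum per pair, plus (when >= 3 pairs) a
    Kruskal-Wallis across the pairs' post-cue window distances.
    """
    report: dict = {}
    conds = list(stats.lengths)
    if len(conds) < 2:
        raise ValueError("need >= 2 conditions")
    if any(v.size < 2 for v in stats.lengths.values()):
        raise ValueError("need >= 2 leave-one-out values per group")
    if len(conds) == 2:
        report["length"] = {
            "test": "rank_sum",
            "p_value": ranksum(stats.lengths[conds[0]], stats.lengths[conds[1]]),
        }
    else:
        report["length"] = kruskal_with_posthoc(stats.lengths, alpha=alpha)
    report["pre_vs_post"] = {
        pair: {
            "test": "rank_sum",
            "p_value": ranksum(stats.pre_window_distance[pair],
                               stats.post_window_distance[pair]),
            "direction": (
                "post>pre"
                if stats.post_window_distance[pair].mean()
                > stats.pre_window_distance[pair].mean()
                else "pre>post"
            ),
        }
        for pair in stats.distance_series
    }
    pairs = list(stats.distance_series)
    if len(pairs) >= 3:
        groups = {p: stats.post_window_distance[p] for p in pairs}
        report["pairwise_distances"] = kruskal_with_posthoc(groups, alpha=alpha)
    return report
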