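"""Hierarchical clustering of phasic response profiles.

Per-condition smoothed z-PSTHs are concatenated per unit into one feature
vector so that a single ("universal") cluster tree spans both reward and
punishment conditions (or all four behavioral-outcome conditions).  The
tree is built with Ward's method on the Euclidean metric and cut at a
fraction of the maximum merge height; clusters with fewer than
``min_cluster_size`` members are discarded (their units flagged, not
reassigned).  Named cutoff presets: 0.23 for the two-condition
reward/punishment analysis, 0.30 for the four-outcome analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .core import SpikeTrain
from .ensemble import compute_psth, zscore_smooth
from .stats import PrevalenceTestResult, kruskal_with_posthoc

__all__ = [
    "CUTOFF_PRESETS",
    "FeatureMatrix",
    "ClusterResult",
    "build_feature_matrix",
    "ward_cut",
    "cluster_prevalence_stats",
]

#: Dendrogram cutoff as a fraction of the maximum merge height.
CUTOFF_PRESETS = {"two_condition": 0.23, "four_condition": 0.30, "tonic": 0.20}


@dataclass
class FeatureMatrix:
    """Per-unit concatenated feature vectors plus provenance."""

    unit_ids: list[str]
    values: np.ndarray  # (n_units, n_features)
    condition_slices: dict[str, slice]
    removed_units: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)


@dataclass
class ClusterResult:
    linkage: np.ndarray  # scipy linkage matrix
    cutoff_fraction: float
    cutoff_height: float
    unit_ids: list[str]
    labels: np.ndarray  # per-unit cluster label; -1 for discarded units
    clusters: dict[int, list[int]]  # label -> member row indices
    discarded: list[int]  # row indices in sub-minimum clusters
    min_cluster_size: int

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def members(self, label: int) -> list[str]:
        return [self.unit_ids[i] for i in self.clusters[label]]


def build_feature_matrix(units: list[SpikeTrain],
                         events_by_condition: dict[str, np.ndarray],
                         bin_width_s: float = 0.1,
                         window: tuple[float, float] = (-2.0, 6.0),
                         baseline_window: tuple[float, float] = (-2.0, 0.0),
                         smooth_bins: int = 10) -> FeatureMatrix:
    """Concatenated per-condition smoothed z-PSTH features.

    Pipeline per condition: trial-averaged PSTH at ``bin_width_s`` ->
    z-score against the pre-cue baseline -> causal Gaussian smoothing over
    ``smooth_bins`` prior bins.  Units dropped in any condition (zero
    baseline SD / NaN) are removed from all conditions and reported.
    """
    if not events_by_condition:
        raise ValueError("need at least one condition")
    for name, ev in events_by_condition.items():
        if np.asarray(ev).size == 0:
            raise ValueError(f"condition {name!r} has no events")
    removed: set[str] = set()
    per_cond: dict[str, dict[str, np.ndarray]] = {}
    for name, ev in events_by_condition.items():
        z = zscore_smooth(
            compute_psth(units, ev, bin_width_s, window, condition=name),
            baseline_window, smooth_bins,
        )
        removed |= set(z.removed_units)
        per_cond[name] = dict(zip(z.unit_ids, z.values))
    kept = [u.unit_id for u in units if u.unit_id not in removed]
    n_bins = {name: len(next(iter(v.values()))) for name, v in per_cond.items() if v}
    slices = {}
    start = 0
    mats = []
    for name in events_by_condition:
        nb = n_bins[name]
        slices[name] = slice(start, start + nb)
        start += nb
        mats.append(np.vstack([per_cond[name][uid] for uid in kept]))
    values = np.hstack(mats) if kept else np.empty((0, start))
    return FeatureMatrix(
        kept, values, slices, sorted(removed),
        params={
            "bin_width_s": bin_width_s,
            "window": window,
            "baseline_window": baseline_window,
            "smooth_bins": smooth_bins,
        },
    )


def ward_cut(matrix: FeatureMatrix | np.ndarray, cutoff_fraction: float = 0.23,
             min_cluster_size: int = 3,
             unit_ids: list[str] | None = None) -> ClusterResult:
    """Agglomerative Ward clustering with a fractional dendrogram cutoff.

    The tree is cut where merge height exceeds ``cutoff_fraction`` times
    the maximum merge height; clusters with fewer than
    ``min_cluster_size`` members are discarded.  Cluster labels are
    canonicalized by descending size, ties broken by smallest member index.
    """
    if not (0 < cutoff_fraction <= 1):
        raise ValueError("cutoff_fraction must be in (0, 1]")
    if isinstance(matrix, FeatureMatrix):
        X = matrix.values
        ids = matrix.unit_ids
    else:
        X = np.asarray(matrix, dtype=float)
        ids = unit_ids if unit_ids is not None else [str(i) for i in range(len(X))]
    n = X.shape[0]
    if n < 2:
        raise ValueError("need >= 2 units to cluster")
    Z = hierarchy.linkage(X, method="ward", metric="euclidean")
    cutoff = cutoff_fraction * Z[:, 2].max()
    raw = hierarchy.fcluster(Z, t=cutoff, criterion="distance")
    clusters: dict[int, list[int]] = {}
    for i, lab in enumerate(raw):
        clusters.setdefault(int(lab), []).append(i)
    retained = {k: v for k, v in clusters.items() if len(v) >= min_cluster_size}
    discarded = sorted(
        i for k, v in clusters.items() if len(v) < min_cluster_size for i in v
    )
    order = sorted(retained, key=lambda k: (-len(retained[k]), min(retained[k])))
    labels = np.full(n, -1, dtype=int)
    canon: dict[int, list[int]] = {}
    for new, old in enumerate(order):
        canon[new] = retained[old]
        labels[retained[old]] = new
    return ClusterResult(Z, cutoff_fraction, float(cutoff), list(ids), labels,
                         canon, discarded, min_cluster_size)


def cluster_prevalence_stats(result: ClusterResult,
                             subject_of_unit: dict[str, str],
                             region_of_unit: dict[str, str],
                             subpop_of_unit: dict[str, str] | None = None,
                             alpha: float = 0.05) -> dict:
    """Leave-one-subject-out cluster-prevalence tests per region.

    For each region, the per-cluster unit count is recomputed k times, each
    time leaving out one subject, giving k samples per cluster; a
    Kruskal-Wallis test asks whether any cluster dominates, and if so the
    largest-mean cluster is compared against every other via rank-sum at a
    Bonferroni-adjusted alpha.  Discarded units are excluded throughout.
    Also emits per-cluster composition tables (region and, if given,
    subpopulation breakdowns).
    """
    subjects = sorted({subject_of_unit[u] for u in result.unit_ids})
    if len(subjects) < 3:
        raise ValueError("need >= 3 subjects for leave-one-out statistics")
    rows = []
    for lab, members in result.clusters.items():
        for i in members:
            uid = result.unit_ids[i]
            rows.append(
                {
                    "unit_id": uid,
                    "cluster": lab,
                    "subject": subject_of_unit[uid],
                    "region": region_of_unit[uid],
                    "subpopulation": (subpop_of_unit or {}).get(uid, ""),
                }
            )
    assign = pd.DataFrame(rows)
    report: dict = {"regions": {}, "composition": {}}
    if assign.empty:
        return report
    report["composition"]["region"] = pd.crosstab(assign["cluster"],
                                                  assign["region"])
    if subpop_of_unit is not None:
        report["composition"]["subpopulation"] = pd.crosstab(
            assign["cluster"], assign["subpopulation"]
        )
    for region, sub in assign.groupby("region"):
        labs = sorted(sub["cluster"].unique())
        if len(labs) < 2:
            report["regions"][region] = PrevalenceTestResult(0.0, 1.0, False)
            continue
        loo = pd.DataFrame(
            {
                lab: [
                    int(((sub["cluster"] == lab) & (sub["subject"] != s)).sum())
                    for s in subjects
                ]
                for lab in labs
            },
            index=subjects,
        )
        groups = {lab: loo[lab].to_numpy(dtype=float) for lab in labs}
        report["regions"][region] = kruskal_with_posthoc(groups, alpha=alpha)
        report.setdefault("loo_counts", {})[region] = loo
    return report
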