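"""End-to-end orchestration: simulate/load -> behavior -> phototag ->
categorization -> trajectories -> phasic clustering -> tonic clustering.

Every stage writes plain-text CSV reports into the output directory and
contributes to a machine-readable summary; the effective configuration and
seeds are echoed alongside so every number is reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, clustering, ensemble, phototag, tonic, trajectories
from .core import Session
from .io import read_session, write_session
from .synthetic import SimConfig, simulate_study

log = logging.getLogger("pavlophys")

STAGES = (
    "simulate",
    "behavior",
    "phototag",
    "categorize",
    "trajectories",
    "cluster_phasic",
    "cluster_tonic",
)

_KNOWN_KEYS = {
    "simulate",
    "sessions",
    "output_dir",
    "seed",
    "bin_width_trajectories_s",
    "bin_width_clustering_s",
    "psth_window",
    "baseline_window",
    "smooth_bins_two_condition",
    "smooth_bins_four_condition",
    "cutoff_two_condition",
    "cutoff_tonic",
    "min_cluster_size",
    "tonic_smoothing_factor",
    "ci_level",
    "log_level",
}


@dataclasses.dataclass
class RunConfig:
    """Pipeline configuration; unknown keys are rejected."""

    output_dir: str = "pavlophys_out"
    seed: int = 0
    simulate: dict | None = None
    sessions: list[str] | None = None
    bin_width_trajectories_s: float = 0.05
    bin_width_clustering_s: float = 0.1
    psth_window: tuple[float, float] = (-2.0, 6.0)
    baseline_window: tuple[float, float] = (-2.0, 0.0)
    smooth_bins_two_condition: int = 25
    smooth_bins_four_condition: int = 10
    cutoff_two_condition: float = clustering.CUTOFF_PRESETS["two_condition"]
    cutoff_tonic: float = clustering.CUTOFF_PRESETS["tonic"]
    min_cluster_size: int = 3
    tonic_smoothing_factor: float = 0.85
    ci_level: float = 0.95
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("psth_window", "baseline_window"):
            if key in d:
                d[key] = tuple(float(v) for v in d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["psth_window"] = list(self.psth_window)
        d["baseline_window"] = list(self.baseline_window)
        return d


def _load_sessions(config: RunConfig) -> tuple[list[Session], pd.DataFrame | None]:
    if config.simulate is not None:
        sim = SimConfig(**{**config.simulate, "seed": config.simulate.get(
            "seed", config.seed)})
        log.info("simulating %d subjects (seed %d)", sim.n_subjects, sim.seed)
        return simulate_study(sim)
    if config.sessions:
        return [read_session(p) for p in config.sessions], None
    raise ValueError("configuration needs either a simulate block or sessions")


def _pooled_zpsth(sessions: list[Session], conditions: dict[str, dict[str, np.ndarray]],
                  bin_width: float, window, baseline_window):
    """Per-subject z-PSTH matrices on a shared unit set.

    ``conditions`` maps condition name -> {subject -> event times}.  Units
    removed by z-scoring in any condition are dropped everywhere.
    Returns ``(data_by_subject, edges, unit_ids_by_subject)``.
    """
    data: dict[str, dict[str, np.ndarray]] = {}
    ids: dict[str, list[str]] = {}
    edges = None
    for s in sessions:
        per_cond = {}
        kept: set[str] | None = None
        for cond, ev_by_subj in conditions.items():
            ev = ev_by_subj.get(s.subject_id)
            if ev is None or len(ev) == 0:
                kept = set()
                continue
            z = ensemble.zscore_smooth(
                ensemble.compute_psth(s.spikes, ev, bin_width, window,
                                      condition=cond),
                baseline_window, smooth_bins=0,
            )
            edges = z.edges
            per_cond[cond] = dict(zip(z.unit_ids, z.values))
            kept = set(z.unit_ids) if kept is None else kept & set(z.unit_ids)
        if not kept:
            continue
        order = [u.unit_id for u in s.spikes if u.unit_id in kept]
        data[s.subject_id] = {
            cond: np.vstack([per_cond[cond][u] for u in order])
            for cond in per_cond
        }
        ids[s.subject_id] = order
    return data, edges, ids


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns (and writes) the summary."""
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    summary: dict = {"stages_completed": [], "seed": config.seed}

    # ---- stage: simulate / load ------------------------------------------
    sessions, ground_truth = _load_sessions(config)
    if ground_truth is not None:
        ground_truth.to_csv(out / "ground_truth.csv", index=False)
        for s in sessions:
            write_session(s, out / "sessions" / s.subject_id)
    summary["n_sessions"] = len(sessions)
    summary["n_units"] = int(sum(len(s.spikes) for s in sessions))
    summary["stages_completed"].append("simulate")

    # ---- stage: behavior --------------------------------------------------
    rows = []
    outcomes_by_subject: dict[str, pd.Series] = {}
    for i, s in enumerate(sessions):
        counts = behavior.per_trial_lick_counts(s.licks, s.trials)
        cE = counts[counts["cs_type"] == "E"].reset_index(drop=True)
        cA = counts[counts["cs_type"] == "A"].reset_index(drop=True)
        outcome = behavior.assess_learning(
            cE, cA, "discrimination", seed=config.seed + i
        )
        outcomes_by_subject[s.subject_id] = behavior.classify_trial_outcomes(
            s.licks, s.trials
        )
        for name in outcome.subset_p:
            rows.append(
                {
                    "subject": s.subject_id,
                    "mode": outcome.mode,
                    "subset": name,
                    "p_value": outcome.subset_p[name],
                    "pass": outcome.subset_pass[name],
                    "anticipatory_rate": outcome.anticipatory_response_rate,
                    "learned": outcome.learned,
                }
            )
    behavior_table = pd.DataFrame(rows)
    behavior_table.to_csv(out / "behavior.csv", index=False)
    learned = behavior_table.groupby("subject")["learned"].first()
    summary["fraction_learned"] = float(learned.mean())
    summary["stages_completed"].append("behavior")

    # ---- stage: phototag --------------------------------------------------
    tag_tables = []
    for s in sessions:
        if len(s.laser) == 0:
            continue
        tag_tables.append(phototag.classify_session_units(s))
    tags = (pd.concat(tag_tables, ignore_index=True)
            if tag_tables else pd.DataFrame())
    tags.to_csv(out / "phototag.csv", index=False)
    if len(tags):
        summary["phototag_counts"] = tags["label"].value_counts().to_dict()
    if ground_truth is not None and len(tags):
        merged = tags.merge(ground_truth, on="unit_id", suffixes=("", "_true"))
        mgn = merged[merged["region"] == "MGN"]
        true_tag = mgn["subpopulation"] == "MGN_to_BLA"
        called = mgn["label"] == "MGN_to_BLA"
        if true_tag.any():
            summary["phototag_sensitivity"] = float(
                (called & true_tag).sum() / true_tag.sum()
            )
        if (~true_tag).any():
            summary["phototag_false_positive_rate"] = float(
                (called & ~true_tag).sum() / (~true_tag).sum()
            )
    subpop = (dict(zip(tags["unit_id"], tags["label"]))
              if len(tags) else {})
    summary["stages_completed"].append("phototag")

    # ---- stage: categorize ------------------------------------------------
    cat_rows = []
    for s in sessions:
        csE = s.cs_onsets("E")
        csA = s.cs_onsets("A")
        us_all = s.trials["us_onset_s"].to_numpy(dtype=float)
        for u in s.spikes:
            resp = ensemble.classify_responsiveness(u, s.cs_onsets(), us_all)
            cat_rows.append(
                {
                    "unit_id": u.unit_id,
                    "subject": u.subject,
                    "region": u.region,
                    "responsiveness": resp.label,
                    "valence_category": ensemble.classify_valence_category(
                        u, csE, csA
                    ),
                }
            )
    categories = pd.DataFrame(cat_rows)
    categories.to_csv(out / "categories.csv", index=False)
    summary["valence_category_counts"] = (
        categories["valence_category"].value_counts().to_dict()
    )
    summary["stages_completed"].append("categorize")

    # ---- stage: trajectories (per region, CS-E vs CS-A) -------------------
    conditions = {
        "CS-E": {s.subject_id: s.cs_onsets("E") for s in sessions},
        "CS-A": {s.subject_id: s.cs_onsets("A") for s in sessions},
    }
    summary["trajectories"] = {}
    for region in ("MGN", "BLA"):
        region_sessions = [
            Session(s.subject_id, s.trials, s.units_in_region(region),
                    s.licks, s.laser, metadata=dict(s.metadata))
            for s in sessions
        ]
        region_sessions = [s for s in region_sessions if s.spikes]
        if len(region_sessions) < 3:
            continue
        data, edges, _ = _pooled_zpsth(
            region_sessions, conditions, config.bin_width_trajectories_s,
            config.psth_window, config.baseline_window,
        )
        if len(data) < 3:
            continue
        geom = trajectories.trajectory_geometry(
            data, edges, n_components=3,
            smooth_bins=config.smooth_bins_two_condition,
        )
        report = trajectories.compare_geometry(geom)
        pd.DataFrame(
            {f"length_{c}": v for c, v in geom.lengths.items()}
        ).to_csv(out / f"trajectory_lengths_{region}.csv", index=False)
        summary["trajectories"][region] = {
            "length_p": report["length"]["p_value"]
            if isinstance(report["length"], dict)
            else report["length"].kw_p,
            "mean_length": {c: float(v.mean()) for c, v in geom.lengths.items()},
            "pre_vs_post_p": {
                "-".join(pair): r["p_value"]
                for pair, r in report["pre_vs_post"].items()
            },
        }
    summary["stages_completed"].append("trajectories")

    # ---- stage: phasic clustering -----------------------------------------
    feats = []
    feat_ids: list[str] = []
    subject_of: dict[str, str] = {}
    region_of: dict[str, str] = {}
    for s in sessions:
        fm = clustering.build_feature_matrix(
            s.spikes,
            {"CS-E": s.cs_onsets("E"), "CS-A": s.cs_onsets("A")},
            bin_width_s=config.bin_width_clustering_s,
            window=config.psth_window,
            baseline_window=config.baseline_window,
        )
        feats.append(fm.values)
        feat_ids.extend(fm.unit_ids)
        for u in s.spikes:
            subject_of[u.unit_id] = u.subject
            region_of[u.unit_id] = u.region
    X = np.vstack(feats)
    phasic = clustering.ward_cut(X, config.cutoff_two_condition,
                                 config.min_cluster_size, unit_ids=feat_ids)
    pd.DataFrame(
        {"unit_id": feat_ids, "cluster": phasic.labels}
    ).to_csv(out / "phasic_clusters.csv", index=False)
    summary["n_phasic_clusters"] = phasic.n_clusters
    summary["n_phasic_discarded"] = len(phasic.discarded)
    try:
        prev = clustering.cluster_prevalence_stats(
            phasic, subject_of, region_of, subpop_of_unit=subpop or None
        )
        summary["phasic_prevalence_p"] = {
            reg: r.kw_p for reg, r in prev["regions"].items()
        }
    except ValueError as exc:
        log.warning("phasic prevalence statistics skipped: %s", exc)
    summary["stages_completed"].append("cluster_phasic")

    # ---- stage: tonic clustering ------------------------------------------
    series_by_unit: dict[str, tonic.TrialCountSeries] = {}
    series_list = []
    for s in sessions:
        for u in s.spikes:
            ts = tonic.trial_window_counts(u, s.trials)
            series_by_unit[u.unit_id] = ts
            series_list.append(ts)
    Z, kept, removed, _ = tonic.normalize_trial_series(
        series_list, config.tonic_smoothing_factor
    )
    tresult = tonic.cluster_trial_series(
        Z, kept, config.cutoff_tonic, config.min_cluster_size
    )
    treport = tonic.tonic_change_report(tresult, series_by_unit,
                                        ci_level=config.ci_level)
    treport.to_csv(out / "tonic_regression.csv", index=False)
    pd.DataFrame({"unit_id": kept, "cluster": tresult.labels}).to_csv(
        out / "tonic_clusters.csv", index=False
    )
    summary["n_tonic_clusters"] = tresult.n_clusters
    summary["n_tonic_removed_units"] = len(removed)
    flagged = treport[treport["change"]]
    summary["n_tonic_flagged_clusters"] = int(flagged["cluster"].nunique())
    summary["stages_completed"].append("cluster_tonic")

    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
    log.info("pipeline complete: %d/%d stages",
             len(summary["stages_completed"]), len(STAGES))
    return summary
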