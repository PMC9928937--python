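"""Ground-truth-labeled synthetic sessions for the discrimination task.

Every downstream stage of the pipeline can be exercised on sessions produced
here: spike trains are inhomogeneous-Poisson realizations of phasic response
templates (cue-locked excitation/inhibition with optional sustained tone
components), licking is Poisson with an elevated anticipatory rate for
"learner" subjects, MGN->BLA projector units respond to laser pulses at a
short controllable latency, and a configurable fraction of units carries a
linear across-trial tonic drift.

Defaults follow the discrimination-session design: 75 reward (CS-E) and 35
punishment (CS-A) trials per session, a 4 s tone, US delivery jittered
1-1.5 s after cue onset, and inter-trial intervals of 20 +/- 4 s (read as
uniform on [16, 24] s).  A phototagging epoch (1 s pulses, then 5 ms pulses
at 1, 10, and 20 Hz) is appended after the last trial, within the same
session.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import Session, SpikeTrain, validate_trials

__all__ = [
    "PhasicEffect",
    "ResponseTemplate",
    "SimConfig",
    "default_templates",
    "generate_trial_table",
    "simulate_unit",
    "simulate_licks",
    "simulate_study",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class PhasicEffect:
    """Cue-locked rate transient: amplitude (Hz, signed), onset latency (s),
    exponential decay constant (s)."""

    amplitude_hz: float = 0.0
    latency_s: float = 0.0
    decay_s: float = 0.3


@dataclass(frozen=True)
class ResponseTemplate:
    """Phasic response profile a simulated unit is drawn from.

    ``sustained_e_hz`` / ``sustained_a_hz`` add a constant rate offset for
    the duration of the corresponding tone.
    """

    label: str
    cue_e: PhasicEffect = PhasicEffect()
    cue_a: PhasicEffect = PhasicEffect()
    sustained_e_hz: float = 0.0
    sustained_a_hz: float = 0.0

    def valence_category(self) -> str:
        """A-priori valence label implied by the template's cue effects."""
        def sign(eff: PhasicEffect, sustained: float) -> str:
            v = eff.amplitude_hz if eff.amplitude_hz != 0 else sustained
            if v > 0:
                return "+"
            if v < 0:
                return "-"
            return ""

        e = sign(self.cue_e, self.sustained_e_hz)
        a = sign(self.cue_a, self.sustained_a_hz)
        label = (f"E{e}" if e else "") + (f"A{a}" if a else "")
        return label or "none"


def default_templates(baseline_rate_hz: float = 8.0) -> list[ResponseTemplate]:
    """Phasic profiles emulating the functional cluster shapes seen in the
    recorded populations: excitation/inhibition to either or both cues, with
    and without sustained tone components, plus a non-responsive profile."""
    exc = lambda a, tau=0.3: PhasicEffect(a, 0.01, tau)  # noqa: E731
    inh = lambda a, tau=0.4: PhasicEffect(-a, 0.01, tau)  # noqa: E731
    b = baseline_rate_hz
    return [
        ResponseTemplate("arousal_exc", cue_e=exc(2.5 * b), cue_a=exc(2.5 * b)),
        ResponseTemplate("arousal_inh", cue_e=inh(0.8 * b), cue_a=inh(0.8 * b)),
        ResponseTemplate("valence_E", cue_e=exc(2.5 * b), cue_a=inh(0.8 * b)),
        ResponseTemplate("valence_A", cue_e=inh(0.8 * b), cue_a=exc(2.5 * b)),
        ResponseTemplate(
            "sustained_exc",
            cue_e=exc(1.5 * b, 1.0),
            cue_a=exc(1.5 * b, 1.0),
            sustained_e_hz=0.5 * b,
            sustained_a_hz=0.5 * b,
        ),
        ResponseTemplate("reward_only", cue_e=exc(2.5 * b)),
        ResponseTemplate("punish_only", cue_a=exc(2.5 * b)),
        ResponseTemplate("flat"),
    ]


@dataclass(frozen=True)
class SimConfig:
    """Study-level simulation parameters (defaults are the task design)."""

    n_subjects: int = 3
    units_per_subpop: dict = field(
        default_factory=lambda: {
            "MGN_untagged": 14,
            "MGN_to_BLA": 8,
            "BLA_out": 12,
            "BLA_in": 6,
        }
    )
    n_reward_trials: int = 75
    n_punish_trials: int = 35
    tone_duration_s: float = 4.0
    us_jitter_s: tuple[float, float] = (1.0, 1.5)
    iti_center_s: float = 20.0
    iti_halfwidth_s: float = 4.0
    baseline_rate_hz: float = 8.0
    response_templates: tuple[ResponseTemplate, ...] = ()
    tonic_slope_spikes_per_trial: float = 0.05
    tonic_fraction: float = 0.2
    lick_rate_iti_hz: float = 1.0
    lick_rate_anticip_hz: float = 6.0
    tag_latency_ms: tuple[float, float] = (3.0, 8.0)
    tag_reliability: float = 0.9
    innet_latency_ms: tuple[float, float] = (15.0, 40.0)
    innet_reliability: float = 0.8
    n_tag_pulses: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 0 or self.n_reward_trials < 0 or self.n_punish_trials < 0:
            raise ConfigurationError("counts must be non-negative")
        if any(v < 0 for v in self.units_per_subpop.values()):
            raise ConfigurationError("unit counts must be non-negative")
        lo, hi = self.us_jitter_s
        if not (0 < lo <= hi < self.tone_duration_s):
            raise ConfigurationError(
                "us_jitter_s must lie within (0, tone_duration_s)"
            )
        if not (0 <= self.iti_halfwidth_s < self.iti_center_s):
            raise ConfigurationError("ITI halfwidth must be < center (ITIs > 0)")
        for r in (
            self.baseline_rate_hz,
            self.lick_rate_iti_hz,
            self.lick_rate_anticip_hz,
        ):
            if r < 0:
                raise ConfigurationError("rates must be non-negative")
        if not (0 <= self.tag_reliability <= 1 and 0 <= self.innet_reliability <= 1):
            raise ConfigurationError("reliabilities must be probabilities")
        if not (0 <= self.tonic_fraction <= 1):
            raise ConfigurationError("tonic_fraction must be in [0, 1]")

    def templates(self) -> list[ResponseTemplate]:
        if self.response_templates:
            return list(self.response_templates)
        return default_templates(self.baseline_rate_hz)


def generate_trial_table(config: SimConfig, seed: int) -> pd.DataFrame:
    """Pseudorandomly interleaved trial table.

    CS types are a seeded shuffle of ``n_reward_trials`` E labels and
    ``n_punish_trials`` A labels.  Each US onset is the CS onset plus a
    uniform draw from the jitter interval; consecutive CS onsets are
    separated by the tone duration plus a uniform ITI draw.
    """
    rng = np.random.default_rng(seed)
    n_e, n_a = config.n_reward_trials, config.n_punish_trials
    types = np.array(["E"] * n_e + ["A"] * n_a)
    if types.size == 0:
        return pd.DataFrame(columns=["trial", "cs_type", "cs_onset_s", "us_onset_s"])
    rng.shuffle(types)
    lo, hi = config.us_jitter_s
    iti_lo = config.iti_center_s - config.iti_halfwidth_s
    iti_hi = config.iti_center_s + config.iti_halfwidth_s
    n = types.size
    gaps = rng.uniform(iti_lo, iti_hi, size=n)  # gap before each trial
    cs = np.empty(n)
    t = gaps[0]
    for i in range(n):
        if i > 0:
            t = cs[i - 1] + config.tone_duration_s + gaps[i]
        cs[i] = t
    us = cs + rng.uniform(lo, hi, size=n)
    table = pd.DataFrame(
        {
            "trial": np.arange(n),
            "cs_type": types,
            "cs_onset_s": cs,
            "us_onset_s": us,
        }
    )
    validate_trials(table)
    return table


def _rate_function(template: ResponseTemplate, baseline: float,
                   tonic_slope_hz_per_trial: float, trials: pd.DataFrame,
                   tone_duration_s: float):
    """Return ``rate(t)`` (vectorized, Hz, rectified at 0) and an upper bound.

    The instantaneous rate is baseline + the cue-locked phasic kernel of the
    current trial's CS type + a sustained term during the tone + a tonic
    term ``slope * trial_index`` applied across the whole trial epoch
    (epochs partition the session at CS onsets minus 5 s).
    """
    cs = trials["cs_onset_s"].to_numpy(dtype=float)
    is_e = (trials["cs_type"] == "E").to_numpy()
    bounds = cs - 5.0  # epoch boundaries; ITIs are >= 16 s so never overlap

    def phasic(dt: np.ndarray, eff: PhasicEffect) -> np.ndarray:
        out = np.zeros_like(dt)
        m = dt >= eff.latency_s
        if eff.amplitude_hz != 0:
            out[m] = eff.amplitude_hz * np.exp(
                -(dt[m] - eff.latency_s) / max(eff.decay_s, 1e-9)
            )
        return out

    def rate(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        r = np.full(t.shape, baseline)
        if cs.size:
            idx = np.clip(np.searchsorted(bounds, t, side="right") - 1, 0, cs.size - 1)
            r = r + tonic_slope_hz_per_trial * idx
            dt = t - cs[idx]
            e_mask = is_e[idx]
            active = dt >= 0
            r = np.where(
                active & e_mask, r + phasic(dt, template.cue_e), r
            )
            r = np.where(
                active & ~e_mask, r + phasic(dt, template.cue_a), r
            )
            in_tone = active & (dt < tone_duration_s)
            r = np.where(in_tone & e_mask, r + template.sustained_e_hz, r)
            r = np.where(in_tone & ~e_mask, r + template.sustained_a_hz, r)
        return np.maximum(r, 0.0)

    n_trials = max(len(trials), 1)
    bound = (
        baseline
        + max(0.0, tonic_slope_hz_per_trial) * n_trials
        + max(0.0, template.cue_e.amplitude_hz, template.cue_a.amplitude_hz)
        + max(0.0, template.sustained_e_hz, template.sustained_a_hz)
    )
    return rate, max(bound, 1e-12)


def _poisson_thinning(rate, rate_max: float, t_stop: float,
                      rng: np.random.Generator, t_start: float = 0.0) -> np.ndarray:
    """Inhomogeneous-Poisson spike times on [t_start, t_stop) by thinning."""
    span = t_stop - t_start
    if span <= 0 or rate_max <= 0:
        return np.empty(0)
    n_cand = rng.poisson(rate_max * span)
    if n_cand == 0:
        return np.empty(0)
    cand = np.sort(rng.uniform(t_start, t_stop, size=n_cand))
    keep = rng.uniform(0, rate_max, size=n_cand) < rate(cand)
    return cand[keep]


def session_end_time(trials: pd.DataFrame, tone_duration_s: float = 4.0,
                     tail_s: float = 10.0) -> float:
    if len(trials) == 0:
        return tail_s
    return float(trials["cs_onset_s"].iloc[-1] + tone_duration_s + tail_s)


def simulate_unit(template: ResponseTemplate, baseline: float,
                  tonic_slope: float, trials: pd.DataFrame, seed: int,
                  tone_duration_s: float = 4.0,
                  t_stop: Optional[float] = None) -> np.ndarray:
    """Inhomogeneous-Poisson spike times for one unit over the session.

    ``tonic_slope`` is in spikes/trial measured over a 1 s window, i.e. the
    unit's rate increases by ``tonic_slope`` Hz per trial.
    """
    if baseline < 0:
        raise ConfigurationError("baseline rate must be non-negative")
    rng = np.random.default_rng(seed)
    if t_stop is None:
        t_stop = session_end_time(trials, tone_duration_s)
    rate, rmax = _rate_function(template, baseline, tonic_slope, trials,
                                tone_duration_s)
    return _poisson_thinning(rate, rmax, t_stop, rng)


def simulate_licks(trials: pd.DataFrame, iti_rate: float, anticip_rate: float,
                   seed: int, a_anticip_rate: Optional[float] = None,
                   t_stop: Optional[float] = None) -> np.ndarray:
    """Poisson lick events: ``iti_rate`` everywhere except the anticipatory
    windows, which use ``anticip_rate`` on E trials (and ``a_anticip_rate``,
    defaulting to ``iti_rate``, on A trials)."""
    if iti_rate < 0 or anticip_rate < 0:
        raise ConfigurationError("lick rates must be non-negative")
    if a_anticip_rate is None:
        a_anticip_rate = iti_rate
    rng = np.random.default_rng(seed)
    if t_stop is None:
        t_stop = session_end_time(trials)
    cs = trials["cs_onset_s"].to_numpy(dtype=float)
    us = trials["us_onset_s"].to_numpy(dtype=float)
    is_e = (trials["cs_type"] == "E").to_numpy()

    def rate(t: np.ndarray) -> np.ndarray:
        r = np.full(np.asarray(t).shape, float(iti_rate))
        if cs.size:
            idx = np.clip(np.searchsorted(cs, t, side="right") - 1, 0, cs.size - 1)
            in_anticip = (t >= cs[idx]) & (t < us[idx])
            r = np.where(in_anticip & is_e[idx], anticip_rate, r)
            r = np.where(in_anticip & ~is_e[idx], a_anticip_rate, r)
        return r

    rmax = max(iti_rate, anticip_rate, a_anticip_rate)
    return _poisson_thinning(rate, rmax, t_stop, rng)


def _laser_epoch(start_s: float, n_tag_pulses: int) -> pd.DataFrame:
    """Photostimulation schedule: 1 s pulses, then 5 ms pulses at 1, 10,
    and 20 Hz (tagging classification uses the 5 ms 1 Hz block)."""
    rows = []
    t = start_s
    for _ in range(5):  # 1 s pulses, one every 5 s
        rows.append((t, 1.0, 0.2))
        t += 5.0
    t += 5.0
    for _ in range(n_tag_pulses):  # 5 ms at 1 Hz
        rows.append((t, 0.005, 1.0))
        t += 1.0
    t += 5.0
    for _ in range(50):  # 5 ms at 10 Hz
        rows.append((t, 0.005, 10.0))
        t += 0.1
    t += 5.0
    for _ in range(50):  # 5 ms at 20 Hz
        rows.append((t, 0.005, 20.0))
        t += 0.05
    return pd.DataFrame(rows, columns=["onset_s", "width_s", "freq_hz"])


def _evoked_spikes(pulses: np.ndarray, latency_ms: float, reliability: float,
                   rng: np.random.Generator, jitter_ms: float = 0.5) -> np.ndarray:
    """Light-evoked spikes: per pulse, one spike at onset + latency with the
    given per-pulse reliability; small Gaussian latency jitter."""
    if pulses.size == 0:
        return np.empty(0)
    fired = rng.uniform(size=pulses.size) < reliability
    lat = (latency_ms + jitter_ms * rng.standard_normal(pulses.size)) / 1000.0
    return pulses[fired] + np.maximum(lat[fired], 5e-4)


def simulate_study(config: SimConfig) -> tuple[list[Session], pd.DataFrame]:
    """Simulate ``n_subjects`` sessions plus a per-unit ground-truth table.

    Every unit is labeled with one of the four circuit subpopulations
    (MGN untagged, MGN->BLA projector, out-of-network BLA, in-network BLA);
    projector and in-network units receive light-evoked spikes during the
    appended laser epoch.  Fully reproducible from ``config.seed``.
    """
    root = np.random.SeedSequence(config.seed)
    subject_seqs = root.spawn(config.n_subjects)
    templates = config.templates()
    sessions: list[Session] = []
    gt_rows = []
    for s_idx, sseq in enumerate(subject_seqs):
        subject = f"sub{s_idx:02d}"
        seeds = sseq.generate_state(4)
        trials = generate_trial_table(config, int(seeds[0]))
        t_stop_trials = session_end_time(trials, config.tone_duration_s)
        laser = _laser_epoch(t_stop_trials + 10.0, config.n_tag_pulses)
        t_stop = float(laser["onset_s"].iloc[-1] + 5.0) if len(laser) else t_stop_trials
        tag_pulses = laser.loc[
            np.isclose(laser["width_s"], 0.005) & np.isclose(laser["freq_hz"], 1.0),
            "onset_s",
        ].to_numpy()
        licks = simulate_licks(
            trials,
            config.lick_rate_iti_hz,
            config.lick_rate_anticip_hz,
            int(seeds[1]),
            t_stop=t_stop_trials,
        )
        unit_rng = np.random.default_rng(int(seeds[2]))
        spike_seq = np.random.SeedSequence(int(seeds[3]))
        spikes: list[SpikeTrain] = []
        u_counter = 0
        for subpop in ("MGN_untagged", "MGN_to_BLA", "BLA_out", "BLA_in"):
            n_units = config.units_per_subpop.get(subpop, 0)
            region = "MGN" if subpop.startswith("MGN") else "BLA"
            for _ in range(n_units):
                unit_id = f"{subject}_u{u_counter:03d}"
                u_counter += 1
                template = templates[unit_rng.integers(len(templates))]
                drifts = unit_rng.uniform() < config.tonic_fraction
                slope = config.tonic_slope_spikes_per_trial if drifts else 0.0
                uspikes = simulate_unit(
                    template,
                    config.baseline_rate_hz,
                    slope,
                    trials,
                    int(spike_seq.spawn(1)[0].generate_state(1)[0]),
                    config.tone_duration_s,
                    t_stop=t_stop,
                )
                tag_latency = np.nan
                if subpop == "MGN_to_BLA":
                    tag_latency = unit_rng.uniform(*config.tag_latency_ms)
                    ev = _evoked_spikes(tag_pulses, tag_latency,
                                        config.tag_reliability, unit_rng)
                    uspikes = np.sort(np.concatenate([uspikes, ev]))
                elif subpop == "BLA_in":
                    tag_latency = unit_rng.uniform(*config.innet_latency_ms)
                    ev = _evoked_spikes(tag_pulses, tag_latency,
                                        config.innet_reliability, unit_rng,
                                        jitter_ms=3.0)
                    uspikes = np.sort(np.concatenate([uspikes, ev]))
                spikes.append(SpikeTrain(unit_id, subject, region, uspikes))
                gt_rows.append(
                    {
                        "unit_id": unit_id,
                        "subject": subject,
                        "subpopulation": subpop,
                        "template": template.label,
                        "valence_category": template.valence_category(),
                        "tonic_slope": slope,
                        "tag_latency_ms": tag_latency,
                    }
                )
        sessions.append(
            Session(
                subject_id=subject,
                trials=trials,
                spikes=spikes,
                licks=licks,
                laser=laser,
                metadata={"seed": config.seed, "subject_index": s_idx},
            )
        )
    ground_truth = pd.DataFrame(gt_rows)
    return sessions, ground_truth
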