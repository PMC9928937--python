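"""Plain-text session container: a directory of CSV tables plus metadata.

Layout (all times in seconds from session start):

    units.csv   unit_id, subject, region, channel
    spikes.csv  unit_id, time_s
    trials.csv  trial, cs_type, cs_onset_s, us_onset_s
    licks.csv   time_s
    laser.csv   onset_s, width_s, freq_hz
    metadata.yaml  format version, subject_id, generator seed, free-form keys

CSV dialect: comma-separated, header row, UTF-8, '.' decimal.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import Session, SpikeTrain, validate_trials

FORMAT_VERSION = 1

_TABLES = {
    "units": ["unit_id", "subject", "region", "channel"],
    "spikes": ["unit_id", "time_s"],
    "trials": ["trial", "cs_type", "cs_onset_s", "us_onset_s"],
    "licks": ["time_s"],
    "laser": ["onset_s", "width_s", "freq_hz"],
}


class SessionFormatError(ValueError):
    """Raised when a session directory fails to parse."""


def write_session(session: Session, path: str | os.PathLike) -> Path:
    """Write a session to ``path`` (created if needed); returns the path."""
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    units = pd.DataFrame(
        [
            {
                "unit_id": u.unit_id,
                "subject": u.subject,
                "region": u.region,
                "channel": u.channel,
            }
            for u in session.spikes
        ],
        columns=_TABLES["units"],
    )
    spikes = pd.DataFrame(
        {
            "unit_id": np.repeat(
                [u.unit_id for u in session.spikes],
                [u.n_spikes for u in session.spikes],
            )
            if session.spikes
            else [],
            "time_s": np.concatenate([u.times for u in session.spikes])
            if session.spikes
            else [],
        }
    )
    units.to_csv(p / "units.csv", index=False)
    spikes.to_csv(p / "spikes.csv", index=False, float_format="%.6f")
    session.trials.to_csv(p / "trials.csv", index=False)
    pd.DataFrame({"time_s": session.licks}).to_csv(
        p / "licks.csv", index=False, float_format="%.6f"
    )
    session.laser.to_csv(p / "laser.csv", index=False)
    meta = {
        "format_version": FORMAT_VERSION,
        "subject_id": session.subject_id,
        **session.metadata,
    }
    with open(p / "metadata.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return p


def _read_table(path: Path, name: str) -> pd.DataFrame:
    f = path / f"{name}.csv"
    if not f.exists():
        raise SessionFormatError(f"missing table: {f}")
    try:
        df = pd.read_csv(f)
    except Exception as exc:  # noqa: BLE001 - reported with file context
        raise SessionFormatError(f"{f}: failed to parse ({exc})") from exc
    missing = set(_TABLES[name]) - set(df.columns)
    if missing:
        raise SessionFormatError(f"{f}: missing columns {sorted(missing)}")
    return df


def _numeric(df: pd.DataFrame, col: str, fname: str) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(vals))
    if bad.size:
        raise SessionFormatError(
            f"{fname}: non-numeric {col} at row {int(bad[0]) + 2}"
        )
    return vals


def read_session(path: str | os.PathLike) -> Session:
    """Read a session directory; lossless inverse of :func:`write_session`."""
    p = Path(path)
    if not p.is_dir():
        raise SessionFormatError(f"not a session directory: {p}")
    units = _read_table(p, "units")
    spikes = _read_table(p, "spikes")
    trials = _read_table(p, "trials")
    licks = _read_table(p, "licks")
    laser = _read_table(p, "laser")
    known = set(units["unit_id"].astype(str))
    if len(spikes):
        spike_units = spikes["unit_id"].astype(str)
        unknown = set(spike_units) - known
        if unknown:
            raise SessionFormatError(
                f"{p / 'spikes.csv'}: spikes reference unknown unit_id(s) "
                f"{sorted(unknown)[:5]}"
            )
        times = _numeric(spikes, "time_s", str(p / "spikes.csv"))
        if np.any(times < 0):
            raise SessionFormatError(f"{p / 'spikes.csv'}: negative time_s")
        by_unit = {
            uid: times[np.asarray(spike_units == uid)] for uid in known
        }
    else:
        by_unit = {uid: np.empty(0) for uid in known}
    trains = [
        SpikeTrain(
            str(r.unit_id), str(r.subject), str(r.region),
            by_unit.get(str(r.unit_id), np.empty(0)), int(r.channel),
        )
        for r in units.itertuples()
    ]
    validate_trials(trials)
    lick_times = (
        _numeric(licks, "time_s", str(p / "licks.csv")) if len(licks) else np.empty(0)
    )
    meta_file = p / "metadata.yaml"
    metadata = {}
    if meta_file.exists():
        with open(meta_file, encoding="utf-8") as fh:
            metadata = yaml.safe_load(fh) or {}
    subject_id = str(metadata.pop("subject_id", "unknown"))
    metadata.pop("format_version", None)
    return Session(
        subject_id=subject_id,
        trials=trials,
        spikes=trains,
        licks=lick_times,
        laser=laser,
        metadata=metadata,
    )
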