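"""Session persistence as paired delimited-text files.

A session directory holds:

* ``session.json`` — metadata sidecar: session/protocol info, format
  version, provenance (generator parameters and seed), and per-trial
  metadata including the delivered US schedule and generator ground truth;
* ``traces.tsv`` — long-format traces: trial_id, eye, t_ms, position_mm;
* ``spikes.tsv`` — spike events: trial_id, unit_id, time_ms, spike_type.

Columns carry explicit units in their names; tab separation, '.' decimal.
The round trip ``read_session(write_session(s)) == s`` is lossless on all
fields including seeds.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    EyelidTrace,
    PlantedCR,
    Session,
    SpikeTrain,
    TrialRecord,
    USDelivery,
)

__all__ = ["write_session", "read_session", "FORMAT_VERSION", "SessionFormatError"]

FORMAT_VERSION = "1"

TRACE_COLUMNS = ["trial_id", "eye", "t_ms", "position_mm"]
SPIKE_COLUMNS = ["trial_id", "unit_id", "time_ms", "spike_type"]


class SessionFormatError(ValueError):
    """Raised when a session on disk fails validation."""


def write_session(session: Session, path: str | Path) -> Path:
    """Write a session to a directory (created if needed)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    trace_rows = []
    spike_rows = []
    meta_trials = []
    for trial in session.trials:
        for eye, tr in sorted(trial.traces.items()):
            trace_rows.append(pd.DataFrame({
                "trial_id": trial.trial_id, "eye": eye,
                "t_ms": tr.times, "position_mm": tr.samples,
            }))
        for train in trial.spikes:
            for kind, times in (("simple", train.simple_spikes),
                                ("complex", train.complex_spikes)):
                if times.size:
                    spike_rows.append(pd.DataFrame({
                        "trial_id": trial.trial_id, "unit_id": train.unit_id,
                        "time_ms": times, "spike_type": kind,
                    }))
        meta_trials.append({
            "trial_id": trial.trial_id, "trial_type": trial.trial_type,
            "protocol": trial.protocol, "cs_on": trial.cs_on,
            "cs_off": trial.cs_off,
            "us_delivered": [asdict(u) for u in trial.us_delivered],
            "planted": [asdict(p) for p in trial.planted],
            "amp_at_us1": trial.amp_at_us1,
            "excluded": trial.excluded,
            "exclusion_reason": trial.exclusion_reason,
            "trace_t0": {eye: tr.t0 for eye, tr in sorted(trial.traces.items())},
            "calibration": {eye: tr.calibration
                            for eye, tr in sorted(trial.traces.items())},
        })

    traces = (pd.concat(trace_rows, ignore_index=True) if trace_rows
              else pd.DataFrame(columns=TRACE_COLUMNS))
    # 17 significant digits guarantee a bit-lossless float64 round trip
    traces.to_csv(path / "traces.tsv", sep="\t", index=False,
                  float_format="%.17g")
    spikes = (pd.concat(spike_rows, ignore_index=True) if spike_rows
              else pd.DataFrame(columns=SPIKE_COLUMNS))
    spikes.to_csv(path / "spikes.tsv", sep="\t", index=False,
                  float_format="%.1f")

    meta = {
        "format_version": FORMAT_VERSION,
        "session_id": session.session_id,
        "protocol": session.protocol,
        "config": session.config,
        "provenance": session.provenance,
        "trials": meta_trials,
    }
    (path / "session.json").write_text(json.dumps(meta, indent=1))
    return path


def _require_columns(df: pd.DataFrame, cols: list[str], fname: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SessionFormatError(f"{fname}: missing columns {missing}")


def read_session(path: str | Path) -> Session:
    """Load a session directory written by :func:`write_session`.

    Validates the format version, required columns and uniform 1 ms
    sampling of every trace; failures name the offending trial and field.
    """
    path = Path(path)
    meta_path = path / "session.json"
    if not meta_path.exists():
        raise SessionFormatError(f"{meta_path} not found")
    meta = json.loads(meta_path.read_text())
    version = meta.get("format_version")
    if version is None:
        raise SessionFormatError(
            "session.json lacks a format_version field; re-export the session "
            "with a current writer or add the field manually")
    if version != FORMAT_VERSION:
        raise SessionFormatError(
            f"format version {version!r} not supported (expected {FORMAT_VERSION!r})")

    traces = pd.read_csv(path / "traces.tsv", sep="\t",
                         float_precision="round_trip")
    _require_columns(traces, TRACE_COLUMNS, "traces.tsv")
    spikes_path = path / "spikes.tsv"
    spikes = pd.read_csv(spikes_path, sep="\t") if spikes_path.exists() \
        else pd.DataFrame(columns=SPIKE_COLUMNS)
    if len(spikes):
        _require_columns(spikes, SPIKE_COLUMNS, "spikes.tsv")

    by_trial_eye = dict(tuple(traces.groupby(["trial_id", "eye"], sort=True)))
    spike_groups = (dict(tuple(spikes.groupby(["trial_id", "unit_id"], sort=True)))
                    if len(spikes) else {})

    trials = []
    for tm in meta["trials"]:
        tid = tm["trial_id"]
        eyes = {}
        for eye, t0 in tm.get("trace_t0", {}).items():
            grp = by_trial_eye.get((tid, eye))
            if grp is None:
                raise SessionFormatError(
                    f"traces.tsv: no samples for trial {tid} eye {eye}")
            t = grp["t_ms"].to_numpy()
            if t.size < 2 or not np.allclose(np.diff(t), 1.0):
                raise SessionFormatError(
                    f"traces.tsv: non-uniform sampling on trial {tid} eye {eye} "
                    f"near t = {t[np.argmax(np.abs(np.diff(t) - 1.0))]:.1f} ms")
            eyes[eye] = EyelidTrace(
                samples=grp["position_mm"].to_numpy(), t0=float(t[0]), eye=eye,
                calibration=float(tm.get("calibration", {}).get(eye, 1.0)))
        spike_list = []
        for (gtid, unit), grp in spike_groups.items():
            if gtid != tid:
                continue
            spike_list.append(SpikeTrain(
                unit_id=str(unit),
                simple_spikes=np.sort(
                    grp.loc[grp.spike_type == "simple", "time_ms"].to_numpy()),
                complex_spikes=np.sort(
                    grp.loc[grp.spike_type == "complex", "time_ms"].to_numpy()),
                trial_id=tid))
        trials.append(TrialRecord(
            trial_id=tid, trial_type=tm["trial_type"], protocol=tm["protocol"],
            cs_on=tm["cs_on"], cs_off=tm["cs_off"], traces=eyes,
            us_delivered=[USDelivery(**u) for u in tm["us_delivered"]],
            spikes=spike_list,
            planted=[PlantedCR(**p) for p in tm.get("planted", [])],
            amp_at_us1=tm.get("amp_at_us1"),
            excluded=tm.get("excluded", False),
            exclusion_reason=tm.get("exclusion_reason", "none")))

    return Session(session_id=meta["session_id"], protocol=meta["protocol"],
                   trials=trials, config=meta.get("config", {}),
                   provenance=meta.get("provenance", {}),
                   format_version=version)
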