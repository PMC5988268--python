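"""Session (de)serialization.

A session is a directory of diff-able text files:

* ``manifest.json`` -- format version, monkey ids, provenance (generator
  config, seed, ground truth when synthetic).
* ``scenes.csv``, ``trials.csv``, ``units.csv`` -- one row per record.
* ``spikes.csv`` -- long format ``unit_id,trial_id,t_ms``.
* ``eye/<trial_id>.csv`` -- ``t_ms,x,y,pupil`` (missing pupil = empty field).
* ``pulses.csv`` -- ``trial_id,t_ms`` cardiac pulse times.

Floats are written with Python's shortest round-trip repr so a
read(write(session)) reproduces every timestamp bit-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (EyeTrace, SceneDef, Session, SessionValidationError,
                    SpikeTrain, Trial, UnitRecord)

FORMAT_VERSION = 1

_EVENT_COLUMNS = ("fix_start", "object_onset", "saccade_onset", "outcome_time")


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return ""
    return repr(float(x))


def _write_csv(path: Path, header: list, rows) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(",".join(header) + "\n")
        for row in rows:
            fh.write(",".join(row) + "\n")


def write_session(session: Session, path) -> None:
    """Serialize ``session`` to directory ``path`` (created if needed)."""
    session.validate()
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)

    manifest = {
        "format_version": FORMAT_VERSION,
        "provenance": session.provenance,
    }
    with open(root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    _write_csv(root / "scenes.csv",
               ["scene_id", "context", "reward_volume", "has_robber",
                "has_distractor", "airpuff_on_fail"],
               ([s.scene_id, s.context, _fmt(s.reward_volume),
                 str(int(s.has_robber)), str(int(s.has_distractor)),
                 str(int(s.airpuff_on_fail))] for s in session.scenes))

    _write_csv(root / "trials.csv",
               ["trial_id", "scene_id", "monkey_id", "first_object_value",
                "object_context", "outcome", "is_repeat", "target_angle_deg",
                *_EVENT_COLUMNS],
               ([t.trial_id, t.scene_id, t.monkey_id, t.first_object_value,
                 t.object_context, t.outcome, str(int(t.is_repeat)),
                 _fmt(t.target_angle_deg),
                 *[_fmt(t.events.get(c)) for c in _EVENT_COLUMNS]]
                for t in session.trials))

    _write_csv(root / "units.csv",
               ["unit_id", "monkey_id", "ap_mm", "ml_mm", "depth_mm",
                "background_fr", "unit_class"],
               ([u.unit_id, u.monkey_id, _fmt(u.coords[0]), _fmt(u.coords[1]),
                 _fmt(u.coords[2]), _fmt(u.background_fr), u.unit_class]
                for u in session.units))

    _write_csv(root / "spikes.csv", ["unit_id", "trial_id", "t_ms"],
               ([st.unit_id, st.trial_id, _fmt(t)]
                for st in session.spike_trains for t in st.spike_times))

    _write_csv(root / "pulses.csv", ["trial_id", "t_ms"],
               ([tid, _fmt(t)]
                for tid, times in sorted(session.pulse_times.items())
                for t in times))

    eye_dir = root / "eye"
    eye_dir.mkdir(exist_ok=True)
    for tr in session.eye_traces:
        with open(eye_dir / f"{tr.trial_id}.csv", "w", newline="") as fh:
            fh.write(f"# sample_rate={_fmt(tr.sample_rate)}\n")
            fh.write("t_ms,x,y,pupil\n")
            times = tr.times
            for i in range(len(tr.x)):
                fh.write(f"{_fmt(times[i])},{_fmt(tr.x[i])},"
                         f"{_fmt(tr.y[i])},{_fmt(tr.pupil[i])}\n")


def _require(root: Path, name: str) -> Path:
    p = root / name
    if not p.exists():
        raise SessionValidationError(f"{name.split('.')[0]}: missing")
    return p


def read_session(path) -> Session:
    """Load a session directory written by :func:`write_session`."""
    root = Path(path)
    with open(_require(root, "manifest.json")) as fh:
        manifest = json.load(fh)

    scenes_df = pd.read_csv(_require(root, "scenes.csv"), dtype={"scene_id": str},
                            float_precision="round_trip")
    scenes = [SceneDef(scene_id=r.scene_id, context=r.context,
                       reward_volume=float(r.reward_volume),
                       has_robber=bool(r.has_robber),
                       has_distractor=bool(r.has_distractor),
                       airpuff_on_fail=bool(r.airpuff_on_fail))
              for r in scenes_df.itertuples()]

    trials_df = pd.read_csv(_require(root, "trials.csv"),
                            dtype={"trial_id": str, "scene_id": str,
                                   "monkey_id": str},
                            float_precision="round_trip")
    trials = []
    for r in trials_df.itertuples():
        events = {"scene_onset": 0.0}
        for c in _EVENT_COLUMNS:
            v = getattr(r, c)
            if pd.notna(v):
                events[c] = float(v)
        trials.append(Trial(trial_id=r.trial_id, scene_id=r.scene_id,
                            monkey_id=r.monkey_id,
                            first_object_value=r.first_object_value,
                            object_context=r.object_context,
                            outcome=r.outcome, is_repeat=bool(r.is_repeat),
                            target_angle_deg=float(r.target_angle_deg),
                            events=events))

    units_df = pd.read_csv(_require(root, "units.csv"),
                           dtype={"unit_id": str, "monkey_id": str},
                           float_precision="round_trip")
    units = [UnitRecord(unit_id=r.unit_id, monkey_id=r.monkey_id,
                        coords=(float(r.ap_mm), float(r.ml_mm),
                                float(r.depth_mm)),
                        background_fr=float(r.background_fr),
                        unit_class=r.unit_class)
             for r in units_df.itertuples()]

    spikes_df = pd.read_csv(_require(root, "spikes.csv"),
                            dtype={"unit_id": str, "trial_id": str},
                            float_precision="round_trip")
    spike_trains = []
    if len(spikes_df):
        for (uid, tid), grp in spikes_df.groupby(
                ["unit_id", "trial_id"], sort=False):
            spike_trains.append(SpikeTrain(
                unit_id=uid, trial_id=tid,
                spike_times=grp["t_ms"].to_numpy(dtype=float)))

    pulses_df = pd.read_csv(_require(root, "pulses.csv"),
                            dtype={"trial_id": str},
                            float_precision="round_trip")
    pulse_times = {tid: grp["t_ms"].to_numpy(dtype=float)
                   for tid, grp in pulses_df.groupby("trial_id", sort=False)}

    eye_traces = []
    eye_dir = root / "eye"
    if eye_dir.exists():
        for p in sorted(eye_dir.glob("*.csv")):
            with open(p) as fh:
                first = fh.readline().strip()
            if not first.startswith("# sample_rate="):
                raise SessionValidationError(
                    f"eye/{p.name}: missing sample_rate header")
            sample_rate = float(first.split("=", 1)[1])
            df = pd.read_csv(p, skiprows=1, float_precision="round_trip")
            eye_traces.append(EyeTrace(
                trial_id=p.stem, sample_rate=sample_rate,
                t0_ms=float(df["t_ms"].iloc[0]) if len(df) else 0.0,
                x=df["x"].to_numpy(dtype=float),
                y=df["y"].to_numpy(dtype=float),
                pupil=df["pupil"].to_numpy(dtype=float)))

    session = Session(scenes=scenes, trials=trials, eye_traces=eye_traces,
                      spike_trains=spike_trains, units=units,
                      pulse_times=pulse_times,
                      provenance=manifest.get("provenance", {}))
    session.validate()
    return session
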