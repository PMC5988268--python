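"""Domain types and window conventions for foraging-task sessions.

All times are in milliseconds relative to scene onset; analysis windows are
half-open ``[a, b)`` so a spike at a boundary is counted exactly once.
The three scene contexts are

* ``D/R`` -- dangerous (a robber object may appear) and rich (0.3 mL reward),
* ``S/R`` -- safe and rich,
* ``S/P`` -- safe and poor (0.1 mL reward).

The fourth cell (dangerous and poor) does not exist in the task design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

CONTEXTS = ("D/R", "S/R", "S/P")
#: Reward volume (mL) for rich vs poor scenes.
REWARD_RICH = 0.3
REWARD_POOR = 0.1

OUTCOMES = ("rewarded", "no_reward", "robbed", "fixation_break")
OBJECT_VALUES = ("good", "bad")
OBJECT_CONTEXTS = ("robber_present", "distractor_present", "absent")
UNIT_CLASSES = ("excited", "inhibited", "other", "unclassified")

#: Baseline window, ms relative to scene onset (half-open).
BASELINE_WINDOW = (-500.0, 0.0)


class SessionValidationError(ValueError):
    """A record violated the session schema; message names record and field."""


@dataclass(frozen=True)
class SceneDef:
    """One visual scene (environment) and its context attributes."""

    scene_id: str
    context: str
    reward_volume: float
    has_robber: bool
    has_distractor: bool = False
    airpuff_on_fail: bool = False

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise SessionValidationError(
                f"scene {self.scene_id}: context {self.context!r} not in {CONTEXTS}")
        if self.reward_volume not in (REWARD_RICH, REWARD_POOR):
            raise SessionValidationError(
                f"scene {self.scene_id}: reward_volume must be "
                f"{REWARD_POOR} or {REWARD_RICH}")
        if self.has_robber != (self.context == "D/R"):
            raise SessionValidationError(
                f"scene {self.scene_id}: has_robber must hold exactly for D/R")
        if self.has_robber and self.has_distractor:
            raise SessionValidationError(
                f"scene {self.scene_id}: robber and distractor are exclusive")
        if self.context == "D/R" and self.reward_volume != REWARD_RICH:
            raise SessionValidationError(
                f"scene {self.scene_id}: dangerous scenes are rich (0.3 mL)")


@dataclass(frozen=True)
class Trial:
    """One foraging trial; event times in ms relative to scene onset."""

    trial_id: str
    scene_id: str
    monkey_id: str
    events: dict
    first_object_value: str
    object_context: str = "absent"
    outcome: str = "rewarded"
    is_repeat: bool = False
    target_angle_deg: float = 0.0

    _SEQUENCE = ("scene_onset", "fix_start", "object_onset",
                 "saccade_onset", "outcome_time")

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise SessionValidationError(
                f"trial {self.trial_id}: outcome {self.outcome!r} invalid")
        if self.first_object_value not in OBJECT_VALUES:
            raise SessionValidationError(
                f"trial {self.trial_id}: first_object_value invalid")
        if self.object_context not in OBJECT_CONTEXTS:
            raise SessionValidationError(
                f"trial {self.trial_id}: object_context invalid")
        ev = self.events
        if ev.get("scene_onset", 0.0) != 0.0:
            raise SessionValidationError(
                f"trial {self.trial_id}: scene_onset must be 0")
        # fix_start = 0 (fixation acquired at scene onset) yields an empty FV
        # window and is tolerated; everything after must strictly increase.
        seq = [ev[name] for name in self._SEQUENCE[1:] if name in ev
               and ev[name] is not None]
        if any(b <= a for a, b in zip(seq, seq[1:])):
            raise SessionValidationError(
                f"trial {self.trial_id}: event times must strictly increase "
                f"along {self._SEQUENCE}")
        if "fix_start" in ev and ev["fix_start"] < 0:
            raise SessionValidationError(
                f"trial {self.trial_id}: fix_start must be >= 0")

    @property
    def fix_start(self) -> float:
        return self.events["fix_start"]

    @property
    def object_onset(self) -> float:
        return self.events["object_onset"]


@dataclass(frozen=True)
class EyeTrace:
    """1 kHz gaze position (deg) and pupil diameter for one trial.

    ``t0_ms`` is the time of the first sample; missing pupil samples are
    NaN (the storage sentinel; never interpolated here).
    """

    trial_id: str
    sample_rate: float
    t0_ms: float
    x: np.ndarray
    y: np.ndarray
    pupil: np.ndarray

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise SessionValidationError(
                f"eye trace {self.trial_id}: sample_rate must be > 0")
        n = len(self.x)
        if len(self.y) != n or len(self.pupil) != n:
            raise SessionValidationError(
                f"eye trace {self.trial_id}: x, y, pupil lengths differ")

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms relative to scene onset."""
        return self.t0_ms + np.arange(len(self.x)) * 1000.0 / self.sample_rate


@dataclass(frozen=True)
class SpikeTrain:
    """Spike timestamps (ms, strictly increasing) for one unit on one trial."""

    unit_id: str
    trial_id: str
    spike_times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times, dtype=float)
        if t.ndim != 1:
            raise SessionValidationError(
                f"spike train {self.unit_id}/{self.trial_id}: 1-D times required")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise SessionValidationError(
                f"spike train {self.unit_id}/{self.trial_id}: "
                "spike_times must strictly increase")
        object.__setattr__(self, "spike_times", t)


@dataclass(frozen=True)
class UnitRecord:
    """One recorded unit: identity, class, coordinates, background rate.

    ``coords`` is (AP mm posterior to the anterior commissure, ML mm,
    depth mm below the anterior commissure).
    """

    unit_id: str
    monkey_id: str
    coords: tuple
    background_fr: float
    unit_class: str = "unclassified"

    def __post_init__(self) -> None:
        if self.unit_class not in UNIT_CLASSES:
            raise SessionValidationError(
                f"unit {self.unit_id}: unit_class {self.unit_class!r} invalid")
        if self.coords[2] <= 0:
            raise SessionValidationError(
                f"unit {self.unit_id}: depth must be > 0")
        if self.background_fr < 0:
            raise SessionValidationError(
                f"unit {self.unit_id}: background_fr must be >= 0")

    @property
    def depth(self) -> float:
        return self.coords[2]


@dataclass(frozen=True)
class AnalysisWindows:
    """Baseline / free-viewing (FV) / fixation (FX) windows for one trial."""

    baseline: tuple = BASELINE_WINDOW
    fv: tuple = (0.0, 1080.0)
    fx: tuple = (1080.0, 1860.0)


@dataclass
class Session:
    """A coherent bundle of scenes, trials, traces, spike trains and units."""

    scenes: list
    trials: list
    eye_traces: list
    spike_trains: list
    units: list
    pulse_times: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def scene(self, scene_id: str) -> SceneDef:
        return self._scene_index[scene_id]

    def trial(self, trial_id: str) -> Trial:
        return self._trial_index[trial_id]

    @property
    def _scene_index(self) -> dict:
        return {s.scene_id: s for s in self.scenes}

    @property
    def _trial_index(self) -> dict:
        return {t.trial_id: t for t in self.trials}

    def context_of_trial(self, trial: Trial) -> str:
        return self.scene(trial.scene_id).context

    def validate(self) -> None:
        """Check cross-reference integrity; raise on the first violation."""
        scene_ids = {s.scene_id for s in self.scenes}
        trial_ids = [t.trial_id for t in self.trials]
        if len(set(trial_ids)) != len(trial_ids):
            raise SessionValidationError("trials: duplicate trial_id")
        trial_id_set = set(trial_ids)
        for t in self.trials:
            if t.scene_id not in scene_ids:
                raise SessionValidationError(
                    f"trial {t.trial_id}: unknown scene_id {t.scene_id!r}")
        for tr in self.eye_traces:
            if tr.trial_id not in trial_id_set:
                raise SessionValidationError(
                    f"eye trace references unknown trial {tr.trial_id!r}")
        seen = set()
        for st in self.spike_trains:
            if st.trial_id not in trial_id_set:
                raise SessionValidationError(
                    f"spike train {st.unit_id!r} references unknown trial "
                    f"{st.trial_id!r}")
            key = (st.unit_id, st.trial_id)
            if key in seen:
                raise SessionValidationError(
                    f"duplicate spike train for unit {st.unit_id!r}, "
                    f"trial {st.trial_id!r}")
            seen.add(key)
        unit_ids = {u.unit_id for u in self.units}
        for st in self.spike_trains:
            if st.unit_id not in unit_ids:
                raise SessionValidationError(
                    f"spike train references unknown unit {st.unit_id!r}")
        for tid in self.pulse_times:
            if tid not in trial_id_set:
                raise SessionValidationError(
                    f"pulses reference unknown trial {tid!r}")


def trial_windows(trial: Trial) -> AnalysisWindows:
    """Return the baseline/FV/FX half-open windows for one trial.

    FV runs from scene onset to fixation start (canonically 1,080 ms), FX
    from fixation start to object onset (canonically 780 ms).
    """
    ev = trial.events
    for name in ("fix_start", "object_onset"):
        if name not in ev or ev[name] is None:
            raise SessionValidationError(
                f"trial {trial.trial_id}: missing event {name!r}")
    fix_start, object_onset = ev["fix_start"], ev["object_onset"]
    if object_onset < fix_start:
        raise SessionValidationError(
            f"trial {trial.trial_id}: object_onset < fix_start")
    return AnalysisWindows(baseline=BASELINE_WINDOW,
                           fv=(0.0, float(fix_start)),
                           fx=(float(fix_start), float(object_onset)))
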