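"""Stimulus schedules for plate-based behavioral trials.

A :class:`StimulusSchedule` is an ordered list of light events plus an
acclimation period.  Three standard paradigms are supported:

``dark_light_cycles``
    Baseline locomotion assay: alternating 5-min dark / 5-min light phases
    over 25 min (starting dark), after a lights-on acclimation.

``flash_series``
    Photosensitive-seizure induction: five 1-s light flashes separated by
    49 s of darkness, after a lights-on acclimation.

``continuous_light``
    Chemoconvulsant (PTZ) trial: 15 min of continuous light after a dark
    acclimation.

Times are seconds from recording start.  Flash events carry a duration
(1 s by default); ``light_on`` / ``light_off`` events toggle the ambient
illumination state used by the simulator and by per-phase summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import ValidationError

__all__ = ["LightEvent", "StimulusSchedule", "read_schedule", "write_schedule"]

_KINDS = ("light_on", "light_off", "flash")


@dataclass(frozen=True)
class LightEvent:
    kind: str
    time: float
    duration: float = 0.0

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValidationError(f"unknown event kind {self.kind!r}")
        if not np.isfinite(self.time) or self.time < 0:
            raise ValidationError(f"event time must be finite and >= 0, got {self.time}")
        if self.kind == "flash" and self.duration <= 0:
            raise ValidationError("flash events require a positive duration")


@dataclass
class StimulusSchedule:
    events: list[LightEvent] = field(default_factory=list)
    paradigm: str | None = None
    acclimation: float = 0.0
    duration: float = 0.0

    def __post_init__(self):
        times = [e.time for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValidationError("schedule events must be in non-decreasing time order")
        if self.events:
            end = max(e.time + e.duration for e in self.events)
            self.duration = max(self.duration, end)

    # ------------------------------------------------------------------ #
    # constructors

    @classmethod
    def flash_series(cls, start: float = 600.0, n_flashes: int = 5,
                     flash_duration: float = 1.0, darkness: float = 49.0,
                     acclimation: float = 600.0) -> "StimulusSchedule":
        """Flash paradigm: lights-on acclimation, then darkness with
        ``n_flashes`` flashes of ``flash_duration`` s separated by
        ``darkness`` s (flash onsets every ``flash_duration + darkness`` s)."""
        if start < acclimation:
            raise ValidationError("flash series must start after the acclimation phase")
        events = [LightEvent("light_on", 0.0), LightEvent("light_off", acclimation)]
        period = flash_duration + darkness
        for i in range(n_flashes):
            events.append(LightEvent("flash", start + i * period, flash_duration))
        sched = cls(events=events, paradigm="flash_series", acclimation=acclimation)
        sched.duration = start + (n_flashes - 1) * period + flash_duration + darkness
        return sched

    @classmethod
    def dark_light_cycles(cls, start: float = 600.0, phase: float = 300.0,
                          n_phases: int = 5, acclimation: float = 600.0) -> "StimulusSchedule":
        """Alternating dark/light phases (starting dark) after a lights-on
        acclimation; defaults give 5 x 5-min phases over 25 min."""
        events = [LightEvent("light_on", 0.0)]
        t = start
        for i in range(n_phases):
            events.append(LightEvent("light_off" if i % 2 == 0 else "light_on", t))
            t += phase
        sched = cls(events=events, paradigm="dark_light_cycles", acclimation=acclimation)
        sched.duration = t
        return sched

    @classmethod
    def continuous_light(cls, start: float = 600.0, duration: float = 900.0,
                         acclimation: float = 600.0) -> "StimulusSchedule":
        """Continuous-light trial (default 15 min) after a dark acclimation."""
        events = [LightEvent("light_off", 0.0), LightEvent("light_on", start)]
        sched = cls(events=events, paradigm="continuous_light", acclimation=acclimation)
        sched.duration = start + duration
        return sched

    # ------------------------------------------------------------------ #
    # queries

    def flashes(self) -> list[LightEvent]:
        return [e for e in self.events if e.kind == "flash"]

    def flash_times(self) -> np.ndarray:
        return np.asarray([e.time for e in self.flashes()], dtype=float)

    def is_dark(self, t) -> np.ndarray:
        """Ambient darkness state at time(s) ``t`` (flash pulses count as
        light for their duration)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        # ambient state from on/off toggles; default light before any event
        times, states = [0.0], [False]
        for e in self.events:
            if e.kind == "light_on":
                times.append(e.time); states.append(False)
            elif e.kind == "light_off":
                times.append(e.time); states.append(True)
        idx = np.searchsorted(np.asarray(times), t, side="right") - 1
        dark = np.asarray(states)[np.clip(idx, 0, None)]
        for e in self.flashes():
            dark = dark & ~((t >= e.time) & (t < e.time + e.duration))
        return dark

    # ------------------------------------------------------------------ #
    # serialization

    def to_dict(self) -> dict:
        return {
            "paradigm": self.paradigm,
            "acclimation": float(self.acclimation),
            "duration": float(self.duration),
            "events": [
                {"kind": e.kind, "time": float(e.time), "duration": float(e.duration)}
                for e in self.events
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "StimulusSchedule":
        """Build a schedule from a mapping; paradigm shorthands (a
        ``paradigm`` key with parameters and no explicit event list) are
        expanded to explicit events.  Expansion is idempotent: a mapping
        that already carries events is used verbatim."""
        if not isinstance(data, dict):
            raise ValidationError("schedule document must be a mapping")
        if "events" in data and data["events"]:
            events = [
                LightEvent(ev["kind"], float(ev["time"]), float(ev.get("duration", 0.0)))
                for ev in data["events"]
            ]
            sched = cls(events=events, paradigm=data.get("paradigm"),
                        acclimation=float(data.get("acclimation", 0.0)))
            if "duration" in data:
                sched.duration = max(sched.duration, float(data["duration"]))
            return sched
        paradigm = data.get("paradigm")
        params = {k: v for k, v in data.items() if k not in ("paradigm", "events", "duration")}
        builders = {
            "flash_series": cls.flash_series,
            "dark_light_cycles": cls.dark_light_cycles,
            "continuous_light": cls.continuous_light,
        }
        if paradigm not in builders:
            raise ValidationError(f"unknown paradigm {paradigm!r}")
        try:
            sched = builders[paradigm](**params)
        except TypeError as exc:
            raise ValidationError(f"bad parameters for paradigm {paradigm!r}: {exc}") from exc
        if "duration" in data:
            sched.duration = max(sched.duration, float(data["duration"]))
        return sched


def read_schedule(path) -> StimulusSchedule:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return StimulusSchedule.from_dict(data)


def write_schedule(schedule: StimulusSchedule, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(schedule.to_dict(), fh, sort_keys=False)
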