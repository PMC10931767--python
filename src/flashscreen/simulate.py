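"""Synthetic larval tracking data with known ground truth.

The locomotion model is a discrete beat-and-glide swimmer sampled on a
regular frame grid: bout onsets follow a discretized Poisson process whose
rate depends on ambient illumination (dark > light, emulating the
stereotyped dark/light locomotion pattern of 120 hpf larvae), per-bout
speed is a truncated normal, and heading performs a random walk updated at
each bout.  The well wall is a reflective disc boundary, which also
reproduces the wall-following look of normal trajectories.

Each light flash triggers one of two response modes, drawn Bernoulli with
the group's seizure probability:

* **startle** (normal): an immediate bout whose speed is scaled by
  ``startle_gain``, and bout speeds amplified for the response window;
* **seizure-like**: a sustained high-speed crossing of the well with
  frequent large (>= 90 deg) heading reversals for ``seizure_duration``
  seconds — the erratic, direction-changing trajectory that the
  classifier is meant to pick out.

Every Bernoulli draw is recorded in a ground-truth table so downstream
stages can be scored against the truth.  Per-well random streams are
derived from the master seed and the well id only, so plate simulation is
independent of well processing order.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .platemap import PlateMap
from .schedule import StimulusSchedule
from .track import Track

__all__ = ["SimParams", "simulate_track", "simulate_plate", "well_rng"]


@dataclass(frozen=True)
class SimParams:
    """Simulator parameters for one experimental group.

    Rates are per second, speeds mm/s, angles degrees.  ``ptz_dose_gain``
    maps a chemoconvulsant dose (mM) to an activity multiplier applied to
    bout rate and bout speed; ``activity_gain`` is the resolved multiplier
    for this group (see :meth:`with_dose`).
    """

    sample_rate: float = 25.0          # Hz; typical plate-tracker range
    arena_radius: float = 5.5          # mm, 48-well plate well
    bout_rate_light: float = 0.8       # bouts/s under illumination
    bout_rate_dark: float = 1.6        # bouts/s in darkness
    bout_speed_mean: float = 25.0      # mm/s burst speed
    bout_speed_sd: float = 6.0
    bout_duration: float = 0.2         # s of movement per bout
    heading_sd: float = 35.0           # deg random-walk step per bout
    startle_gain: float = 1.8          # speed multiplier, 2 s post-flash
    seizure_speed_mean: float = 70.0   # mm/s sustained during seizure mode
    seizure_speed_sd: float = 10.0
    seizure_turn_rate: float = 4.0     # heading reversals/s
    seizure_duration: float = 2.0      # s
    p_seizure: float = 0.0             # per flash per larva
    activity_gain: float = 1.0
    ptz_dose_gain: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        numeric = {
            "sample_rate": self.sample_rate, "arena_radius": self.arena_radius,
            "bout_rate_light": self.bout_rate_light, "bout_rate_dark": self.bout_rate_dark,
            "bout_speed_mean": self.bout_speed_mean, "bout_speed_sd": self.bout_speed_sd,
            "bout_duration": self.bout_duration, "heading_sd": self.heading_sd,
            "startle_gain": self.startle_gain, "seizure_speed_mean": self.seizure_speed_mean,
            "seizure_speed_sd": self.seizure_speed_sd,
            "seizure_turn_rate": self.seizure_turn_rate,
            "seizure_duration": self.seizure_duration, "activity_gain": self.activity_gain,
        }
        for name, value in numeric.items():
            if not np.isfinite(value) or value < 0:
                raise ValidationError(f"SimParams.{name} must be finite and >= 0, got {value}")
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be > 0")
        if self.arena_radius <= 0:
            raise ValidationError("arena_radius must be > 0")
        if not 0.0 <= self.p_seizure <= 1.0:
            raise ValidationError(f"p_seizure must be in [0, 1], got {self.p_seizure}")

    def with_dose(self, dose: float) -> "SimParams":
        """Resolve ``ptz_dose_gain`` for a given dose into ``activity_gain``."""
        if not self.ptz_dose_gain or dose in (None, ""):
            return self
        dose = float(dose)
        gains = {float(k): float(v) for k, v in self.ptz_dose_gain.items()}
        if dose in gains:
            return replace(self, activity_gain=self.activity_gain * gains[dose])
        if dose == 0.0:
            return self
        raise ValidationError(f"no dose->gain entry for dose {dose}")


def well_rng(master_seed: int, well_id: str) -> np.random.Generator:
    """Deterministic per-well random stream, independent of well order.

    Keyed on ``(master_seed, crc32(well_id))`` through a SeedSequence so
    identical (seed, well) pairs always yield identical streams.
    """
    key = zlib.crc32(str(well_id).encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(int(master_seed), spawn_key=(key,)))


def _truncated_speeds(rng, mean, sd, size):
    """Speed draws from a normal truncated at zero."""
    if sd == 0:
        return np.full(size, float(mean))
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


# --------------------------------------------------------------------------- #
# position integration with a reflective disc boundary

def _integrate_py(speed, dheading, dt, radius, x0, y0, heading0):
    n = speed.shape[0]
    xs = np.empty(n); ys = np.empty(n)
    x, y, heading = x0, y0, heading0
    r2max = radius * radius
    for i in range(n):
        heading += dheading[i]
        if speed[i] > 0.0:
            step = speed[i] * dt
            vx = step * math.cos(heading)
            vy = step * math.sin(heading)
            nx = x + vx
            ny = y + vy
            if nx * nx + ny * ny > r2max:
                r = math.sqrt(x * x + y * y)
                if r > 1e-12:
                    ux, uy = x / r, y / r
                else:
                    rr = math.sqrt(nx * nx + ny * ny)
                    ux, uy = nx / rr, ny / rr
                dot = vx * ux + vy * uy
                vx -= 2.0 * dot * ux
                vy -= 2.0 * dot * uy
                heading = math.atan2(vy, vx)
                nx = x + vx
                ny = y + vy
                rr2 = nx * nx + ny * ny
                if rr2 > r2max:
                    s = radius / math.sqrt(rr2) * 0.999
                    nx *= s
                    ny *= s
            x, y = nx, ny
        xs[i] = x
        ys[i] = y
    return xs, ys


try:  # jit-compile the integration loop when numba is available
    from numba import njit
    _integrate = njit(cache=False)(_integrate_py)
except Exception:  # pragma: no cover - numba is a declared dependency
    _integrate = _integrate_py


# --------------------------------------------------------------------------- #

def simulate_track(params: SimParams, schedule: StimulusSchedule,
                   duration: float | None = None,
                   rng: np.random.Generator | int | None = None,
                   subject_id: str = "sim", well_id: str = "w1"):
    """Simulate one larva; returns ``(Track, ground_truth_frame)``.

    ``ground_truth_frame`` has one row per flash with the Bernoulli
    seizure draw.  Identical parameters, schedule and seed give
    bit-identical output.
    """
    if duration is None:
        duration = schedule.duration
    if duration < schedule.duration:
        raise ValidationError(
            f"duration {duration}s does not cover the schedule ({schedule.duration}s)")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(params.seed if rng is None else int(rng))

    rate = params.sample_rate
    dt = 1.0 / rate
    n = int(round(duration * rate)) + 1
    t = np.arange(n) * dt
    gain = params.activity_gain

    dark = schedule.is_dark(t)
    bout_rate = np.where(dark, params.bout_rate_dark, params.bout_rate_light) * gain
    onsets = np.flatnonzero(rng.random(n) < np.clip(bout_rate * dt, 0.0, 1.0))

    speed = np.zeros(n)
    dheading = np.zeros(n)
    bout_len = max(1, int(round(params.bout_duration * rate)))
    if onsets.size:
        bout_speeds = _truncated_speeds(
            rng, params.bout_speed_mean * gain, params.bout_speed_sd * gain, onsets.size)
        turns = rng.normal(0.0, math.radians(params.heading_sd), size=onsets.size)
        for i, sp, dh in zip(onsets, bout_speeds, turns):
            stop = min(i + bout_len, n)
            np.maximum(speed[i:stop], sp, out=speed[i:stop])
            dheading[i] += dh

    # flash responses
    gt_rows = []
    win_len = max(1, int(round(params.seizure_duration * rate)))
    for k, ev in enumerate(schedule.flashes(), start=1):
        i0 = int(round(ev.time * rate))
        if i0 >= n:
            raise ValidationError("flash beyond simulated duration")
        seizure = bool(rng.random() < params.p_seizure)
        i1 = min(i0 + win_len, n)
        if seizure:
            m = i1 - i0
            speed[i0:i1] = _truncated_speeds(
                rng, params.seizure_speed_mean * gain, params.seizure_speed_sd * gain, m)
            dheading[i0:i1] = 0.0
            rev = rng.random(m) < min(params.seizure_turn_rate * dt, 1.0)
            rev[0] = m > 1  # erratic mode kicks off with a direction change
            signs = rng.choice((-1.0, 1.0), size=int(rev.sum()))
            angles = rng.uniform(math.radians(120.0), math.radians(180.0), size=int(rev.sum()))
            dheading[i0:i1][rev] += signs * angles
        else:
            # startle: amplify in-window bouts and guarantee an immediate bout
            speed[i0:i1] *= params.startle_gain
            sp = float(_truncated_speeds(
                rng, params.bout_speed_mean * gain, params.bout_speed_sd * gain, 1)[0])
            sp *= params.startle_gain
            stop = min(i0 + bout_len, n)
            np.maximum(speed[i0:stop], sp, out=speed[i0:stop])
            dheading[i0] += rng.normal(0.0, math.radians(params.heading_sd))
        gt_rows.append({"subject_id": subject_id, "flash_index": k,
                        "t_flash": float(ev.time), "seizure_flag": seizure})

    # start at a uniform point in the inner disc, random initial heading
    r0 = params.arena_radius * 0.8 * math.sqrt(rng.random())
    phi0 = rng.uniform(0.0, 2.0 * math.pi)
    heading0 = rng.uniform(0.0, 2.0 * math.pi)
    xs, ys = _integrate(speed, dheading, dt, params.arena_radius,
                        r0 * math.cos(phi0), r0 * math.sin(phi0), heading0)

    track = Track(subject_id, well_id, t, xs, ys, rate, arena_radius=params.arena_radius)
    return track, pd.DataFrame(gt_rows, columns=["subject_id", "flash_index",
                                                 "t_flash", "seizure_flag"])


def simulate_plate(plate_map: PlateMap, schedule: StimulusSchedule,
                   params_by_group: dict, rng_seed: int = 0,
                   duration: float | None = None):
    """Simulate every occupied well of a plate.

    Returns ``(tracks, ground_truth)`` where ``ground_truth`` has one row
    per (subject, flash) with the seizure draw and the subject's group.
    Per-well seeds derive from ``rng_seed`` and the well id only, so the
    result is independent of row order in the plate map.
    """
    missing = [g for g in plate_map.groups if g not in params_by_group]
    if missing:
        raise ValidationError(f"groups without simulator parameters: {missing}")
    tracks, gts = [], []
    for row in plate_map.entries.itertuples(index=False):
        params = params_by_group[row.group_label]
        dose = getattr(row, "dose", 0.0)
        if params.ptz_dose_gain and dose not in ("", None):
            params = params.with_dose(float(dose) if dose == dose else 0.0)
        rng = well_rng(rng_seed, row.well_id)
        track, gt = simulate_track(params, schedule, duration=duration, rng=rng,
                                   subject_id=row.subject_id, well_id=row.well_id)
        gt = gt.assign(group_label=row.group_label)
        tracks.append(track)
        gts.append(gt)
    ground_truth = pd.concat(gts, ignore_index=True) if gts else pd.DataFrame()
    return tracks, ground_truth
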