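"""Per-frame and per-window kinematic readouts from centroid tracks.

All quantities derive from finite differences of the centroid position:

* ``speed``  — step displacement times the sample rate (mm/s);
* ``accel``  — first difference of speed times the sample rate (mm/s^2);
* ``heading`` — direction of the step vector, defined only for steps above
  a noise floor (tracking-jitter guard, default 0.05 mm);
* ``heading_change`` — wrapped to (-180, 180], defined only between two
  consecutive defined headings.

A *turn* is a maximal run of consecutive same-sign heading changes whose
summed magnitude reaches a threshold (default 90 deg); runs broken by a
sign flip or by a sub-noise-floor step count separately.  Mobility states
are a centroid proxy for tracker-defined mobility: per-frame displacement
as a percentage of a reference body length (default 4 mm, a 120 hpf
larva), partitioned into immobile / mobile / highly-mobile frames.

Everything is invariant under rigid rotation and translation of the
coordinate frame.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .schedule import StimulusSchedule
from .track import Track

__all__ = [
    "frame_kinematics", "count_turns", "mobility_states",
    "extract_flash_responses", "total_distance", "max_velocity",
    "per_minute_distance", "FEATURE_COLUMNS",
]

#: default noise floor below which a step carries no heading information (mm)
NOISE_FLOOR_MM = 0.05
#: reference body length for the mobility proxy (mm)
BODY_LENGTH_MM = 4.0
#: mobility state cuts (% of body length per frame)
IMMOBILE_CUT = 20.0
HIGH_CUT = 60.0
#: default turn threshold (deg)
TURN_THRESHOLD_DEG = 90.0
#: dropout tolerance inside an analysis window (frames)
MAX_DROPOUT_FRAMES = 5

FEATURE_COLUMNS = [
    "max_velocity", "max_acceleration", "angular_velocity", "n_turns",
    "mobility_pct", "dur_immobile", "dur_mobile", "dur_highly_mobile",
]


def frame_kinematics(track: Track, noise_floor: float = NOISE_FLOOR_MM,
                     smooth: bool = False) -> pd.DataFrame:
    """Per-frame speed, acceleration, heading and heading change.

    Row ``i`` describes the step ending at frame ``i`` (forward
    difference); row 0 has zero speed and undefined heading.  With
    ``smooth=True`` a centred 3-point mean is applied to the speed series
    before differentiation of acceleration.
    """
    if len(track.t) < 3:
        raise ValidationError("track too short for kinematics (need >= 3 frames)")
    rate = track.sample_rate
    dx = np.diff(track.x)
    dy = np.diff(track.y)
    step = np.hypot(dx, dy)

    speed = np.zeros(len(track.t))
    speed[1:] = step * rate
    if smooth:
        kernel = np.array([1.0, 1.0, 1.0]) / 3.0
        speed = np.convolve(speed, kernel, mode="same")
    accel = np.zeros_like(speed)
    accel[1:] = np.diff(speed) * rate

    heading = np.full(len(track.t), np.nan)
    moving = step >= noise_floor
    heading[1:][moving] = np.degrees(np.arctan2(dy[moving], dx[moving]))

    heading_change = np.full(len(track.t), np.nan)
    both = ~np.isnan(heading[1:]) & ~np.isnan(heading[:-1])
    dh = heading[1:] - heading[:-1]
    dh = (dh + 180.0) % 360.0 - 180.0
    dh[dh == -180.0] = 180.0  # wrap to (-180, 180]
    heading_change[1:][both] = dh[both]

    return pd.DataFrame({
        "t": track.t, "speed": speed, "accel": accel,
        "heading": heading, "heading_change": heading_change,
        "step": np.concatenate(([0.0], step)),
    })


def _window_frames(track: Track, t0: float, t1: float) -> slice:
    if t1 <= t0:
        raise ValidationError("empty analysis window")
    if t0 < track.t[0] - 1e-9 or t1 > track.t[-1] + 1.0 / track.sample_rate + 1e-9:
        raise ValidationError(
            f"window [{t0}, {t1}] outside track span [{track.t[0]}, {track.t[-1]}]")
    return track.window_slice(t0, t1)


def count_turns(track: Track, window: tuple[float, float],
                angle_threshold: float = TURN_THRESHOLD_DEG,
                noise_floor: float = NOISE_FLOOR_MM,
                _frames: pd.DataFrame | None = None) -> int:
    """Number of turn events in ``window = (t0, t1)``.

    A turn is a maximal run of consecutive same-sign heading changes whose
    summed magnitude is at least ``angle_threshold`` degrees.
    """
    frames = _frames if _frames is not None else frame_kinematics(track, noise_floor)
    sl = _window_frames(track, *window)
    dh = frames["heading_change"].to_numpy()[sl]

    n_turns = 0
    acc = 0.0
    sign = 0
    for v in dh:
        if np.isnan(v) or v == 0.0:
            # run broken by a sub-noise-floor step (or no rotation)
            if abs(acc) >= angle_threshold:
                n_turns += 1
            acc, sign = 0.0, 0
            continue
        s = 1 if v > 0 else -1
        if s != sign:
            if abs(acc) >= angle_threshold:
                n_turns += 1
            acc, sign = 0.0, s
        acc += v
    if abs(acc) >= angle_threshold:
        n_turns += 1
    return n_turns


def mobility_states(track: Track, window: tuple[float, float],
                    immobile_cut: float = IMMOBILE_CUT, high_cut: float = HIGH_CUT,
                    body_length: float = BODY_LENGTH_MM,
                    _frames: pd.DataFrame | None = None) -> dict:
    """Mobility proxy over a window: percentage of body length moved per
    frame, partitioned into immobile / mobile / highly-mobile durations.

    Returns ``mobility_pct`` (percent of frames not immobile) and the
    three cumulative durations, which partition the window exactly.
    """
    if not (0.0 <= immobile_cut < high_cut <= 100.0):
        raise ValidationError(f"invalid mobility cuts ({immobile_cut}, {high_cut})")
    frames = _frames if _frames is not None else frame_kinematics(track)
    sl = _window_frames(track, *window)
    step = frames["step"].to_numpy()[sl]
    if step.size == 0:
        raise ValidationError("empty analysis window")
    proxy = np.clip(step / body_length * 100.0, 0.0, 100.0)
    immobile = proxy < immobile_cut
    high = proxy > high_cut
    mobile = ~immobile & ~high
    dt = 1.0 / track.sample_rate
    return {
        "mobility_pct": 100.0 * float((~immobile).mean()),
        "dur_immobile": float(immobile.sum()) * dt,
        "dur_mobile": float(mobile.sum()) * dt,
        "dur_highly_mobile": float(high.sum()) * dt,
    }


def total_distance(track: Track, window: tuple[float, float] | None = None,
                   _frames: pd.DataFrame | None = None) -> float:
    """Path length (mm) over a window (default: whole track)."""
    frames = _frames if _frames is not None else frame_kinematics(track)
    if window is None:
        window = (float(track.t[0]), float(track.t[-1]) + 1.0 / track.sample_rate)
    sl = _window_frames(track, *window)
    return float(frames["step"].to_numpy()[sl].sum())


def max_velocity(track: Track, window: tuple[float, float] | None = None,
                 _frames: pd.DataFrame | None = None) -> float:
    """Maximum speed (mm/s) over a window (default: whole track); dropout
    frames are excluded."""
    frames = _frames if _frames is not None else frame_kinematics(track)
    if window is None:
        window = (float(track.t[0]), float(track.t[-1]) + 1.0 / track.sample_rate)
    sl = _window_frames(track, *window)
    speed = frames["speed"].to_numpy()[sl]
    ok = track.valid[sl]
    if not ok.any():
        raise ValidationError("no valid frames in window")
    return float(speed[ok].max())


def per_minute_distance(track: Track, window: tuple[float, float] | None = None,
                        _frames: pd.DataFrame | None = None) -> pd.Series:
    """Path length binned per minute of recording time."""
    frames = _frames if _frames is not None else frame_kinematics(track)
    if window is None:
        window = (float(track.t[0]), float(track.t[-1]) + 1.0 / track.sample_rate)
    sl = _window_frames(track, *window)
    t = track.t[sl]
    step = frames["step"].to_numpy()[sl]
    minutes = np.floor(t / 60.0).astype(int)
    return pd.Series(step).groupby(minutes).sum().rename("distance_mm")


def extract_flash_responses(track: Track, schedule: StimulusSchedule,
                            window_s: float = 2.0,
                            angle_threshold: float = TURN_THRESHOLD_DEG,
                            noise_floor: float = NOISE_FLOOR_MM,
                            immobile_cut: float = IMMOBILE_CUT,
                            high_cut: float = HIGH_CUT,
                            body_length: float = BODY_LENGTH_MM) -> pd.DataFrame:
    """One feature row per flash, computed on ``[t_flash, t_flash + window_s]``.

    Returns a table with ``subject_id``, ``flash_index`` (1-based),
    ``t_flash``, the eight kinematic features and a ``valid`` flag that is
    False when the window contains a dropout gap longer than
    ``MAX_DROPOUT_FRAMES`` frames.
    """
    flashes = schedule.flashes()
    if not flashes:
        return pd.DataFrame(columns=["subject_id", "flash_index", "t_flash",
                                     *FEATURE_COLUMNS, "valid"])
    frames = frame_kinematics(track, noise_floor)
    rate = track.sample_rate
    rows = []
    for k, ev in enumerate(flashes, start=1):
        t0, t1 = float(ev.time), float(ev.time) + window_s
        sl = _window_frames(track, t0, t1)
        invalid = ~track.valid[sl]
        valid = int(invalid.sum()) <= MAX_DROPOUT_FRAMES
        speed = frames["speed"].to_numpy()[sl]
        accel = frames["accel"].to_numpy()[sl]
        dh = frames["heading_change"].to_numpy()[sl]
        defined = ~np.isnan(dh)
        ang_vel = float(np.abs(dh[defined]).mean() * rate) if defined.any() else 0.0
        mob = mobility_states(track, (t0, t1), immobile_cut, high_cut,
                              body_length, _frames=frames)
        rows.append({
            "subject_id": track.subject_id,
            "flash_index": k,
            "t_flash": t0,
            "max_velocity": float(speed.max()) if speed.size else 0.0,
            "max_acceleration": float(accel.max()) if accel.size else 0.0,
            "angular_velocity": ang_vel,
            "n_turns": count_turns(track, (t0, t1), angle_threshold,
                                   noise_floor, _frames=frames),
            **mob,
            "valid": valid,
        })
    df = pd.DataFrame(rows)
    return df[["subject_id", "flash_index", "t_flash", *FEATURE_COLUMNS, "valid"]]
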