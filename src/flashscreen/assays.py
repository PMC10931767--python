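"""Assay-level aggregation and univariate statistics.

Three plate-level behavioral assays are summarized per subject and
compared to the same-plate negative control ("scrambled") group:

* **locomotion** — total distance moved over the dark/light cycle
  paradigm, cumulative, per minute, and split by dark/light phase;
* **ptz** — maximum velocity over the continuous-light chemoconvulsant
  trial;
* **flash** — per-subject mean over the five flash responses of maximum
  velocity and turn count.

Group comparisons use classical one-way ANOVA across the groups sharing a
plate, or a two-sample t-test (Welch by default) when exactly two groups
are present.  Comparisons never cross plates: each plate carries its own
control, which is the design guard against batch effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from . import kinematics as kin
from .platemap import PlateMap
from .schedule import StimulusSchedule
from .track import Track

__all__ = ["AssayResult", "locomotion_assay", "ptz_assay", "flash_assay",
           "compare_to_control"]

#: subjects with more dropout than this fraction of frames are excluded
MAX_DROPOUT_FRACTION = 0.2


@dataclass
class AssayResult:
    """Per-subject assay summary.

    ``values`` has one row per subject with the summary columns plus
    ``subject_id``, ``group_label`` and ``plate_id``; ``per_minute`` is a
    long table (locomotion assay only).
    """

    assay: str
    values: pd.DataFrame
    per_minute: pd.DataFrame | None = None


def _meta(plate_map: PlateMap, subject_id: str) -> dict:
    tab = plate_map.subject_table()
    if subject_id not in tab.index:
        raise ValidationError(f"subject {subject_id!r} absent from plate map")
    row = tab.loc[subject_id]
    return {"group_label": str(row["group_label"]), "plate_id": str(row["plate_id"])}


def _usable(track: Track) -> bool:
    frac = 1.0 - track.valid.mean()
    if frac > MAX_DROPOUT_FRACTION:
        warnings.warn(
            f"excluding subject {track.subject_id!r}: "
            f"{100 * frac:.0f}% tracking dropout")
        return False
    return True


def locomotion_assay(tracks, schedule: StimulusSchedule,
                     plate_map: PlateMap) -> AssayResult:
    """Total distance moved over the dark/light cycle paradigm."""
    if schedule.paradigm not in (None, "dark_light_cycles"):
        raise ValidationError(
            f"locomotion assay expects a dark_light_cycles schedule, "
            f"got {schedule.paradigm!r}")
    rows, per_minute = [], []
    for track in tracks:
        if not _usable(track):
            continue
        frames = kin.frame_kinematics(track)
        total = kin.total_distance(track, _frames=frames)
        dark = schedule.is_dark(track.t)
        step = frames["step"].to_numpy()
        meta = _meta(plate_map, track.subject_id)
        rows.append({
            "subject_id": track.subject_id, **meta,
            "total_distance": total,
            "dark_distance": float(step[dark].sum()),
            "light_distance": float(step[~dark].sum()),
        })
        pm = kin.per_minute_distance(track, _frames=frames)
        per_minute.append(pd.DataFrame({
            "subject_id": track.subject_id, "minute": pm.index,
            "distance_mm": pm.to_numpy(), **meta,
        }))
    values = pd.DataFrame(rows)
    pm_df = pd.concat(per_minute, ignore_index=True) if per_minute else None
    return AssayResult("locomotion", values, pm_df)


def ptz_assay(tracks, schedule: StimulusSchedule, plate_map: PlateMap) -> AssayResult:
    """Per-subject maximum velocity over the continuous-light trial."""
    if schedule.paradigm not in (None, "continuous_light"):
        raise ValidationError(
            f"ptz assay expects a continuous_light schedule, got {schedule.paradigm!r}")
    light_on = [e.time for e in schedule.events if e.kind == "light_on"]
    t0 = light_on[-1] if light_on else 0.0
    rows = []
    for track in tracks:
        if not _usable(track):
            continue
        t1 = min(schedule.duration, float(track.t[-1]) + 1.0 / track.sample_rate)
        rows.append({
            "subject_id": track.subject_id, **_meta(plate_map, track.subject_id),
            "max_velocity": kin.max_velocity(track, (t0, t1)),
        })
    return AssayResult("ptz", pd.DataFrame(rows))


def flash_assay(responses: pd.DataFrame, plate_map: PlateMap) -> AssayResult:
    """Per-subject mean over valid flash responses of max velocity and
    turn count; subjects with no valid response are dropped with a warning."""
    if responses.empty:
        raise ValidationError("no flash responses to summarize")
    rows = []
    for subject, grp in responses.groupby("subject_id", sort=False):
        ok = grp[grp["valid"].astype(bool)] if "valid" in grp.columns else grp
        if ok.empty:
            warnings.warn(f"subject {subject!r} has no valid flash response; dropped")
            continue
        rows.append({
            "subject_id": subject, **_meta(plate_map, subject),
            "mean_max_velocity": float(ok["max_velocity"].mean()),
            "mean_n_turns": float(ok["n_turns"].mean()),
        })
    return AssayResult("flash", pd.DataFrame(rows))


def compare_to_control(result: AssayResult, value_name: str,
                       control_group: str = "scrambled",
                       equal_var: bool = False) -> pd.DataFrame:
    """Per-plate univariate comparison against the same-plate control.

    With more than two groups on a plate a one-way ANOVA across all its
    groups is reported; with exactly two, a two-sample t-test (Welch by
    default, pooled with ``equal_var=True``).  Significance convention is
    p < 0.05.  Returns one row per plate with test, statistic, df and p.
    """
    df = result.values
    if value_name not in df.columns:
        raise ValidationError(f"no column {value_name!r} in assay values")
    out = []
    for plate_id, plate in df.groupby("plate_id"):
        groups = list(pd.unique(plate["group_label"]))
        if control_group not in groups:
            raise ValidationError(f"plate {plate_id!r} lacks control group "
                                  f"{control_group!r}")
        samples = [plate.loc[plate["group_label"] == g, value_name].to_numpy(dtype=float)
                   for g in groups]
        for g, s in zip(groups, samples):
            if len(s) < 2:
                raise ValidationError(
                    f"group {g!r} on plate {plate_id!r} has n={len(s)} < 2")
        if len(groups) == 2:
            stat = stats.ttest_ind(samples[0], samples[1], equal_var=equal_var)
            out.append({
                "plate_id": plate_id, "test": "t",
                "groups": ",".join(groups), "statistic": float(stat.statistic),
                "df": float(stat.df), "p_value": float(stat.pvalue),
            })
        else:
            f = stats.f_oneway(*samples)
            n_tot = sum(len(s) for s in samples)
            out.append({
                "plate_id": plate_id, "test": "anova",
                "groups": ",".join(groups), "statistic": float(f.statistic),
                "df": float(len(groups) - 1), "df_resid": float(n_tot - len(groups)),
                "p_value": float(f.pvalue),
            })
    return pd.DataFrame(out)
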