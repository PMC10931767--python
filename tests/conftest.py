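import numpy as np
import pandas as pd
import pytest

import flashscreen as fs


def make_track(points, rate=25.0, subject="t1", well="w1", valid=None,
               arena_radius=None):
    """Track from an explicit coordinate list, frames 1/rate apart."""
    pts = np.asarray(points, dtype=float)
    t = np.arange(len(pts)) / rate
    return fs.Track(subject, well, t, pts[:, 0], pts[:, 1], rate,
                    valid=valid, arena_radius=arena_radius)


def straight_track(speed=5.0, rate=25.0, n=100, angle=0.0, start=(0.0, 0.0)):
    step = speed / rate
    d = np.arange(n) * step
    x = start[0] + d * np.cos(np.radians(angle))
    y = start[1] + d * np.sin(np.radians(angle))
    return make_track(np.column_stack([x, y]), rate=rate)


def two_group_plate(n_ctrl, n_other, other="crispant", plate_id="P1", offset=0):
    rows = []
    for i in range(n_ctrl + n_other):
        rows.append({
            "well_id": f"W{offset + i:03d}",
            "subject_id": f"s{offset + i:03d}",
            "group_label": "scrambled" if i < n_ctrl else other,
            "plate_id": plate_id,
        })
    return fs.PlateMap(entries=pd.DataFrame(rows))


@pytest.fixture
def flash_schedule():
    """Compact flash paradigm: 60 s lights-on acclimation then five 1-s
    flashes separated by 49 s of darkness."""
    return fs.StimulusSchedule.flash_series(start=70, acclimation=60)


@pytest.fixture(scope="session")
def screen_run():
    """One simulated screening plate run end-to-end, with ground truth.

    84 control wells (per-flash seizure probability 0.05) and 12 crispant
    wells (0.30), five flashes each, classified with default settings.
    """
    sched = fs.StimulusSchedule.flash_series(start=70, acclimation=60)
    plate = two_group_plate(84, 12)
    params = {"scrambled": fs.SimParams(p_seizure=0.05),
              "crispant": fs.SimParams(p_seizure=0.30)}
    tracks, gt = fs.simulate_plate(plate, sched, params, rng_seed=20240)
    responses = pd.concat(
        [fs.extract_flash_responses(tr, sched) for tr in tracks],
        ignore_index=True)
    model, calls, summaries = fs.classify_responses(responses, plate)
    return {
        "schedule": sched, "plate": plate, "tracks": tracks,
        "ground_truth": gt, "responses": responses,
        "model": model, "calls": calls, "summaries": summaries,
    }
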