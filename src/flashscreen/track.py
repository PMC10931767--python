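"""Centroid tracking tables: the :class:`Track` container and its file dialect.

The native dialect is a long-format CSV with header
``subject_id,well_id,t,x,y`` (one row per frame, UTF-8, ``.`` decimal
separator, ``#`` comment lines allowed).  Coordinates are arena-local
millimetres with the origin at the well centre; time is seconds from
recording start.  Rows with missing coordinates represent tracking
dropout: gaps of at most ``max_gap`` consecutive frames are linearly
interpolated, longer gaps are interpolated too but flagged invalid so
downstream feature windows touching them can be excluded.

An import shim (:func:`read_ethovision`) maps video-tracker exports with
different column names and junk header rows onto the native dialect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["Track", "read_tracks", "write_tracks", "read_ethovision", "write_table"]

#: default maximum dropout run (frames) that is silently interpolated
MAX_GAP_FRAMES = 5


@dataclass
class Track:
    """One larva's centroid time series.

    Attributes
    ----------
    subject_id, well_id : str
    t : ndarray, seconds, strictly increasing, regular spacing
    x, y : ndarray, mm, same length as ``t``, finite after gap filling
    sample_rate : float, Hz
    valid : boolean ndarray, False on frames inside long dropout gaps
    arena_radius : optional well radius (mm) for confinement checks
    """

    subject_id: str
    well_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    sample_rate: float
    valid: np.ndarray = None
    arena_radius: float | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.t.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        self.validate()

    def validate(self) -> None:
        n = len(self.t)
        if n < 2:
            raise ValidationError(f"track {self.subject_id!r}: length {n} < 2")
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise ValidationError(f"track {self.subject_id!r}: array length mismatch")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValidationError(f"track {self.subject_id!r}: non-monotone time")
        if self.sample_rate <= 0 or not np.isfinite(self.sample_rate):
            raise ValidationError(f"track {self.subject_id!r}: bad sample_rate")
        expected = 1.0 / self.sample_rate
        if np.any(np.abs(dt - expected) > 0.05 * expected):
            raise ValidationError(
                f"track {self.subject_id!r}: irregular frame spacing "
                f"(expected {expected:.4g}s)")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValidationError(f"track {self.subject_id!r}: non-finite coordinates")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def window_slice(self, t0: float, t1: float) -> slice:
        """Index slice of frames with ``t0 <= t < t1`` (half-open)."""
        i0 = int(np.searchsorted(self.t, t0 - 1e-9, side="left"))
        i1 = int(np.searchsorted(self.t, t1 - 1e-9, side="left"))
        return slice(i0, i1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject_id": self.subject_id,
            "well_id": self.well_id,
            "t": self.t,
            "x": self.x,
            "y": self.y,
        })


def _fill_gaps(t, x, y, max_gap: int):
    """Interpolate NaN coordinate runs; runs longer than ``max_gap`` frames
    are still interpolated but their frames are marked invalid."""
    x = x.astype(float).copy()
    y = y.astype(float).copy()
    missing = ~(np.isfinite(x) & np.isfinite(y))
    valid = np.ones(len(t), dtype=bool)
    if missing.any():
        if missing.all():
            raise ValidationError("track has no valid coordinates")
        # flag long runs
        idx = np.flatnonzero(np.diff(np.concatenate(([0], missing.view(np.int8), [0]))))
        for start, stop in zip(idx[::2], idx[1::2]):
            if stop - start > max_gap:
                valid[start:stop] = False
        ok = ~missing
        x[missing] = np.interp(t[missing], t[ok], x[ok])
        y[missing] = np.interp(t[missing], t[ok], y[ok])
    return x, y, valid


def _infer_sample_rate(t: np.ndarray) -> float:
    dt = np.diff(t)
    if len(dt) == 0 or np.any(dt <= 0):
        raise ValidationError("non-monotone time")
    return 1.0 / float(np.median(dt))


def read_tracks(path, max_gap: int = MAX_GAP_FRAMES,
                arena_radius: float | None = None) -> list[Track]:
    """Read the native tracking CSV; one :class:`Track` per subject."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = {"subject_id", "well_id", "t", "x", "y"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"tracking file {path}: missing columns {sorted(required - set(df.columns))}")
    if df.empty:
        raise ValidationError(f"tracking file {path}: no rows")
    tracks, rates = [], []
    for subject, grp in df.groupby("subject_id", sort=False):
        t = grp["t"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValidationError(f"track {subject!r}: non-monotone time")
        rate = _infer_sample_rate(t)
        rates.append(rate)
        x, y, valid = _fill_gaps(t, grp["x"].to_numpy(), grp["y"].to_numpy(), max_gap)
        wells = grp["well_id"].unique()
        if len(wells) != 1:
            raise ValidationError(f"track {subject!r}: multiple well ids {wells}")
        tracks.append(Track(str(subject), str(wells[0]), t, x, y, rate,
                            valid=valid, arena_radius=arena_radius))
    if max(rates) / min(rates) > 1.01:
        raise ValidationError("tracking file mixes sample rates across subjects")
    return tracks


def write_tracks(tracks, path, header_comment: str | None = None) -> None:
    frames = [tr.to_frame() for tr in tracks]
    write_table(pd.concat(frames, ignore_index=True), path, header_comment)


def write_table(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write a result table as CSV, with an optional ``#`` header comment
    (used to stamp run seed and config hash on every output)."""
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_ethovision(path, column_map: dict | None = None, skiprows: int = 0,
                    subject_id: str = "subject", well_id: str = "well",
                    max_gap: int = MAX_GAP_FRAMES) -> list[Track]:
    """Import shim for video-tracker exports (single-subject table with a
    configurable header offset and column naming).

    ``column_map`` maps native names (``t``, ``x``, ``y``) to the export's
    column names; defaults cover the common ``Trial time`` /
    ``X center`` / ``Y center`` layout.  Non-numeric coordinate cells
    (``'-'`` placeholders) become dropout gaps.
    """
    cmap = {"t": "Trial time", "x": "X center", "y": "Y center"}
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, skiprows=skiprows)
    missing = [v for v in cmap.values() if v not in df.columns]
    if missing:
        raise ValidationError(f"export {path}: missing columns {missing}")
    out = pd.DataFrame({
        "subject_id": subject_id,
        "well_id": well_id,
        "t": pd.to_numeric(df[cmap["t"]], errors="coerce"),
        "x": pd.to_numeric(df[cmap["x"]], errors="coerce"),
        "y": pd.to_numeric(df[cmap["y"]], errors="coerce"),
    })
    if out["t"].isna().any():
        warnings.warn("dropping rows with unparseable time values")
        out = out[out["t"].notna()]
    t = out["t"].to_numpy(dtype=float)
    rate = _infer_sample_rate(t)
    x, y, valid = _fill_gaps(t, out["x"].to_numpy(), out["y"].to_numpy(), max_gap)
    return [Track(subject_id, well_id, t, x, y, rate, valid=valid)]
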