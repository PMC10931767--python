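"""Plate maps: well -> subject/group/treatment assignments.

Each plate carries its own negative-control group (by convention
``"scrambled"``, larvae injected with Cas9 plus a non-targeting guide) so
that all statistical comparisons stay within a plate; a plate without a
control raises a warning rather than an error so the simulator can build
arbitrary layouts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
import yaml

from .errors import ValidationError

__all__ = ["PlateMap", "read_plate_map", "CONTROL_GROUP"]

CONTROL_GROUP = "scrambled"

_COLUMNS = ["well_id", "subject_id", "group_label", "genotype",
            "treatment", "dose", "dose_unit", "plate_id"]


@dataclass
class PlateMap:
    """Wrapper around a tidy table with one row per occupied well."""

    entries: pd.DataFrame
    control_group: str = CONTROL_GROUP

    def __post_init__(self):
        df = pd.DataFrame(self.entries).copy()
        if df.empty:
            raise ValidationError("plate map is empty")
        for col in ("well_id", "subject_id", "group_label"):
            if col not in df.columns:
                raise ValidationError(f"plate map missing column {col!r}")
        for col in _COLUMNS:
            if col not in df.columns:
                df[col] = "" if col in ("genotype", "treatment", "dose_unit") else (
                    0.0 if col == "dose" else "plate1")
        if df["well_id"].duplicated().any():
            dups = df.loc[df["well_id"].duplicated(), "well_id"].tolist()
            raise ValidationError(f"duplicate well ids in plate map: {dups}")
        if df["subject_id"].duplicated().any():
            dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
            raise ValidationError(f"duplicate subject ids in plate map: {dups}")
        self.entries = df[_COLUMNS].reset_index(drop=True)
        for plate_id, plate in self.entries.groupby("plate_id"):
            if self.control_group not in set(plate["group_label"]):
                warnings.warn(
                    f"plate {plate_id!r} has no {self.control_group!r} control group")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def groups(self) -> list[str]:
        return list(pd.unique(self.entries["group_label"]))

    @property
    def wells(self) -> list[str]:
        return list(self.entries["well_id"])

    def subject_table(self) -> pd.DataFrame:
        """Per-subject metadata indexed by subject_id."""
        return self.entries.set_index("subject_id")

    def group_of(self, subject_id: str) -> str:
        tab = self.subject_table()
        if subject_id not in tab.index:
            raise ValidationError(f"subject {subject_id!r} absent from plate map")
        return str(tab.loc[subject_id, "group_label"])

    def to_csv(self, path, header_comment: str | None = None) -> None:
        from .track import write_table
        write_table(self.entries, path, header_comment)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, control_group: str = CONTROL_GROUP) -> "PlateMap":
        return cls(entries=df, control_group=control_group)


def read_plate_map(path, control_group: str = CONTROL_GROUP) -> PlateMap:
    """Read a plate map from CSV, or from YAML (mapping well_id -> fields)."""
    path = str(path)
    if path.endswith((".yaml", ".yml")):
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not data:
            raise ValidationError(f"plate map {path}: empty document")
        rows = []
        for well, fields in data.items():
            row = {"well_id": str(well)}
            row.update(fields or {})
            rows.append(row)
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path, comment="#")
    if df.empty:
        raise ValidationError(f"plate map {path}: no entries")
    return PlateMap(entries=df, control_group=control_group)
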