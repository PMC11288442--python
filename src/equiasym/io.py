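"""Readers and writers: study-layout workbooks, CSV interchange, traces.

The deposited study data live in a spreadsheet workbook with three sheets
('Straight-line Hard Surface', 'Straight-line Soft Surface', 'Lunge'),
one row per horse and trial.  Since external column names vary between
deposits, the reader maps columns through a user-editable
:class:`DatasetSchema` (loadable from YAML) rather than guessing.  The
package's canonical interchange format is tidy CSV in the internal column
names; spreadsheet support is an adapter at the boundary.  Units are
asserted by the schema (mm for parameters, seconds for durations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

TRIAL_COLUMNS = [
    "horse_id", "condition", "n_strides",
    "mean_hd_min", "mean_hd_max", "mean_pd_min", "mean_pd_max",
    "sd_hd_min", "sd_hd_max", "sd_pd_min", "sd_pd_max",
    "mean_stride_duration",
]

_NUMERIC = TRIAL_COLUMNS[2:]


class SchemaError(ValueError):
    """Workbook does not match the declared schema."""


@dataclass
class DatasetSchema:
    """Mapping between an external workbook layout and internal fields."""

    sheets: dict = field(
        default_factory=lambda: {
            "straight_hard": "Straight-line Hard Surface",
            "straight_soft": "Straight-line Soft Surface",
            "lunge": "Lunge",
        }
    )
    #: external column name -> internal field name
    columns: dict = field(
        default_factory=lambda: {
            "Horse": "horse_id",
            "Discipline": "discipline",
            "Strides": "n_strides",
            "HDmin (mm)": "mean_hd_min",
            "HDmax (mm)": "mean_hd_max",
            "PDmin (mm)": "mean_pd_min",
            "PDmax (mm)": "mean_pd_max",
            "SD HDmin (mm)": "sd_hd_min",
            "SD HDmax (mm)": "sd_hd_max",
            "SD PDmin (mm)": "sd_pd_min",
            "SD PDmax (mm)": "sd_pd_max",
            "Stride duration (s)": "mean_stride_duration",
        }
    )
    #: value of the direction column on the lunge sheet -> condition label
    lunge_direction_column: str = "Direction"
    lunge_direction_map: dict = field(
        default_factory=lambda: {"Left": "lunge_left", "Right": "lunge_right"}
    )
    units: dict = field(
        default_factory=lambda: {"asymmetry": "mm", "duration": "s"}
    )

    def validate(self) -> None:
        required = set(TRIAL_COLUMNS) - {"condition"}
        mapped = set(self.columns.values())
        missing = required - mapped - {"discipline"}
        if missing:
            raise SchemaError(f"schema maps no column to {sorted(missing)}")
        counts = pd.Series(list(self.columns.values())).value_counts()
        dupes = counts[counts > 1].index.tolist()
        if dupes:
            raise SchemaError(f"internal field(s) mapped more than once: {dupes}")
        if self.units.get("asymmetry") != "mm" or self.units.get("duration") != "s":
            raise SchemaError(
                "schema must declare asymmetry in mm and duration in s; "
                f"got {self.units}"
            )

    @classmethod
    def from_yaml(cls, path) -> "DatasetSchema":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {
            "sheets": self.sheets,
            "columns": self.columns,
            "lunge_direction_column": self.lunge_direction_column,
            "lunge_direction_map": self.lunge_direction_map,
            "units": self.units,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class WorkbookData:
    """Parsed study workbook: trial summaries, horse metadata, row errors."""

    trials: pd.DataFrame
    horses: pd.DataFrame
    row_errors: pd.DataFrame


def read_study_workbook(path, schema: DatasetSchema | None = None) -> WorkbookData:
    """Read a study-layout workbook into the internal trial table.

    Raises :class:`SchemaError` naming any missing sheet or column.  Rows
    with non-numeric cells in numeric fields are dropped and reported in
    ``row_errors`` instead of failing the whole read.
    """
    schema = schema or DatasetSchema()
    schema.validate()
    xls = pd.ExcelFile(path)
    missing_sheets = [s for s in schema.sheets.values() if s not in xls.sheet_names]
    if missing_sheets:
        raise SchemaError(f"workbook is missing sheet(s) {missing_sheets}")

    frames, errors, horse_meta = [], [], {}
    for condition, sheet in schema.sheets.items():
        raw = xls.parse(sheet)
        missing_cols = [c for c in schema.columns if c not in raw.columns]
        if condition == "lunge" and schema.lunge_direction_column not in raw.columns:
            missing_cols.append(schema.lunge_direction_column)
        if missing_cols:
            raise SchemaError(f"sheet {sheet!r} is missing column(s) {missing_cols}")
        df = raw.rename(columns=schema.columns)
        if condition == "lunge":
            df["condition"] = df[schema.lunge_direction_column].map(
                schema.lunge_direction_map
            )
            bad_dir = df["condition"].isna()
            for i in df.index[bad_dir]:
                errors.append({"sheet": sheet, "row": int(i),
                               "problem": "unknown lunge direction"})
            df = df.loc[~bad_dir]
        else:
            df["condition"] = condition
        for col in _NUMERIC:
            df[col] = pd.to_numeric(df[col], errors="coerce")
        bad = df[_NUMERIC].isna().any(axis=1)
        for i in df.index[bad]:
            errors.append({"sheet": sheet, "row": int(i),
                           "problem": "non-numeric value in numeric column"})
        df = df.loc[~bad]
        if "discipline" in df.columns:
            horse_meta.update(
                dict(zip(df["horse_id"].astype(str), df["discipline"]))
            )
        df["horse_id"] = df["horse_id"].astype(str)
        frames.append(df[TRIAL_COLUMNS])

    trials = pd.concat(frames, ignore_index=True)
    trials["n_strides"] = trials["n_strides"].astype(int)
    horses = pd.DataFrame(
        {"horse_id": list(horse_meta), "discipline": list(horse_meta.values())}
    )
    return WorkbookData(
        trials=trials,
        horses=horses,
        row_errors=pd.DataFrame(errors, columns=["sheet", "row", "problem"]),
    )


def write_study_workbook(trials: pd.DataFrame, path,
                         horses: pd.DataFrame | None = None,
                         schema: DatasetSchema | None = None) -> None:
    """Write a trial table in the study's three-sheet workbook layout."""
    schema = schema or DatasetSchema()
    schema.validate()
    inv_cols = {v: k for k, v in schema.columns.items()}
    inv_dir = {v: k for k, v in schema.lunge_direction_map.items()}
    df = trials.copy()
    if horses is not None and "discipline" in horses.columns:
        df = df.merge(horses[["horse_id", "discipline"]], on="horse_id", how="left")
    if "discipline" not in df.columns:
        df["discipline"] = ""
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        for condition, sheet in schema.sheets.items():
            if condition == "lunge":
                sub = df.loc[df["condition"].isin(inv_dir)].copy()
                sub[schema.lunge_direction_column] = sub["condition"].map(inv_dir)
                extra = [schema.lunge_direction_column]
            else:
                sub = df.loc[df["condition"] == condition].copy()
                extra = []
            out = sub[[c for c in TRIAL_COLUMNS if c != "condition"]
                      + ["discipline"]].rename(columns=inv_cols)
            for col in extra:
                out[col] = sub[col].to_numpy()
            out.to_excel(writer, sheet_name=sheet, index=False)


def write_traces(trial, path) -> None:
    """Write simulated traces as plain tabular text (TSV).

    Columns: time_s, head_z_mm, pelvis_z_mm, pastern_z_mm, pastern_phase.
    """
    pd.DataFrame(
        {
            "time_s": trial.head.time,
            "head_z_mm": trial.head.z,
            "pelvis_z_mm": trial.pelvis.z,
            "pastern_z_mm": trial.pastern.z,
            "pastern_phase": trial.pastern_phase,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_traces(path):
    """Read a trace file written by :func:`write_traces`.

    Returns (head, pelvis, pastern) :class:`~equiasym.strides.DisplacementTrace`.
    """
    from .strides import DisplacementTrace

    df = pd.read_csv(path, sep="\t")
    t = df["time_s"].to_numpy()
    return (
        DisplacementTrace("head", t, df["head_z_mm"].to_numpy()),
        DisplacementTrace("pelvis", t, df["pelvis_z_mm"].to_numpy()),
        DisplacementTrace("pastern", t, df["pastern_z_mm"].to_numpy()),
    )
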