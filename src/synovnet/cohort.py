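"""The patient-by-marker cohort table: the interchange object between all stages.

A :class:`CohortTable` wraps a pandas DataFrame with one row per patient.
Reserved columns are ``patient_id``, ``group`` and (optionally)
``archetype``; every other column is a numeric marker. The table is strict:
duplicate patient identifiers, missing marker cells and non-numeric marker
cells are hard errors, because the downstream similarity network assumes a
complete numeric matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

RESERVED_COLUMNS = ("patient_id", "group", "archetype")

#: Bookkeeping columns that are not markers but may appear in generated tables.
FLAG_COLUMNS = ("composition_rescaled",)


class CohortError(ValueError):
    """Raised when a cohort table violates its invariants."""


@dataclass
class CohortTable:
    """Patient records with clinical group labels and numeric marker values.

    Parameters
    ----------
    df : pandas.DataFrame
        One row per patient. Must contain ``patient_id`` and ``group``
        columns; every non-reserved column is treated as a marker.
    units : dict, optional
        Marker name -> unit string, written to the sidecar JSON on export.
    """

    df: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -----------------------------------------------------

    def validate(self) -> None:
        df = self.df
        for col in ("patient_id", "group"):
            if col not in df.columns:
                raise CohortError(f"cohort is missing required column {col!r}")
        dup = df["patient_id"][df["patient_id"].duplicated()]
        if len(dup):
            raise CohortError(f"duplicate patient_id: {dup.iloc[0]!r}")
        for marker in self.marker_names:
            col = df[marker]
            if col.isna().any():
                patient = df.loc[col.isna(), "patient_id"].iloc[0]
                raise CohortError(
                    f"missing value for marker {marker!r} in patient {patient!r}"
                )
            if not np.issubdtype(col.dtype, np.number):
                raise CohortError(f"marker column {marker!r} is not numeric")

    # -- views ----------------------------------------------------------

    @property
    def patient_ids(self) -> list[str]:
        return list(self.df["patient_id"])

    @property
    def group_labels(self) -> list[str]:
        return list(self.df["group"])

    @property
    def marker_names(self) -> list[str]:
        return [
            c
            for c in self.df.columns
            if c not in RESERVED_COLUMNS and c not in FLAG_COLUMNS
        ]

    def __len__(self) -> int:
        return len(self.df)

    def marker_matrix(self, markers: Iterable[str] | None = None) -> pd.DataFrame:
        """Numeric patient x marker matrix indexed by patient_id."""
        markers = list(markers) if markers is not None else self.marker_names
        unknown = [m for m in markers if m not in self.df.columns]
        if unknown:
            raise CohortError(f"unknown marker(s): {unknown}")
        out = self.df.set_index("patient_id")[markers].astype(float)
        return out


def read_cohort(path: str | Path) -> CohortTable:
    """Read a cohort CSV (header row; patient_id, group, then markers).

    Any empty or non-numeric marker cell is rejected with an error naming
    the offending patient and marker. A ``<path>.units.json`` sidecar, if
    present, supplies marker units.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str, "group": str})
    for col in ("patient_id", "group"):
        if col not in df.columns:
            raise CohortError(f"{path}: missing required column {col!r}")
    marker_cols = [
        c for c in df.columns if c not in RESERVED_COLUMNS and c not in FLAG_COLUMNS
    ]
    for marker in marker_cols:
        coerced = pd.to_numeric(df[marker], errors="coerce")
        bad = coerced.isna() & df[marker].notna()
        if bad.any():
            row = df.index[bad][0]
            raise CohortError(
                f"{path}: non-numeric value {df.loc[row, marker]!r} for marker "
                f"{marker!r} in patient {df.loc[row, 'patient_id']!r}"
            )
        df[marker] = coerced
    units: dict[str, str] = {}
    sidecar = path.with_suffix(path.suffix + ".units.json")
    if sidecar.exists():
        units = json.loads(sidecar.read_text())
    return CohortTable(df, units=units)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write the cohort CSV plus a ``.units.json`` sidecar with marker units."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.df.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".units.json")
    sidecar.write_text(json.dumps(cohort.units, indent=1, sort_keys=True) + "\n")
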