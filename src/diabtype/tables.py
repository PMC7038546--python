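"""Normalized longitudinal event tables and their delimited-text readers.

One file per table, UTF-8 with a header row.  Dates are ISO-8601 calendar
dates; all downstream comparisons are date-level.  Undotted ICD-9 claims
dialects ("25001") are normalized to dotted form at read time so that rule
evaluation only ever sees dotted codes.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

from .icd9 import normalize_icd9

DRUG_CLASSES = (
    "metformin",
    "sulfonylurea",
    "thiazolidinedione",
    "dpp4",
    "glp1",
    "sglt2",
    "agi",
    "other_glm",
    "insulin_long",
    "insulin_intermediate",
    "insulin_short",
    "insulin_premixed",
)
INSULIN_CLASSES = tuple(c for c in DRUG_CLASSES if c.startswith("insulin_"))
NON_INSULIN_CLASSES = tuple(c for c in DRUG_CLASSES if not c.startswith("insulin_"))

LAB_TESTS = ("hba1c", "fpg", "egfr")
SETTINGS = ("inpatient", "outpatient")
SOURCES = ("principal", "mixed")
DELIVERY_KINDS = ("delivery", "pregnancy_related")
TRUE_TYPES = ("T1D", "T2D", "monogenic_secondary", "missing")

#: table name -> (required columns, date columns, enum columns)
SCHEMAS: dict[str, tuple[tuple[str, ...], tuple[str, ...], dict[str, tuple[str, ...]]]] = {
    "persons": (("person_id", "sex", "birth_date"), ("birth_date",), {"sex": ("female", "male")}),
    "encounters": (
        ("person_id", "date", "icd9", "source", "setting"),
        ("date",),
        {"source": SOURCES, "setting": SETTINGS},
    ),
    "prescriptions": (
        ("person_id", "drug_class", "start_date", "duration_days"),
        ("start_date",),
        {"drug_class": DRUG_CLASSES},
    ),
    "labs": (
        ("person_id", "date", "test", "value", "setting"),
        ("date",),
        {"test": LAB_TESTS, "setting": SETTINGS},
    ),
    "deliveries": (("person_id", "date", "kind"), ("date",), {"kind": DELIVERY_KINDS}),
    "labels": (("person_id", "true_type"), (), {"true_type": TRUE_TYPES}),
}


class SchemaError(ValueError):
    """A table violates its documented column schema."""


@dataclasses.dataclass
class EventTables:
    """Container for the per-person longitudinal event tables."""

    persons: pd.DataFrame
    encounters: pd.DataFrame
    prescriptions: pd.DataFrame
    labs: pd.DataFrame
    deliveries: pd.DataFrame

    def subset(self, person_ids) -> "EventTables":
        """Restrict every table to the given person ids."""
        ids = set(person_ids)
        return EventTables(
            **{
                f.name: getattr(self, f.name)[
                    getattr(self, f.name)["person_id"].isin(ids)
                ].reset_index(drop=True)
                for f in dataclasses.fields(self)
            }
        )

    def table_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(self))


def _parse_dates(df: pd.DataFrame, table: str, cols: tuple[str, ...]) -> pd.DataFrame:
    for col in cols:
        parsed = pd.to_datetime(df[col], format="ISO8601", errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            # +2: header row plus 1-based numbering
            lines = [int(i) + 2 for i in df.index[bad][:5]]
            raise SchemaError(
                f"{table}: unparseable date in column '{col}' at line(s) {lines}"
            )
        df[col] = parsed.dt.normalize()
    return df


def validate_table(df: pd.DataFrame, table: str) -> pd.DataFrame:
    """Check required columns and enum domains; normalize dates and codes."""
    required, date_cols, enums = SCHEMAS[table]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{table}: missing required column '{col}'")
    df = df.copy()
    df = _parse_dates(df, table, date_cols)
    for col, domain in enums.items():
        bad = ~df[col].isin(domain) & df[col].notna()
        if bad.any():
            values = sorted(df.loc[bad, col].astype(str).unique()[:5])
            raise SchemaError(f"{table}: invalid {col} value(s) {values}")
    if table == "encounters":
        empty = df["icd9"].isna() | (df["icd9"].astype(str).str.strip() == "")
        if empty.any():
            raise SchemaError("encounters: empty icd9 code")
        df["icd9"] = df["icd9"].astype(str).map(normalize_icd9)
    if table == "prescriptions":
        df["duration_days"] = df["duration_days"].astype(int)
        if (df["duration_days"] < 1).any():
            raise SchemaError("prescriptions: duration_days must be >= 1")
    df["person_id"] = df["person_id"].astype(str)
    return df


def _paths(directory: str | Path) -> dict[str, Path]:
    d = Path(directory)
    return {t: d / f"{t}.csv" for t in SCHEMAS}


def read_event_tables(directory: str | Path, sep: str = ",") -> EventTables:
    """Read the five event tables from ``<directory>/<table>.csv``.

    Missing optional tables (deliveries) yield empty frames; the persons
    table is required.  Unknown columns are preserved.
    """
    frames = {}
    for table, path in _paths(directory).items():
        if table == "labels":
            continue
        if path.exists():
            dtypes = {"person_id": str}
            if table == "encounters":
                dtypes["icd9"] = str  # "250.00" must not collapse to 250.0
            raw = pd.read_csv(path, sep=sep, dtype=dtypes)
            frames[table] = validate_table(raw, table)
        else:
            if table == "persons":
                raise FileNotFoundError(f"required table missing: {path}")
            frames[table] = empty_table(table)
    return EventTables(**frames)


def read_labels(path: str | Path, sep: str = ",") -> pd.DataFrame:
    raw = pd.read_csv(path, sep=sep, dtype={"person_id": str})
    return validate_table(raw, "labels")


def write_event_tables(
    tables: EventTables, directory: str | Path, sep: str = ",",
    labels: pd.DataFrame | None = None,
) -> None:
    """Write tables as delimited text; round-trips through the reader."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for name in tables.table_names():
        df = getattr(tables, name).copy()
        for col in SCHEMAS[name][1]:
            df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
        df.to_csv(d / f"{name}.csv", sep=sep, index=False)
    if labels is not None:
        labels.to_csv(d / "labels.csv", sep=sep, index=False)


def empty_table(table: str) -> pd.DataFrame:
    required, date_cols, _ = SCHEMAS[table]
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in required})
    for col in date_cols:
        df[col] = pd.Series(dtype="datetime64[ns]")
    if table == "prescriptions":
        df["duration_days"] = pd.Series(dtype=int)
    return df


def empty_event_tables() -> EventTables:
    return EventTables(**{t: empty_table(t) for t in SCHEMAS if t != "labels"})
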