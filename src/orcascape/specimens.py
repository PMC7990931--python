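"""Specimen domain types, CSV I/O and validation.

A :class:`SpecimenRecord` holds one whale's stranding metadata together with
its whole-tooth (dentine) or bone isotope values: δ¹⁸O of the phosphate
fraction of biogenic apatite (``d18O_p``, ‰ VSMOW) and δ¹³C of structural
carbonate (``d13C_sc``, ‰ VPDB).  Ages are growth-layer-group (GLG) counts
and may be missing; missing values are represented as ``None``, never zero.

The packaged fixture (:func:`load_fixture`) contains the 22 stranded killer
whales analysed in the study this package operationalises: 10 eastern
Canadian Arctic (ECA) and 7 northwest Atlantic (NWA) teeth plus 2 Greenland
and 3 Denmark bone specimens.
"""

from __future__ import annotations

import csv
import importlib.resources
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "SpecimenRecord",
    "GLGProfile",
    "ReferenceCohort",
    "SchemaError",
    "RowParseError",
    "ValidationIssue",
    "read_specimens",
    "write_specimens",
    "validate_specimens",
    "read_glg_profiles",
    "write_glg_profiles",
    "load_fixture",
    "load_fixture_expected",
    "load_reference_endpoints",
]

REGIONS = ("ECA", "NWA", "Greenland", "Denmark", "other")
TISSUES = ("dentine", "bone")

SPECIMEN_COLUMNS = (
    "specimen_id",
    "region",
    "tissue",
    "year_of_death",
    "age_years",
    "d18O_p",
    "d13C_sc",
    "stranding_group",
)
MANDATORY_COLUMNS = ("specimen_id", "region", "tissue", "year_of_death", "d18O_p")


class SchemaError(ValueError):
    """A mandatory column is absent from the input file."""


class RowParseError(ValueError):
    """A cell in a data row could not be parsed; carries the row index."""

    def __init__(self, row_index: int, message: str):
        self.row_index = row_index
        super().__init__(f"row {row_index}: {message}")


@dataclass(frozen=True)
class SpecimenRecord:
    """One whale: metadata plus whole-tooth/bone isotope values."""

    specimen_id: str
    region: str
    tissue: str
    year_of_death: int
    d18O_p: float
    age_years: float | None = None
    d13C_sc: float | None = None
    d18O_sc: float | None = None
    stranding_group: str | None = None


@dataclass(frozen=True)
class GLGProfile:
    """Per-GLG (annual growth layer) isotope series for one tooth.

    ``values`` is an ordered sequence of ``(glg_index, d18O_sc, d13C_sc)``
    tuples with 1-based, strictly increasing indices; either analyte may be
    ``None`` for an individual layer.
    """

    specimen_id: str
    values: tuple[tuple[int, float | None, float | None], ...]

    def __post_init__(self):
        if len(self.values) < 1:
            raise ValueError("GLGProfile requires at least one entry")
        idx = [v[0] for v in self.values]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("glg_index must be strictly increasing")

    def analyte(self, name: str) -> list[float | None]:
        col = {"d18O_sc": 1, "d13C_sc": 2}[name]
        return [v[col] for v in self.values]


@dataclass(frozen=True)
class ReferenceCohort:
    """A labelled group of known-origin reference animals (δ¹⁸O endpoints)."""

    label: str
    records: tuple[SpecimenRecord, ...] = field(default=())
    mean_d18O_p: float | None = None
    sd_d18O_p: float | None = None

    def __post_init__(self):
        if not self.records and self.mean_d18O_p is None:
            raise ValueError("ReferenceCohort needs records or summary values")


@dataclass(frozen=True)
class ValidationIssue:
    specimen_id: str
    field: str
    message: str


def _parse_float(cell: str, row_index: int, column: str) -> float | None:
    cell = cell.strip()
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise RowParseError(row_index, f"cannot parse {column}={cell!r} as a number") from None


def read_specimens(path: str | Path, dialect: dict | None = None) -> list[SpecimenRecord]:
    """Read specimen records from a CSV file.

    Missing cells become ``None``; row order is preserved.  Raises
    :class:`SchemaError` when a mandatory column is absent and
    :class:`RowParseError` (with the 1-based data-row index) for an
    unparsable number.
    """
    dialect = dialect or {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, **dialect)
        header = reader.fieldnames or []
        for col in MANDATORY_COLUMNS:
            if col not in header:
                raise SchemaError(f"missing mandatory column: {col}")
        records = []
        for i, row in enumerate(reader, start=1):
            sid = (row.get("specimen_id") or "").strip()
            try:
                year = int(row["year_of_death"])
            except (TypeError, ValueError):
                raise RowParseError(i, f"cannot parse year_of_death={row.get('year_of_death')!r}") from None
            d18o_p = _parse_float(row.get("d18O_p") or "", i, "d18O_p")
            if d18o_p is None:
                raise RowParseError(i, "d18O_p is mandatory but empty")
            records.append(
                SpecimenRecord(
                    specimen_id=sid,
                    region=(row.get("region") or "other").strip() or "other",
                    tissue=(row.get("tissue") or "").strip(),
                    year_of_death=year,
                    age_years=_parse_float(row.get("age_years") or "", i, "age_years"),
                    d18O_p=d18o_p,
                    d13C_sc=_parse_float(row.get("d13C_sc") or "", i, "d13C_sc"),
                    d18O_sc=_parse_float(row.get("d18O_sc") or "", i, "d18O_sc"),
                    stranding_group=(row.get("stranding_group") or "").strip() or None,
                )
            )
    return records


def write_specimens(records: Iterable[SpecimenRecord], path: str | Path) -> None:
    """Write records to CSV using the canonical column order (empty = missing)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SPECIMEN_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.specimen_id,
                    r.region,
                    r.tissue,
                    r.year_of_death,
                    "" if r.age_years is None else _fmt(r.age_years),
                    _fmt(r.d18O_p),
                    "" if r.d13C_sc is None else _fmt(r.d13C_sc),
                    r.stranding_group or "",
                ]
            )


def _fmt(x: float) -> str:
    # integers print without a trailing .0 so round-trips are byte-stable
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


def validate_specimens(records: Sequence[SpecimenRecord]) -> list[ValidationIssue]:
    """Report (never raise) violations of the record invariants.

    Checks: δ¹⁸O_P inside the physical sanity window [0, 40]‰, age below
    120 GLGs when present, year of death ≥ 1800, and known region/tissue
    labels.  Records are never mutated.
    """
    issues: list[ValidationIssue] = []

    def flag(r, field_, msg):
        issues.append(ValidationIssue(r.specimen_id, field_, msg))

    for r in records:
        if not (0.0 <= r.d18O_p <= 40.0):
            flag(r, "d18O_p", f"{r.d18O_p} outside sanity window [0, 40]")
        if r.age_years is not None and not (0.0 <= r.age_years < 120.0):
            flag(r, "age_years", f"{r.age_years} outside [0, 120)")
        if r.year_of_death < 1800:
            flag(r, "year_of_death", f"{r.year_of_death} before 1800")
        if r.region not in REGIONS:
            flag(r, "region", f"unknown region {r.region!r}")
        if r.tissue not in TISSUES:
            flag(r, "tissue", f"unknown tissue {r.tissue!r}")
        if r.d13C_sc is not None and not (-40.0 <= r.d13C_sc <= 10.0):
            flag(r, "d13C_sc", f"{r.d13C_sc} outside sanity window [-40, 10]")
    return issues


def read_glg_profiles(path: str | Path) -> list[GLGProfile]:
    """Read long-format per-GLG series (specimen_id, glg_index, d18O_sc, d13C_sc)."""
    rows: dict[str, list[tuple[int, float | None, float | None]]] = {}
    order: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for col in ("specimen_id", "glg_index"):
            if col not in (reader.fieldnames or []):
                raise SchemaError(f"missing mandatory column: {col}")
        for i, row in enumerate(reader, start=1):
            sid = row["specimen_id"].strip()
            try:
                idx = int(row["glg_index"])
            except ValueError:
                raise RowParseError(i, f"cannot parse glg_index={row['glg_index']!r}") from None
            if sid not in rows:
                rows[sid] = []
                order.append(sid)
            rows[sid].append(
                (
                    idx,
                    _parse_float(row.get("d18O_sc") or "", i, "d18O_sc"),
                    _parse_float(row.get("d13C_sc") or "", i, "d13C_sc"),
                )
            )
    return [GLGProfile(sid, tuple(sorted(rows[sid]))) for sid in order]


def write_glg_profiles(profiles: Iterable[GLGProfile], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["specimen_id", "glg_index", "d18O_sc", "d13C_sc"])
        for p in profiles:
            for idx, o, c in p.values:
                writer.writerow([p.specimen_id, idx, "" if o is None else _fmt(o), "" if c is None else _fmt(c)])


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("orcascape").joinpath("data", name))


def load_fixture() -> list[SpecimenRecord]:
    """The 22 packaged study specimens (10 ECA + 7 NWA teeth, 5 bone)."""
    return read_specimens(_data_path("specimens.csv"))


def load_fixture_expected() -> list[dict]:
    """Published per-specimen results for cross-checking a pipeline run.

    Columns: estimated source-water δ¹⁸O (``d18o_marine``) and its standard
    error, the Suess-adjusted δ¹³C_SC, and two provenance flags —
    ``suess_swapped`` marks the two rows whose published adjusted values are
    interchanged relative to the stated formula, and ``suess_excluded`` marks
    the age-less bone rows whose published adjustment is not reconstructible.
    """
    out = []
    with open(_data_path("table2_expected.csv"), newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                {
                    "specimen_id": row["specimen_id"],
                    "d18o_marine": float(row["d18o_marine"]),
                    "se": float(row["se"]),
                    "d13c_sc_suess": float(row["d13c_sc_suess"]),
                    "suess_swapped": row["suess_swapped"] == "1",
                    "suess_excluded": row["suess_excluded"] == "1",
                }
            )
    return out


def load_reference_endpoints() -> list[ReferenceCohort]:
    """Published summary values of the two known-origin endpoint cohorts."""
    out = []
    with open(_data_path("reference_endpoints.csv"), newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                ReferenceCohort(
                    label=row["label"],
                    mean_d18O_p=float(row["mean_d18o_p"]),
                    sd_d18O_p=float(row["sd_d18o_p"]),
                )
            )
    return out
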