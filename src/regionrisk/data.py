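"""Data model, ingest and validation for region-by-factor tables.

A *region table* holds one row per small geographic unit (a county or a
ZIP/ZCTA) and one column per breast-cancer risk factor (incidence and
mortality per 100,000 women, percentage-scale demographic factors, median
household income in dollars).  Factor metadata — risk direction and
integer weight — lives in :class:`FactorSpec`.

Conventions
-----------
* Region identifiers are opaque strings; ZIP codes keep leading zeros and
  no geocoding is attempted.
* Percentages are stored on the 0–100 scale as printed, never 0–1.
* Missing values are explicit (``None``), never silently zero.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

__all__ = [
    "FactorSpec",
    "RegionRecord",
    "RegionTable",
    "Violation",
    "RegionTableError",
    "read_region_table",
    "write_region_table",
    "read_factor_config",
    "validate_region_table",
    "parse_number",
]

#: Minimum number of regions required before quartile operations make sense.
MIN_REGIONS = 4

_DIRECTIONS = ("direct", "inverse")

#: Cell contents treated as an explicitly missing value.
_MISSING_TOKENS = {"", "n.d.", "nd", "na", "n/a", "nan", "none", "null", "."}

_NUMBER_RE = re.compile(r"^[+-]?(\d{1,3}(,\d{3})+|\d+)(\.\d*)?([eE][+-]?\d+)?$")


class RegionTableError(ValueError):
    """Raised on malformed input tables or factor configurations."""


@dataclass(frozen=True)
class FactorSpec:
    """Metadata for one risk factor.

    Parameters
    ----------
    name:
        Column label, unique within a configuration.
    direction:
        ``"direct"`` if a larger raw value means *higher* risk (e.g.
        % uninsured, mortality rate); ``"inverse"`` if a larger value means
        *lower* risk (e.g. median income, educational attainment).
    weight:
        Positive integer weight in the integrated quartile score.  The
        default configuration weights incidence and mortality double.
    units:
        Free-text units note ("per 100,000", "%", "$", ...).
    """

    name: str
    direction: str = "direct"
    weight: int = 1
    units: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise RegionTableError("factor name must be non-empty")
        if self.direction not in _DIRECTIONS:
            raise RegionTableError(
                f"factor {self.name!r}: direction must be one of {_DIRECTIONS}, "
                f"got {self.direction!r}"
            )
        if not isinstance(self.weight, int) or self.weight < 1:
            raise RegionTableError(
                f"factor {self.name!r}: weight must be a positive integer, "
                f"got {self.weight!r}"
            )


@dataclass
class RegionRecord:
    """One geographic unit: identifier, optional parent group, factor values.

    ``values`` maps factor name → float, with ``None`` marking an
    explicitly missing value.
    """

    region_id: str
    values: dict[str, float | None]
    group_id: str | None = None

    def __post_init__(self) -> None:
        if not self.region_id:
            raise RegionTableError("region_id must be a non-empty string")


@dataclass
class RegionTable:
    """An ordered collection of :class:`RegionRecord` plus factor metadata."""

    records: list[RegionRecord]
    factors: list[FactorSpec]
    provenance: str = ""

    def __post_init__(self) -> None:
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise RegionTableError(f"duplicate factor names: {dupes}")
        seen: set[str] = set()
        for rec in self.records:
            if rec.region_id in seen:
                raise RegionTableError(f"duplicate region_id {rec.region_id!r}")
            seen.add(rec.region_id)
        known = set(names)
        for rec in self.records:
            unknown = sorted(set(rec.values) - known)
            if unknown:
                raise RegionTableError(
                    f"region {rec.region_id!r} has values for unconfigured "
                    f"factor(s) {unknown}"
                )

    # -- convenience accessors -------------------------------------------
    @property
    def region_ids(self) -> list[str]:
        return [r.region_id for r in self.records]

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    def factor(self, name: str) -> FactorSpec:
        for f in self.factors:
            if f.name == name:
                return f
        raise RegionTableError(f"unknown factor {name!r}")

    def column(self, name: str) -> dict[str, float | None]:
        """Map region_id → value for one factor (missing as ``None``)."""
        self.factor(name)
        return {r.region_id: r.values.get(name) for r in self.records}

    def groups(self) -> dict[str, list[RegionRecord]]:
        """Records keyed by group_id; ungrouped records are skipped."""
        out: dict[str, list[RegionRecord]] = {}
        for rec in self.records:
            if rec.group_id is not None:
                out.setdefault(rec.group_id, []).append(rec)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format view: one row per region, factors as columns."""
        rows = []
        for rec in self.records:
            row: dict[str, object] = {"region_id": rec.region_id}
            if any(r.group_id is not None for r in self.records):
                row["group_id"] = rec.group_id
            for f in self.factors:
                row[f.name] = rec.values.get(f.name)
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class Violation:
    """One validation finding (reported, never raised)."""

    region_id: str
    factor: str | None
    kind: str  # "missing" | "range" | "negative"
    message: str


def parse_number(text: str) -> float | None:
    """Parse one numeric cell; ``None`` for an explicit missing token.

    Accepts a leading currency symbol and comma thousands separators, so
    ``"$13,523"``, ``"13,523"`` and ``"13523"`` all parse to 13523.0.
    Raises :class:`RegionTableError` on anything else non-numeric.
    """
    s = text.strip()
    if s.lower() in _MISSING_TOKENS:
        return None
    s = s.lstrip("$").replace("%", "").strip()
    if not _NUMBER_RE.match(s):
        raise RegionTableError(f"non-numeric cell {text!r}")
    return float(s.replace(",", ""))


def read_factor_config(path: str | Path) -> list[FactorSpec]:
    """Read a YAML/JSON factor configuration.

    The file holds a list of ``{name, direction, weight, units}`` mappings;
    ``direction`` defaults to direct, ``weight`` to 1.
    """
    raw = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(raw)
    if not isinstance(data, list):
        raise RegionTableError("factor config must be a list of mappings")
    specs = []
    for i, item in enumerate(data):
        if not isinstance(item, dict) or "name" not in item:
            raise RegionTableError(f"factor config entry {i} lacks a name")
        specs.append(
            FactorSpec(
                name=str(item["name"]),
                direction=str(item.get("direction", "direct")),
                weight=int(item.get("weight", 1)),
                units=str(item.get("units", "")),
            )
        )
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise RegionTableError("factor names must be unique in the config")
    return specs


def _records_from_rows(
    rows: Iterable[dict[str, str]],
    header: Sequence[str],
    config: Sequence[FactorSpec],
) -> list[RegionRecord]:
    known = {f.name for f in config}
    if "region_id" not in header:
        raise RegionTableError("missing required column 'region_id'")
    extra = [c for c in header if c not in known and c not in ("region_id", "group_id")]
    if extra:
        raise RegionTableError(
            f"unknown factor column(s) {extra}; not present in the factor config"
        )
    records = []
    for i, row in enumerate(rows, start=2):  # header is line 1
        rid = (row.get("region_id") or "").strip()
        gid = (row.get("group_id") or "").strip() or None
        values: dict[str, float | None] = {}
        for col in header:
            if col in ("region_id", "group_id"):
                continue
            cell = row.get(col)
            try:
                values[col] = parse_number("" if cell is None else str(cell))
            except RegionTableError as exc:
                raise RegionTableError(
                    f"row {i}, column {col!r}: {exc}"
                ) from None
        records.append(RegionRecord(region_id=rid, group_id=gid, values=values))
    return records


def read_region_table(
    path: str | Path, config: Sequence[FactorSpec], *, require_min: bool = True
) -> RegionTable:
    """Read a region table from CSV or a JSON records document.

    CSV: comma-separated, UTF-8, header row with ``region_id``, optional
    ``group_id``, and one column per configured factor.  JSON: an array of
    objects with the same keys.  Numeric parsing strips currency symbols
    and thousands separators.

    Raises :class:`RegionTableError` for unknown factor columns,
    non-numeric cells (with row/column coordinates), duplicate region ids,
    or fewer than four regions (unless ``require_min=False``).
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json" or text.lstrip().startswith("["):
        raw = json.loads(text)
        if not isinstance(raw, list):
            raise RegionTableError("JSON region table must be an array of objects")
        header: list[str] = []
        for obj in raw:
            for k in obj:
                if k not in header:
                    header.append(k)
        rows = [{k: "" if v is None else str(v) for k, v in obj.items()} for obj in raw]
        records = _records_from_rows(rows, header, config)
    else:
        reader = csv.DictReader(text.splitlines())
        if reader.fieldnames is None:
            raise RegionTableError("empty file: no header row")
        records = _records_from_rows(reader, reader.fieldnames, config)
    if require_min and len(records) < MIN_REGIONS:
        raise RegionTableError(
            f"fewer than {MIN_REGIONS} regions ({len(records)} found); "
            "quartile operations need at least 4"
        )
    return RegionTable(records=records, factors=list(config), provenance=str(path))


def write_region_table(table: RegionTable, path: str | Path) -> None:
    """Write a region table as CSV (round-trips with :func:`read_region_table`)."""
    path = Path(path)
    has_groups = any(r.group_id is not None for r in table.records)
    header = ["region_id"] + (["group_id"] if has_groups else []) + table.factor_names
    with path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for rec in table.records:
            row: list[str] = [rec.region_id]
            if has_groups:
                row.append(rec.group_id or "")
            for name in table.factor_names:
                v = rec.values.get(name)
                row.append("" if v is None else repr(v))
            w.writerow(row)


# Factors whose units mark them as a 0-100 percentage.
_PERCENT_UNIT_RE = re.compile(r"%|percent", re.IGNORECASE)


def validate_region_table(table: RegionTable) -> list[Violation]:
    """Check every record against the data-model invariants.

    Returns a list of findings — missing values, percentages outside
    [0, 100], negative rates or incomes — and is empty iff the table is
    clean.  Never raises: validation reports, it does not reject.
    """
    findings: list[Violation] = []
    for rec in table.records:
        for f in table.factors:
            v = rec.values.get(f.name)
            if v is None:
                findings.append(
                    Violation(rec.region_id, f.name, "missing",
                              f"{rec.region_id}: missing value for {f.name!r}")
                )
                continue
            if _PERCENT_UNIT_RE.search(f.units) and not (0.0 <= v <= 100.0):
                findings.append(
                    Violation(rec.region_id, f.name, "range",
                              f"{rec.region_id}: {f.name}={v} outside [0, 100] %")
                )
            elif v < 0:
                findings.append(
                    Violation(rec.region_id, f.name, "negative",
                              f"{rec.region_id}: {f.name}={v} is negative")
                )
    return findings
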