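"""Schema-validated CSV reading and writing.

One tabular dialect package-wide: comma-delimited, UTF-8, header row,
"." decimal on write with "," accepted on read (values such as ``"0,14"``
are normalized at ingest). Errors carry the 1-based line number of the
offending row.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from collections.abc import Iterable, Mapping, Sequence

__all__ = ["TableError", "TableSchema", "SCHEMAS", "read_table", "write_table"]

_DECIMAL_COMMA = re.compile(r"^-?\d+,\d+(?:[eE][+-]?\d+)?$")


class TableError(ValueError):
    """Raised for missing columns, unparseable values or empty files."""


@dataclass(frozen=True)
class TableSchema:
    """Column names (lowercase) mapped to target types; optional columns may
    be absent from the file or blank in a row."""

    name: str
    columns: dict[str, type]
    optional: dict[str, type] = field(default_factory=dict)

    @property
    def all_columns(self) -> dict[str, type]:
        return {**self.columns, **self.optional}


SCHEMAS: dict[str, TableSchema] = {
    "docking": TableSchema(
        name="docking",
        columns={
            "ligand_id": str,
            "substrate_id": str,
            "target_id": str,
            "k1_um": float,
            "ka_um": float,
            "k4_um": float,
            "kb_direct_um": float,
        },
        optional={"e_binding_kcal_mol": float},
    ),
    "ic50_replicates": TableSchema(
        name="ic50_replicates",
        columns={"replicate_id": str, "ic50_mg_ml": float},
    ),
    "plate": TableSchema(
        name="plate",
        columns={
            "replicate_id": str,
            "concentration_mg_ml": float,
            "eb1": float,
            "es": float,
        },
    ),
    "dose_response": TableSchema(
        name="dose_response",
        columns={"concentration_mg_ml": float, "inhibition_pct": float},
    ),
    "groups": TableSchema(
        name="groups",
        columns={"group_label": str, "value": float},
        optional={"timepoint": str},
    ),
    "ligand_energies": TableSchema(
        name="ligand_energies",
        columns={"ligand_id": str},
        optional={"e_binding_kcal_mol": float, "ki_um": float},
    ),
    "classification": TableSchema(
        name="classification",
        columns={
            "ligand_id": str,
            "kb_pred_um": float,
            "kb_direct_um": float,
            "fold": float,
            "verdict": str,
        },
    ),
}


def _normalize_decimal(raw: str) -> str:
    return raw.replace(",", ".") if _DECIMAL_COMMA.match(raw) else raw


def _convert(raw: str, target: type, column: str, line_no: int, path: Path):
    raw = raw.strip()
    if target is float:
        raw = _normalize_decimal(raw)
        try:
            value = float(raw)
        except ValueError:
            raise TableError(
                f"{path}, line {line_no}: cannot parse {raw!r} in column {column!r} as a number"
            ) from None
        if not math.isfinite(value):
            raise TableError(
                f"{path}, line {line_no}: non-finite value {raw!r} in column {column!r}"
            )
        return value
    return raw


def read_table(path: str | Path, schema_name: str) -> list[dict]:
    """Read and validate a CSV file against a named schema.

    Headers are matched case-insensitively. Returns one dict per row with
    lowercase keys and typed values; blank optional fields become None.
    """
    if schema_name not in SCHEMAS:
        raise KeyError(f"unknown schema {schema_name!r}; available: {sorted(SCHEMAS)}")
    schema = SCHEMAS[schema_name]
    path = Path(path)
    if not path.exists():
        raise TableError(f"{path}: file does not exist")

    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise TableError(f"{path}: file is empty") from None
        header_map = {}
        for idx, name in enumerate(header):
            header_map[name.strip().lower()] = idx
        missing = [c for c in schema.columns if c not in header_map]
        if missing:
            raise TableError(
                f"{path}: missing required column(s) {missing} for schema "
                f"{schema.name!r}; found header {header}"
            )
        present = {c: header_map[c] for c in schema.all_columns if c in header_map}

        records: list[dict] = []
        for line_no, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            record: dict = {}
            for column, idx in present.items():
                target = schema.all_columns[column]
                raw = row[idx].strip() if idx < len(row) else ""
                if raw == "":
                    if column in schema.optional:
                        record[column] = None
                        continue
                    raise TableError(
                        f"{path}, line {line_no}: required column {column!r} is blank"
                    )
                record[column] = _convert(raw, target, column, line_no, path)
            for column in schema.optional:
                record.setdefault(column, None)
            records.append(record)

    if not records:
        raise TableError(f"{path}: no data rows")
    return records


def _format_value(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)  # shortest exact round-trip representation
    return str(value)


def write_table(
    records: Iterable[Mapping],
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write records as CSV; floats use the shortest round-trip
    representation so that read_table(write_table(x)) preserves values."""
    records = list(records)
    if not records:
        raise TableError("refusing to write an empty table")
    if columns is None:
        columns = list(records[0].keys())
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for record in records:
            writer.writerow([_format_value(record.get(c)) for c in columns])
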