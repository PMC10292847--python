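"""Reading and writing CanReg5 table exports as tab-separated values.

CanReg5 exports are plain tab-delimited text with a single header row and
no quoting dialect: a tab or newline inside a field is unrepresentable.
Columns beyond the key columns are carried verbatim -- the tool rewrites
identifiers and must never touch clinical content.  Output filenames
follow the CanReg5 convention ``<TableName>_yyyy-MM-dd hh_mm_ss``.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .schema import RegistrySchema, TableKind


class TSVFormatError(ValueError):
    """A file does not conform to the plain tab-delimited contract."""


class MissingColumnError(TSVFormatError):
    """A table lacks a key column required for its kind."""


@dataclass
class Table:
    """One CanReg5 table: kind, ordered header and all-string rows."""

    kind: TableKind
    data: pd.DataFrame  # dtype str throughout; column order significant

    @property
    def header(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def copy(self) -> "Table":
        return Table(self.kind, self.data.copy())

    @classmethod
    def from_rows(
        cls, kind: TableKind, header: list[str], rows: list[list[str]]
    ) -> "Table":
        df = pd.DataFrame(rows, columns=header, dtype=object)
        return cls(kind, df.astype(str) if len(df) else df)

    def require_columns(self, cols: tuple[str, ...]) -> None:
        missing = [c for c in cols if c not in self.data.columns]
        if missing:
            raise MissingColumnError(
                f"{self.kind.value} table is missing required column(s): "
                + ", ".join(missing)
            )


@dataclass
class CentreDataset:
    """The three linked tables exported by one registry centre."""

    centre_label: str
    patient: Table
    tumour: Table
    source: Table

    def __post_init__(self) -> None:
        for attr, kind in (
            ("patient", TableKind.PATIENT),
            ("tumour", TableKind.TUMOUR),
            ("source", TableKind.SOURCE),
        ):
            if getattr(self, attr).kind is not kind:
                raise ValueError(f"{attr} table has kind {getattr(self, attr).kind}")

    def tables(self) -> list[Table]:
        return [self.patient, self.tumour, self.source]


#: capitalised table names used in output filenames
_TABLE_FILE_NAMES = {
    TableKind.PATIENT: "Patient",
    TableKind.TUMOUR: "Tumour",
    TableKind.SOURCE: "Source",
}


def timestamped_name(kind: TableKind, clock: dt.datetime) -> str:
    """CanReg5-style export base name, e.g. ``Patient_2022-10-15 17_32_18``."""
    return f"{_TABLE_FILE_NAMES[kind]}_{clock.strftime('%Y-%m-%d %H_%M_%S')}"


def read_table(
    path: str | Path, kind: TableKind, schema: RegistrySchema
) -> Table:
    """Read one table export.

    All columns are preserved verbatim (the schema only names the key
    columns, which must be present); row order is kept.  Both LF and CRLF
    line endings are accepted.

    Raises ``FileNotFoundError``, :class:`MissingColumnError`, or
    :class:`TSVFormatError` for a row whose field count differs from the
    header's.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"{kind.value} table file not found: {path}")
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t", quoting=csv.QUOTE_NONE, quotechar=None)
        try:
            header = next(reader)
        except StopIteration:
            raise TSVFormatError(f"{path}: empty file, expected a header line") from None
        rows: list[list[str]] = []
        for i, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise TSVFormatError(
                    f"{path}, line {i}: {len(row)} fields, header has {len(header)}"
                )
            rows.append(row)
    table = Table.from_rows(kind, header, rows)
    table.require_columns(schema.role_columns(kind))
    return table


def write_table(table: Table, out_dir: str | Path, clock: dt.datetime) -> Path:
    """Write a table as TSV under the timestamped-name convention.

    Returns the written path (``<TableName>_yyyy-MM-dd hh_mm_ss.tsv``).
    A tab or newline inside any field raises :class:`TSVFormatError`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{timestamped_name(table.kind, clock)}.tsv"
    lines = ["\t".join(table.header)]
    for row in table.data.itertuples(index=False, name=None):
        for value in row:
            if "\t" in value or "\n" in value or "\r" in value:
                raise TSVFormatError(
                    f"field value {value!r} contains a tab or newline and cannot "
                    "be written as plain TSV"
                )
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
    return path


def write_centre(
    dataset: CentreDataset, out_dir: str | Path, clock: dt.datetime
) -> list[Path]:
    """Write the three tables of a centre; returns the three paths."""
    return [write_table(t, out_dir, clock) for t in dataset.tables()]


def read_centre(
    patient_path: str | Path,
    tumour_path: str | Path,
    source_path: str | Path,
    schema: RegistrySchema,
    centre_label: str = "",
) -> CentreDataset:
    """Read a centre's three exports into one dataset."""
    return CentreDataset(
        centre_label=centre_label,
        patient=read_table(patient_path, TableKind.PATIENT, schema),
        tumour=read_table(tumour_path, TableKind.TUMOUR, schema),
        source=read_table(source_path, TableKind.SOURCE, schema),
    )
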