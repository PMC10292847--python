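"""Sequential multi-centre merging against an evolving central state.

Centres are converted one after another, each starting where the
previous conversion's ID assignment stopped, so the merged tables cannot
contain a duplicate identifier by construction.  The merge report
nevertheless *recomputes* the collision count on the merged tables, and
:func:`validate_central` offers an exhaustive referential-integrity
audit (duplicate keys, dangling foreign keys, malformed identifiers,
disagreeing redundant link columns) for any central state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .convert import ConversionResult, convert_dataset
from .io_tsv import CentreDataset, Table
from .schema import (
    IDRole,
    IDScheme,
    MalformedIDError,
    RegistrySchema,
    TableKind,
    parse_id,
)


class CentralStateError(ValueError):
    """The central database state violates its own invariants."""


def _empty_table(kind: TableKind, schema: RegistrySchema) -> Table:
    return Table.from_rows(kind, list(schema.role_columns(kind)), [])


@dataclass
class CentralState:
    """Accumulated central tables plus the last assigned registration number.

    The workflow needs only ``last_unique_id``; the tables may be empty
    placeholders when the central database itself lives inside CanReg5.
    """

    last_unique_id: int
    patient: Table
    tumour: Table
    source: Table

    @classmethod
    def empty(
        cls, schema: RegistrySchema, last_unique_id: int = 0
    ) -> "CentralState":
        return cls(
            last_unique_id=last_unique_id,
            patient=_empty_table(TableKind.PATIENT, schema),
            tumour=_empty_table(TableKind.TUMOUR, schema),
            source=_empty_table(TableKind.SOURCE, schema),
        )

    def tables(self) -> list[Table]:
        return [self.patient, self.tumour, self.source]


@dataclass
class CentreMergeEntry:
    """Per-centre line of the merge report."""

    centre_label: str
    patients: int
    tumours: int
    sources: int
    orphan_tumours: int
    orphan_sources: int
    first_assigned_id: int  # 0-width range when the centre had no patients
    last_assigned_id: int


@dataclass
class MergeReport:
    entries: list[CentreMergeEntry] = field(default_factory=list)
    collision_count: int = -1  # recomputed on the merged tables, never assumed

    @property
    def total_patients(self) -> int:
        return sum(e.patients for e in self.entries)

    @property
    def total_tumours(self) -> int:
        return sum(e.tumours for e in self.entries)

    @property
    def total_sources(self) -> int:
        return sum(e.sources for e in self.entries)

    @property
    def total_records(self) -> int:
        return self.total_patients + self.total_tumours + self.total_sources

    def to_frame(self) -> pd.DataFrame:
        """Tabular form of the report (one row per centre plus a total row)."""
        rows = [
            {
                "centre": e.centre_label,
                "patients": e.patients,
                "tumours": e.tumours,
                "sources": e.sources,
                "orphan_tumours": e.orphan_tumours,
                "orphan_sources": e.orphan_sources,
                "first_assigned_id": e.first_assigned_id,
                "last_assigned_id": e.last_assigned_id,
            }
            for e in self.entries
        ]
        rows.append(
            {
                "centre": "TOTAL",
                "patients": self.total_patients,
                "tumours": self.total_tumours,
                "sources": self.total_sources,
                "orphan_tumours": sum(e.orphan_tumours for e in self.entries),
                "orphan_sources": sum(e.orphan_sources for e in self.entries),
                "first_assigned_id": "",
                "last_assigned_id": "",
            }
        )
        return pd.DataFrame(rows)

    def summary_text(self) -> str:
        lines = [
            f"{e.centre_label}: {e.patients} patients, {e.tumours} tumours, "
            f"{e.sources} sources (IDs {e.first_assigned_id}..{e.last_assigned_id})"
            for e in self.entries
        ]
        lines.append(
            f"TOTAL: {self.total_patients} patients, {self.total_tumours} tumours, "
            f"{self.total_sources} sources across {len(self.entries)} centre(s)"
        )
        lines.append(f"primary-key collisions in merged tables: {self.collision_count}")
        return "\n".join(lines)


@dataclass
class Violation:
    table: TableKind
    row_index: int
    rule: str  # duplicate_pk | dangling_fk | malformed_id | fk_pair_inconsistency
    detail: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return not self.violations

    def summary_text(self) -> str:
        if self.is_clean:
            return "no violations"
        return "\n".join(
            f"{v.table.value} row {v.row_index}: {v.rule}: {v.detail}"
            for v in self.violations
        )


def count_pk_collisions(state: CentralState, schema: RegistrySchema) -> int:
    """Number of primary-key values occurring more than once, summed over tables."""
    total = 0
    for table in state.tables():
        counts = table.data[schema.pk_column(table.kind)].value_counts()
        total += int((counts > 1).sum())
    return total


def _append(central: Table, converted: Table) -> Table:
    """Append converted rows, preserving central column order and adding new
    columns at the end; columns absent from one side are filled with ''."""
    if central.n_rows == 0 and not central.header:
        return converted.copy()
    cols = list(central.header) + [
        c for c in converted.header if c not in central.header
    ]
    merged = pd.concat(
        [central.data.reindex(columns=cols), converted.data.reindex(columns=cols)],
        ignore_index=True,
    ).fillna("")
    return Table(central.kind, merged.astype(str) if len(merged) else merged)


def merge_centres(
    central: CentralState,
    centres: list[CentreDataset],
    schema: RegistrySchema,
    scheme: IDScheme,
    orphan_policy: str = "fail",
) -> tuple[CentralState, MergeReport, list[ConversionResult]]:
    """Convert each centre in order and append it to the central tables.

    The new last unique ID of each conversion seeds the next, so assigned
    registration-number ranges are consecutive and disjoint.  Returns the
    new central state, a report with a recomputed collision count, and
    the per-centre conversion results (converted tables + ID maps).

    Raises :class:`CentralStateError` if the central state fails
    :func:`validate_central` up front; conversion errors propagate.
    """
    pre = validate_central(central, schema, scheme)
    if not pre.is_clean:
        raise CentralStateError(
            "central state is invalid:\n" + pre.summary_text()
        )

    state = CentralState(
        last_unique_id=central.last_unique_id,
        patient=central.patient.copy(),
        tumour=central.tumour.copy(),
        source=central.source.copy(),
    )
    report = MergeReport()
    results: list[ConversionResult] = []
    for centre in centres:
        before = state.last_unique_id
        result = convert_dataset(centre, before, schema, scheme, orphan_policy)
        results.append(result)
        conv = result.converted
        report.entries.append(
            CentreMergeEntry(
                centre_label=centre.centre_label,
                patients=conv.patient.n_rows,
                tumours=conv.tumour.n_rows,
                sources=conv.source.n_rows,
                orphan_tumours=len(result.orphans.orphan_tumours),
                orphan_sources=len(result.orphans.orphan_sources),
                first_assigned_id=before + 1,
                last_assigned_id=result.new_last_unique_id,
            )
        )
        state = CentralState(
            last_unique_id=result.new_last_unique_id,
            patient=_append(state.patient, conv.patient),
            tumour=_append(state.tumour, conv.tumour),
            source=_append(state.source, conv.source),
        )
    report.collision_count = count_pk_collisions(state, schema)
    return state, report, results


def validate_central(
    state: CentralState, schema: RegistrySchema, scheme: IDScheme
) -> ValidationReport:
    """Audit a central state for referential-integrity violations.

    Checks, in table order (patient, tumour, source) and then row order:
    duplicate primary keys, malformed identifiers, dangling foreign keys,
    disagreement between the two redundant patient-link columns of the
    tumour table, registration numbers above ``last_unique_id``.
    Problems are reported, never raised.
    """
    report = ValidationReport()

    def add(kind: TableKind, row: int, rule: str, detail: str) -> None:
        report.violations.append(Violation(kind, row, rule, detail))

    def check_pks(
        table: Table, pk_col: str, role: IDRole
    ) -> dict[str, int]:
        """Returns well-formed PK -> row index; reports duplicates/malformed."""
        seen: dict[str, int] = {}
        for i, value in enumerate(table.data[pk_col]):
            try:
                parse_id(value, role, scheme)
            except MalformedIDError as exc:
                add(table.kind, i, "malformed_id", str(exc))
                continue
            if value in seen:
                add(table.kind, i, "duplicate_pk", f"{pk_col}={value!r}")
            else:
                seen[value] = i
        return seen

    for table in state.tables():
        try:
            table.require_columns(schema.role_columns(table.kind))
        except Exception as exc:
            add(table.kind, -1, "malformed_id", str(exc))
            return report

    patient_pks = check_pks(state.patient, schema.patient_pk_col, IDRole.PATIENT_PK)
    record_of_patient: dict[str, str] = {}
    for i, (pk, rec) in enumerate(
        zip(
            state.patient.data[schema.patient_pk_col],
            state.patient.data[schema.patient_record_id_col],
        )
    ):
        try:
            rec_parts = parse_id(rec, IDRole.PATIENT_RECORD_ID, scheme)
            pk_parts = parse_id(pk, IDRole.PATIENT_PK, scheme)
        except MalformedIDError as exc:
            add(TableKind.PATIENT, i, "malformed_id", str(exc))
            continue
        if rec_parts.patient_number != pk_parts.patient_number:
            add(
                TableKind.PATIENT,
                i,
                "fk_pair_inconsistency",
                f"record ID {rec!r} does not embed registration number {pk!r}",
            )
        else:
            record_of_patient[pk] = rec
        if pk_parts.patient_number > state.last_unique_id:
            add(
                TableKind.PATIENT,
                i,
                "malformed_id",
                f"registration number {pk!r} exceeds last_unique_id "
                f"{state.last_unique_id}",
            )

    tumour_pks = check_pks(state.tumour, schema.tumour_pk_col, IDRole.TUMOUR_PK)
    for i, (pk, patient_fk, record_fk) in enumerate(
        zip(
            state.tumour.data[schema.tumour_pk_col],
            state.tumour.data[schema.tumour_patient_fk_col],
            state.tumour.data[schema.tumour_patient_record_fk_col],
        )
    ):
        try:
            parse_id(patient_fk, IDRole.PATIENT_PK, scheme)
            parse_id(record_fk, IDRole.PATIENT_RECORD_ID, scheme)
        except MalformedIDError as exc:
            add(TableKind.TUMOUR, i, "malformed_id", str(exc))
            continue
        if patient_fk not in patient_pks:
            add(
                TableKind.TUMOUR,
                i,
                "dangling_fk",
                f"{schema.tumour_patient_fk_col}={patient_fk!r} matches no patient",
            )
        elif record_fk != record_of_patient.get(patient_fk, record_fk):
            add(
                TableKind.TUMOUR,
                i,
                "fk_pair_inconsistency",
                f"{schema.tumour_patient_record_fk_col}={record_fk!r} disagrees "
                f"with patient {patient_fk!r}",
            )
        if pk in tumour_pks and not pk.startswith(patient_fk[: scheme.patient_width]):
            add(
                TableKind.TUMOUR,
                i,
                "fk_pair_inconsistency",
                f"tumour ID {pk!r} does not embed patient FK {patient_fk!r}",
            )

    for i, (pk, tumour_fk) in enumerate(
        zip(
            state.source.data[schema.source_pk_col],
            state.source.data[schema.source_tumour_fk_col],
        )
    ):
        try:
            parse_id(pk, IDRole.SOURCE_PK, scheme)
        except MalformedIDError as exc:
            add(TableKind.SOURCE, i, "malformed_id", str(exc))
            continue
        try:
            parse_id(tumour_fk, IDRole.TUMOUR_PK, scheme)
        except MalformedIDError as exc:
            add(TableKind.SOURCE, i, "malformed_id", str(exc))
            continue
        if tumour_fk not in tumour_pks:
            add(
                TableKind.SOURCE,
                i,
                "dangling_fk",
                f"{schema.source_tumour_fk_col}={tumour_fk!r} matches no tumour",
            )
        if not pk.startswith(tumour_fk):
            add(
                TableKind.SOURCE,
                i,
                "fk_pair_inconsistency",
                f"source ID {pk!r} does not embed tumour FK {tumour_fk!r}",
            )

    # duplicate-PK check for sources (check_pks not called above for sources)
    seen: set[str] = set()
    for i, value in enumerate(state.source.data[schema.source_pk_col]):
        if value in seen:
            add(TableKind.SOURCE, i, "duplicate_pk", f"{schema.source_pk_col}={value!r}")
        seen.add(value)

    report.violations.sort(
        key=lambda v: ([t for t in TableKind].index(v.table), v.row_index)
    )
    return report
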