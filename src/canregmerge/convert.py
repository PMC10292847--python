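"""Collision-free renumbering of one centre's patient/tumour/source tables.

Each centre numbers its patients sequentially from 1, so the same
registration number refers to different people in different centres.
Conversion assigns every patient of a centre a fresh registration number
strictly after the central database's last unique ID, in input row
order, then rewrites every tumour and source identifier by replacing the
patient-number prefix while preserving the original suffixes.  Link
structure (which tumour belongs to which patient, which source to which
tumour) is preserved exactly, and the emitted :class:`IDMap` is a full
audit trail from old to new identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_tsv import CentreDataset, Table
from .schema import (
    IDOverflowError,
    IDParts,
    IDRole,
    IDScheme,
    RegistrySchema,
    compose_id,
    parse_id,
)


class ConversionError(ValueError):
    """Base class for errors that abort a conversion."""


class DuplicateKeyError(ConversionError):
    """A primary-key value occurs more than once within an input table."""


class OrphanRecordError(ConversionError):
    """A tumour or source references a parent record that does not exist."""


class LinkInconsistencyError(ConversionError):
    """Redundant identifier columns disagree about the same link.

    CanReg5 carries the patient link of a tumour in two columns (patient
    ID and patient record ID) and embeds the parent's number as the
    prefix of each child's own ID; any disagreement among these means
    the export is corrupt, and renumbering it would silently pick a
    winner, so conversion refuses instead.
    """


@dataclass
class OrphanReport:
    """Child records whose parent could not be found."""

    orphan_tumours: list[str] = field(default_factory=list)
    orphan_sources: list[str] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not self.orphan_tumours and not self.orphan_sources


@dataclass
class IDMap:
    """Injective old->new identifier mappings for one conversion."""

    patient_map: dict[str, str] = field(default_factory=dict)
    patient_record_map: dict[str, str] = field(default_factory=dict)
    tumour_map: dict[str, str] = field(default_factory=dict)
    source_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("patient_map", "patient_record_map", "tumour_map", "source_map"):
            m = getattr(self, name)
            if len(set(m.values())) != len(m):
                raise ValueError(f"{name} is not injective")


@dataclass
class ConversionResult:
    converted: CentreDataset
    id_map: IDMap
    new_last_unique_id: int
    orphans: OrphanReport


def _check_unique_pk(table: Table, pk_col: str) -> None:
    dup = table.data[pk_col][table.data[pk_col].duplicated()]
    if len(dup):
        raise DuplicateKeyError(
            f"duplicate {pk_col} value(s) in {table.kind.value} table: "
            + ", ".join(sorted(set(dup)))
        )


def convert_dataset(
    dataset: CentreDataset,
    last_unique_id: int,
    schema: RegistrySchema,
    scheme: IDScheme,
    orphan_policy: str = "fail",
) -> ConversionResult:
    """Renumber a centre's three tables starting after ``last_unique_id``.

    Patients receive registration numbers ``last_unique_id + 1``,
    ``last_unique_id + 2``, ... in input row order.  Tumour and source
    IDs keep their original suffixes on top of the new patient number;
    all foreign-key columns are rewritten consistently; every non-key
    column passes through byte-identical.  Row order is preserved.

    ``orphan_policy`` is ``"fail"`` (raise on a tumour or source whose
    parent is absent) or ``"report_and_skip"`` (drop such rows and list
    them in the returned :class:`OrphanReport`; sources of a skipped
    tumour are skipped too).
    """
    if last_unique_id < 0:
        raise ConversionError(f"last_unique_id must be >= 0, got {last_unique_id}")
    if orphan_policy not in ("fail", "report_and_skip"):
        raise ConversionError(f"unknown orphan policy {orphan_policy!r}")

    for table in dataset.tables():
        table.require_columns(schema.role_columns(table.kind))
        _check_unique_pk(table, schema.pk_column(table.kind))

    n_patients = dataset.patient.n_rows
    if last_unique_id + n_patients >= 10**scheme.patient_width:
        raise IDOverflowError(
            f"assigning {n_patients} patients after ID {last_unique_id} exceeds "
            f"the {scheme.patient_width}-digit registration-number width"
        )

    id_map = IDMap()
    old_record_of_patient: dict[str, str] = {}  # old REGNO -> old record ID

    # --- patients: sequential renumbering in row order -------------------
    patient_df = dataset.patient.data.copy()
    new_pks: list[str] = []
    new_record_ids: list[str] = []
    for offset, (old_pk, old_rec) in enumerate(
        zip(
            patient_df[schema.patient_pk_col],
            patient_df[schema.patient_record_id_col],
        ),
        start=1,
    ):
        pk_parts = parse_id(old_pk, IDRole.PATIENT_PK, scheme)
        rec_parts = parse_id(old_rec, IDRole.PATIENT_RECORD_ID, scheme)
        if rec_parts.patient_number != pk_parts.patient_number:
            raise LinkInconsistencyError(
                f"patient record ID {old_rec!r} does not embed its own "
                f"registration number {old_pk!r}"
            )
        new_number = last_unique_id + offset
        new_pk = compose_id(IDParts(new_number), IDRole.PATIENT_PK, scheme)
        new_rec = compose_id(
            IDParts(new_number, record_suffix=rec_parts.record_suffix),
            IDRole.PATIENT_RECORD_ID,
            scheme,
        )
        id_map.patient_map[old_pk] = new_pk
        id_map.patient_record_map[old_rec] = new_rec
        old_record_of_patient[old_pk] = old_rec
        new_pks.append(new_pk)
        new_record_ids.append(new_rec)
    patient_df[schema.patient_pk_col] = new_pks
    patient_df[schema.patient_record_id_col] = new_record_ids

    # --- tumours: new patient prefix + original tumour suffix ------------
    tumour_df = dataset.tumour.data.copy()
    orphans = OrphanReport()
    orphan_tumour_rows: list[int] = []
    new_tumour_pks: list[str] = []
    new_patient_fks: list[str] = []
    new_record_fks: list[str] = []
    for idx, (old_pk, patient_fk, record_fk) in enumerate(
        zip(
            tumour_df[schema.tumour_pk_col],
            tumour_df[schema.tumour_patient_fk_col],
            tumour_df[schema.tumour_patient_record_fk_col],
        )
    ):
        pk_parts = parse_id(old_pk, IDRole.TUMOUR_PK, scheme)
        fk_parts = parse_id(patient_fk, IDRole.PATIENT_PK, scheme)
        if pk_parts.patient_number != fk_parts.patient_number:
            raise LinkInconsistencyError(
                f"tumour ID {old_pk!r} does not embed its patient FK {patient_fk!r}"
            )
        if patient_fk not in id_map.patient_map:
            orphans.orphan_tumours.append(old_pk)
            orphan_tumour_rows.append(idx)
            new_tumour_pks.append(old_pk)
            new_patient_fks.append(patient_fk)
            new_record_fks.append(record_fk)
            continue
        if record_fk != old_record_of_patient[patient_fk]:
            raise LinkInconsistencyError(
                f"tumour {old_pk!r}: patient record FK {record_fk!r} disagrees "
                f"with patient {patient_fk!r}'s record ID "
                f"{old_record_of_patient[patient_fk]!r}"
            )
        new_patient_pk = id_map.patient_map[patient_fk]
        new_tumour_pk = (
            new_patient_pk[: scheme.patient_width] + pk_parts.tumour_suffix
        )
        id_map.tumour_map[old_pk] = new_tumour_pk
        new_tumour_pks.append(new_tumour_pk)
        new_patient_fks.append(new_patient_pk)
        new_record_fks.append(id_map.patient_record_map[record_fk])
    if orphans.orphan_tumours and orphan_policy == "fail":
        raise OrphanRecordError(
            "tumour record(s) reference missing patient(s): "
            + ", ".join(orphans.orphan_tumours)
        )
    tumour_df[schema.tumour_pk_col] = new_tumour_pks
    tumour_df[schema.tumour_patient_fk_col] = new_patient_fks
    tumour_df[schema.tumour_patient_record_fk_col] = new_record_fks
    if orphan_tumour_rows:
        tumour_df = tumour_df.drop(tumour_df.index[orphan_tumour_rows]).reset_index(
            drop=True
        )

    # --- sources: new tumour prefix + original source suffix -------------
    source_df = dataset.source.data.copy()
    orphan_source_rows: list[int] = []
    new_source_pks: list[str] = []
    new_tumour_fks: list[str] = []
    for idx, (old_pk, tumour_fk) in enumerate(
        zip(
            source_df[schema.source_pk_col],
            source_df[schema.source_tumour_fk_col],
        )
    ):
        pk_parts = parse_id(old_pk, IDRole.SOURCE_PK, scheme)
        fk_parts = parse_id(tumour_fk, IDRole.TUMOUR_PK, scheme)
        if (
            pk_parts.patient_number != fk_parts.patient_number
            or pk_parts.tumour_suffix != fk_parts.tumour_suffix
        ):
            raise LinkInconsistencyError(
                f"source ID {old_pk!r} does not embed its tumour FK {tumour_fk!r}"
            )
        if tumour_fk not in id_map.tumour_map:
            orphans.orphan_sources.append(old_pk)
            orphan_source_rows.append(idx)
            new_source_pks.append(old_pk)
            new_tumour_fks.append(tumour_fk)
            continue
        new_tumour_pk = id_map.tumour_map[tumour_fk]
        new_source_pk = new_tumour_pk + pk_parts.source_suffix
        id_map.source_map[old_pk] = new_source_pk
        new_source_pks.append(new_source_pk)
        new_tumour_fks.append(new_tumour_pk)
    if orphans.orphan_sources and orphan_policy == "fail":
        raise OrphanRecordError(
            "source record(s) reference missing tumour(s): "
            + ", ".join(orphans.orphan_sources)
        )
    source_df[schema.source_pk_col] = new_source_pks
    source_df[schema.source_tumour_fk_col] = new_tumour_fks
    if orphan_source_rows:
        source_df = source_df.drop(source_df.index[orphan_source_rows]).reset_index(
            drop=True
        )

    converted = CentreDataset(
        centre_label=dataset.centre_label,
        patient=Table(dataset.patient.kind, patient_df),
        tumour=Table(dataset.tumour.kind, tumour_df),
        source=Table(dataset.source.kind, source_df),
    )
    # re-run the injectivity invariant on the completed maps
    return ConversionResult(
        converted=converted,
        id_map=IDMap(
            dict(id_map.patient_map),
            dict(id_map.patient_record_map),
            dict(id_map.tumour_map),
            dict(id_map.source_map),
        ),
        new_last_unique_id=last_unique_id + n_patients,
        orphans=orphans,
    )
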