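"""Shared fixtures and the independent relabel-by-join oracle."""

from __future__ import annotations

import pandas as pd
import pytest

from canregmerge import (
    CentreDataset,
    IDScheme,
    RegistrySchema,
    Table,
    TableKind,
)


@pytest.fixture
def schema() -> RegistrySchema:
    return RegistrySchema()


@pytest.fixture
def small_scheme() -> IDScheme:
    """4-digit registration numbers, 2-digit suffixes — compact worked examples."""
    return IDScheme(patient_width=4, record_suffix_width=2,
                    tumour_suffix_width=2, source_suffix_width=2)


def make_dataset(
    schema: RegistrySchema,
    patients: list[tuple[str, str]],
    tumours: list[tuple[str, str, str]],
    sources: list[tuple[str, str]],
    label: str = "centre",
) -> CentreDataset:
    """Handmade dataset from (pk, ...) tuples, with one filler column each."""
    return CentreDataset(
        centre_label=label,
        patient=Table.from_rows(
            TableKind.PATIENT,
            [schema.patient_pk_col, schema.patient_record_id_col, "SEX"],
            [[pk, rec, "1"] for pk, rec in patients],
        ),
        tumour=Table.from_rows(
            TableKind.TUMOUR,
            [
                schema.tumour_pk_col,
                schema.tumour_patient_record_fk_col,
                schema.tumour_patient_fk_col,
                "TOPOGRAPHY",
            ],
            [[pk, rec_fk, pat_fk, "C50.9"] for pk, rec_fk, pat_fk in tumours],
        ),
        source=Table.from_rows(
            TableKind.SOURCE,
            [schema.source_pk_col, schema.source_tumour_fk_col, "SOURCE"],
            [[pk, fk, "PATHOLOGY"] for pk, fk in sources],
        ),
    )


def oracle_convert(
    dataset: CentreDataset,
    last_unique_id: int,
    schema: RegistrySchema,
    scheme: IDScheme,
) -> CentreDataset:
    """Brute-force relabel-by-join reference conversion.

    Relabels patients sequentially, then rebuilds the tumour and source
    tables by joining each child row to its parent on the *old* foreign
    key and recomposing the child ID by plain string slicing.  Shares no
    code with the conversion under test.
    """
    pw = scheme.patient_width
    pat = dataset.patient.data.copy()
    old_pks = list(pat[schema.patient_pk_col])
    new_pk_of = {
        old: str(last_unique_id + i + 1).zfill(pw) for i, old in enumerate(old_pks)
    }
    old_rec_of = dict(zip(old_pks, pat[schema.patient_record_id_col]))
    new_rec_of = {
        old_rec_of[old]: new_pk_of[old] + old_rec_of[old][pw:] for old in old_pks
    }
    pat[schema.patient_pk_col] = [new_pk_of[o] for o in old_pks]
    pat[schema.patient_record_id_col] = [
        new_rec_of[r] for r in dataset.patient.data[schema.patient_record_id_col]
    ]

    tum = dataset.tumour.data.copy()
    new_tumour_of = {}
    for old_tid, pat_fk in zip(
        tum[schema.tumour_pk_col], tum[schema.tumour_patient_fk_col]
    ):
        new_tumour_of[old_tid] = new_pk_of[pat_fk] + old_tid[pw:]
    tum[schema.tumour_pk_col] = [new_tumour_of[t] for t in tum[schema.tumour_pk_col]]
    tum[schema.tumour_patient_record_fk_col] = [
        new_rec_of[r] for r in tum[schema.tumour_patient_record_fk_col]
    ]
    tum[schema.tumour_patient_fk_col] = [
        new_pk_of[p] for p in tum[schema.tumour_patient_fk_col]
    ]

    src = dataset.source.data.copy()
    tw = pw + scheme.tumour_suffix_width
    src[schema.source_pk_col] = [
        new_tumour_of[fk] + sid[tw:]
        for sid, fk in zip(src[schema.source_pk_col], src[schema.source_tumour_fk_col])
    ]
    src[schema.source_tumour_fk_col] = [
        new_tumour_of[fk] for fk in src[schema.source_tumour_fk_col]
    ]
    return CentreDataset(
        centre_label=dataset.centre_label,
        patient=Table(TableKind.PATIENT, pat),
        tumour=Table(TableKind.TUMOUR, tum),
        source=Table(TableKind.SOURCE, src),
    )


def assert_datasets_equal(a: CentreDataset, b: CentreDataset) -> None:
    for ta, tb in zip(a.tables(), b.tables()):
        pd.testing.assert_frame_equal(
            ta.data.reset_index(drop=True), tb.data.reset_index(drop=True)
        )
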