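"""Synthetic CanReg5 centre exports for testing and demonstration.

Generates centres whose patients are numbered sequentially from a
configurable start (default 1).  Because every centre starts its own
sequence at 1, two independently generated centres share identifier
values by default -- exactly the cross-centre collision situation the
merge tool exists to resolve.  Non-key columns (sex, dates, topography
and the like) are filled with deterministic pseudo-random values of
plausible shape; they carry no epidemiological meaning, only the link
structure matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_tsv import CentreDataset, Table
from .schema import (
    IDOverflowError,
    IDParts,
    IDRole,
    IDScheme,
    RegistrySchema,
    TableKind,
    compose_id,
)

#: record counts received centrally from the Sri Lankan hospital network,
#: one entry per hospital whose export went through the ID conversion
SRI_LANKA_HOSPITAL_RECORDS: tuple[tuple[str, int], ...] = (
    ("District General Hospital, Ampara", 90),
    ("Teaching Hospital, Anuradhapura", 1388),
    ("District General Hospital, Avissawella", 247),
    ("Provincial General Hospital, Badulla", 2472),
    ("Teaching Hospital, Batticaloa", 2045),
    ("District General Hospital, Chilaw", 256),
    ("District General Hospital, Gampaha", 637),
    ("District General Hospital, Hambanthota", 1320),
    ("Teaching Hospital, Jaffna (Base Hospital - Tellipalai)", 1129),
    ("National Hospital, Kandy", 4763),
    ("Teaching Hospital, Karapitiya", 2041),
    ("District General Hospital, Kegalle", 320),
    ("Teaching Hospital, Kurunegala", 1524),
    ("District General Hospital, Monaragala", 387),
    ("District General Hospital, Nuwaraeliya", 354),
    ("District General Hospital, Polonnaruwa", 140),
    ("Teaching Hospital, Ragama", 189),
    ("Teaching Hospital, Rathnapura", 2451),
    ("District General Hospital, Trincomalee", 265),
    ("District General Hospital, Vavuniya", 264),
    ("Pathology laboratory (Excel sheet submission)", 7332),
    ("Apeksha Hospital (National Cancer Institute)", 17788),
)


@dataclass(frozen=True)
class CountDistribution:
    """Distribution over non-negative integer counts.

    Either a fixed value, or a set of values with probabilities.
    """

    values: tuple[int, ...]
    probabilities: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not self.values or any(v < 0 for v in self.values):
            raise ValueError("count distribution needs non-negative integer support")
        if self.probabilities is not None:
            if len(self.probabilities) != len(self.values):
                raise ValueError("probabilities must match values in length")
            if abs(sum(self.probabilities) - 1.0) > 1e-9:
                raise ValueError("probabilities must sum to 1")

    @classmethod
    def fixed(cls, k: int) -> "CountDistribution":
        return cls((k,))

    @classmethod
    def uniform_range(cls, lo: int, hi: int) -> "CountDistribution":
        return cls(tuple(range(lo, hi + 1)))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if len(self.values) == 1:
            return np.full(n, self.values[0], dtype=int)
        return rng.choice(np.array(self.values), size=n, p=self.probabilities)

    @property
    def max_value(self) -> int:
        return max(self.values)


@dataclass(frozen=True)
class GenSpec:
    """Recipe for one synthetic centre export."""

    centre_label: str
    n_patients: int
    tumours_per_patient: CountDistribution = field(
        default_factory=lambda: CountDistribution.fixed(1)
    )
    sources_per_tumour: CountDistribution = field(
        default_factory=lambda: CountDistribution.fixed(1)
    )
    start_regno: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.start_regno < 1:
            raise ValueError("start_regno must be >= 1")


_SITES = ("C16.9", "C18.7", "C20.9", "C34.1", "C50.9", "C53.9", "C61.9", "C73.9")
_MORPHOLOGIES = ("8000", "8070", "8140", "8500", "9861")
_SOURCES = ("PATHOLOGY", "CLINICAL", "RADIOLOGY", "DEATH CERTIFICATE")


def _date(rng: np.random.Generator, lo_year: int, hi_year: int) -> str:
    return (
        f"{rng.integers(lo_year, hi_year + 1):04d}"
        f"{rng.integers(1, 13):02d}{rng.integers(1, 29):02d}"
    )


def generate_centre(
    spec: GenSpec,
    schema: RegistrySchema | None = None,
    scheme: IDScheme | None = None,
) -> CentreDataset:
    """Generate one centre's three tables from a seeded recipe.

    Patients are numbered ``start_regno, start_regno + 1, ...``; each
    patient's tumours take suffixes 01, 02, ... and each tumour's sources
    likewise; the patient record suffix is always 01.  The same spec
    always yields byte-identical tables.

    Raises :class:`IDOverflowError` if a number or per-parent count does
    not fit the scheme's widths.
    """
    schema = schema or RegistrySchema()
    scheme = scheme or IDScheme()
    rng = np.random.default_rng(spec.seed)

    last_number = spec.start_regno + spec.n_patients - 1
    if last_number >= 10**scheme.patient_width:
        raise IDOverflowError(
            f"registration numbers up to {last_number} do not fit in "
            f"{scheme.patient_width} digits"
        )
    for dist, width, what in (
        (spec.tumours_per_patient, scheme.tumour_suffix_width, "tumours per patient"),
        (spec.sources_per_tumour, scheme.source_suffix_width, "sources per tumour"),
    ):
        if dist.max_value >= 10**width:
            raise IDOverflowError(f"{what} can reach {dist.max_value}, "
                                  f"suffix width is {width} digits")

    n = spec.n_patients
    tumour_counts = spec.tumours_per_patient.sample(rng, n)

    patient_rows: list[list[str]] = []
    tumour_rows: list[list[str]] = []
    source_rows: list[list[str]] = []
    for i in range(n):
        number = spec.start_regno + i
        regno = compose_id(IDParts(number), IDRole.PATIENT_PK, scheme)
        record_suffix = "1".zfill(scheme.record_suffix_width)
        record_id = compose_id(
            IDParts(number, record_suffix=record_suffix),
            IDRole.PATIENT_RECORD_ID,
            scheme,
        )
        sex = str(rng.integers(1, 3))
        birth = _date(rng, 1930, 2000)
        patient_rows.append([regno, record_id, sex, birth])
        n_tumours = int(tumour_counts[i])
        source_counts = spec.sources_per_tumour.sample(rng, n_tumours)
        for t in range(1, n_tumours + 1):
            t_suffix = str(t).zfill(scheme.tumour_suffix_width)
            tumour_id = compose_id(
                IDParts(number, tumour_suffix=t_suffix), IDRole.TUMOUR_PK, scheme
            )
            tumour_rows.append(
                [
                    tumour_id,
                    record_id,
                    regno,
                    _date(rng, 2015, 2021),
                    str(rng.choice(np.array(_SITES))),
                    str(rng.choice(np.array(_MORPHOLOGIES))),
                ]
            )
            for s in range(1, int(source_counts[t - 1]) + 1):
                s_suffix = str(s).zfill(scheme.source_suffix_width)
                source_id = compose_id(
                    IDParts(number, tumour_suffix=t_suffix, source_suffix=s_suffix),
                    IDRole.SOURCE_PK,
                    scheme,
                )
                source_rows.append(
                    [source_id, tumour_id, str(rng.choice(np.array(_SOURCES)))]
                )

    patient = Table.from_rows(
        TableKind.PATIENT,
        [schema.patient_pk_col, schema.patient_record_id_col, "SEX", "BIRTHD"],
        patient_rows,
    )
    tumour = Table.from_rows(
        TableKind.TUMOUR,
        [
            schema.tumour_pk_col,
            schema.tumour_patient_record_fk_col,
            schema.tumour_patient_fk_col,
            "INCID",
            "TOPOGRAPHY",
            "MORPHOLOGY",
        ],
        tumour_rows,
    )
    source = Table.from_rows(
        TableKind.SOURCE,
        [schema.source_pk_col, schema.source_tumour_fk_col, "SOURCE"],
        source_rows,
    )
    return CentreDataset(spec.centre_label, patient, tumour, source)


def generate_scenario(
    per_centre_counts: list[tuple[str, int]],
    seed: int = 0,
    schema: RegistrySchema | None = None,
    scheme: IDScheme | None = None,
) -> list[CentreDataset]:
    """One centre per (label, n_records) entry, maximally colliding.

    Each record is realised as one patient with exactly one tumour and
    one source, and every centre numbers its patients from 1 -- the
    structure of a registry network submitting independently numbered
    exports for central merging.
    """
    return [
        generate_centre(
            GenSpec(
                centre_label=label,
                n_patients=n,
                tumours_per_patient=CountDistribution.fixed(1),
                sources_per_tumour=CountDistribution.fixed(1),
                start_regno=1,
                seed=seed + i,
            ),
            schema,
            scheme,
        )
        for i, (label, n) in enumerate(per_centre_counts)
    ]
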