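"""Registry table schema and composite identifier scheme.

CanReg5 stores a registry as three linked tables -- patient, tumour and
source.  Identifiers nest: the patient registration number (REGNO) is a
zero-padded decimal string; the patient *record* ID appends a record
suffix; a tumour ID appends a tumour suffix to the registration number;
a source ID appends a source suffix to the tumour ID.  Column names and
component widths vary between registries, so both are configurable and
carried explicitly through every operation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, fields
from pathlib import Path


class TableKind(enum.Enum):
    """The three linked CanReg5 tables."""

    PATIENT = "patient"
    TUMOUR = "tumour"
    SOURCE = "source"


class IDRole(enum.Enum):
    """Role an identifier column plays in the three-table link structure."""

    PATIENT_PK = "patient_pk"
    PATIENT_RECORD_ID = "patient_record_id"
    TUMOUR_PK = "tumour_pk"
    SOURCE_PK = "source_pk"


#: suffix components each role carries, in composition order
_ROLE_SUFFIXES: dict[IDRole, tuple[str, ...]] = {
    IDRole.PATIENT_PK: (),
    IDRole.PATIENT_RECORD_ID: ("record_suffix",),
    IDRole.TUMOUR_PK: ("tumour_suffix",),
    IDRole.SOURCE_PK: ("tumour_suffix", "source_suffix"),
}


class SchemaError(ValueError):
    """Invalid schema or ID-scheme configuration."""


class MalformedIDError(ValueError):
    """An identifier string does not fit the configured composite scheme."""


class IDOverflowError(MalformedIDError):
    """A registration number needs more digits than the scheme allows."""


@dataclass(frozen=True)
class RegistrySchema:
    """Column names of the key columns in the three tables.

    Defaults are the standard CanReg5 names; registries may rename any of
    them, so every operation takes the schema explicitly.
    """

    patient_pk_col: str = "REGNO"
    patient_record_id_col: str = "PATIENTRECORDID"
    tumour_pk_col: str = "TUMOURID"
    tumour_patient_record_fk_col: str = "PATIENTRECORDIDTUMOURTABLE"
    tumour_patient_fk_col: str = "PATIENTIDTUMOURTABLE"
    source_pk_col: str = "SOURCERECORDID"
    source_tumour_fk_col: str = "TUMOURIDSOURCETABLE"

    def __post_init__(self) -> None:
        for f in fields(self):
            if not getattr(self, f.name):
                raise SchemaError(f"column name for {f.name} must be non-empty")
        for kind in TableKind:
            cols = self.role_columns(kind)
            if len(set(cols)) != len(cols):
                raise SchemaError(
                    f"duplicate role column name within {kind.value} table: {cols}"
                )

    def role_columns(self, kind: TableKind) -> tuple[str, ...]:
        """Key columns this tool rewrites in a table of the given kind."""
        if kind is TableKind.PATIENT:
            return (self.patient_pk_col, self.patient_record_id_col)
        if kind is TableKind.TUMOUR:
            return (
                self.tumour_pk_col,
                self.tumour_patient_record_fk_col,
                self.tumour_patient_fk_col,
            )
        return (self.source_pk_col, self.source_tumour_fk_col)

    def pk_column(self, kind: TableKind) -> str:
        return {
            TableKind.PATIENT: self.patient_pk_col,
            TableKind.TUMOUR: self.tumour_pk_col,
            TableKind.SOURCE: self.source_pk_col,
        }[kind]


@dataclass(frozen=True)
class IDScheme:
    """Digit widths of the composite-ID components.

    ``patient_width`` bounds the largest assignable registration number at
    ``10**patient_width - 1``; suffix widths bound tumours per patient,
    sources per tumour and records per patient the same way.
    """

    patient_width: int = 8
    record_suffix_width: int = 2
    tumour_suffix_width: int = 2
    source_suffix_width: int = 2

    def __post_init__(self) -> None:
        for f in fields(self):
            w = getattr(self, f.name)
            if not isinstance(w, int) or w < 1:
                raise SchemaError(f"{f.name} must be an integer >= 1, got {w!r}")

    def suffix_width(self, component: str) -> int:
        return getattr(self, f"{component.rsplit('_suffix', 1)[0]}_suffix_width")

    def total_width(self, role: IDRole) -> int:
        """Exact length of a well-formed identifier string for *role*."""
        return self.patient_width + sum(
            self.suffix_width(c) for c in _ROLE_SUFFIXES[role]
        )


@dataclass(frozen=True)
class IDParts:
    """Decomposed identifier: registration number plus role suffixes.

    Suffixes are kept as digit strings because their zero-padding is
    significant and preserved verbatim through conversion.
    """

    patient_number: int
    record_suffix: str | None = None
    tumour_suffix: str | None = None
    source_suffix: str | None = None

    def __post_init__(self) -> None:
        if self.patient_number < 0:
            raise MalformedIDError(
                f"patient_number must be non-negative, got {self.patient_number}"
            )
        for name in ("record_suffix", "tumour_suffix", "source_suffix"):
            v = getattr(self, name)
            if v is not None and not (v.isascii() and v.isdigit()):
                raise MalformedIDError(f"{name} must be a digit string, got {v!r}")


def default_canreg_schema() -> RegistrySchema:
    """Schema with the standard CanReg5 column names."""
    return RegistrySchema()


def compose_id(parts: IDParts, role: IDRole, scheme: IDScheme) -> str:
    """Build the identifier string for *role* from its components.

    The registration number is zero-padded to ``scheme.patient_width``
    digits and the role's suffixes are appended in record/tumour/source
    order.  Raises :class:`IDOverflowError` if the number does not fit,
    :class:`MalformedIDError` on a missing, extra or wrong-width suffix.
    """
    if parts.patient_number >= 10**scheme.patient_width:
        raise IDOverflowError(
            f"registration number {parts.patient_number} does not fit in "
            f"{scheme.patient_width} digits"
        )
    required = _ROLE_SUFFIXES[role]
    for name in ("record_suffix", "tumour_suffix", "source_suffix"):
        v = getattr(parts, name)
        if name in required:
            if v is None:
                raise MalformedIDError(f"role {role.value} requires {name}")
            if len(v) != scheme.suffix_width(name):
                raise MalformedIDError(
                    f"{name} {v!r} must be {scheme.suffix_width(name)} digits wide"
                )
        elif v is not None:
            raise MalformedIDError(f"role {role.value} does not take {name}")
    out = str(parts.patient_number).zfill(scheme.patient_width)
    for name in required:
        out += getattr(parts, name)
    return out


def parse_id(id_string: str, role: IDRole, scheme: IDScheme) -> IDParts:
    """Split an identifier string into its components (inverse of compose).

    Raises :class:`MalformedIDError` on non-digit characters or a length
    other than the role's exact total width.
    """
    expected = scheme.total_width(role)
    if len(id_string) != expected:
        raise MalformedIDError(
            f"{role.value} ID {id_string!r} has length {len(id_string)}, "
            f"expected {expected}"
        )
    if not (id_string.isascii() and id_string.isdigit()):
        raise MalformedIDError(f"{role.value} ID {id_string!r} contains non-digits")
    pos = scheme.patient_width
    kwargs: dict[str, str] = {}
    for name in _ROLE_SUFFIXES[role]:
        w = scheme.suffix_width(name)
        kwargs[name] = id_string[pos : pos + w]
        pos += w
    return IDParts(patient_number=int(id_string[: scheme.patient_width]), **kwargs)


# ---------------------------------------------------------------------------
# plain-text configuration (key = value, '#' comments)

_SCHEMA_KEYS = {f.name for f in fields(RegistrySchema)}
_SCHEME_KEYS = {f.name for f in fields(IDScheme)}


def load_config(path: str | Path) -> tuple[RegistrySchema, IDScheme]:
    """Read schema column names and ID widths from a key = value file.

    Unknown keys are rejected; omitted keys keep their defaults.
    """
    schema_kw: dict[str, str] = {}
    scheme_kw: dict[str, int] = {}
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise SchemaError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key in _SCHEMA_KEYS:
            schema_kw[key] = value
        elif key in _SCHEME_KEYS:
            try:
                scheme_kw[key] = int(value)
            except ValueError:
                raise SchemaError(f"{path}:{lineno}: {key} must be an integer") from None
        else:
            raise SchemaError(f"{path}:{lineno}: unknown key {key!r}")
    return RegistrySchema(**schema_kw), IDScheme(**scheme_kw)


def dump_config(schema: RegistrySchema, scheme: IDScheme, path: str | Path) -> None:
    """Write a configuration file that :func:`load_config` reads back."""
    lines = ["# CanReg5 registry schema configuration"]
    lines += [f"{f.name} = {getattr(schema, f.name)}" for f in fields(schema)]
    lines += [f"{f.name} = {getattr(scheme, f.name)}" for f in fields(scheme)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
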