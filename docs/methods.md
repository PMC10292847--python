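# Methods

## Conversion model

The central object is a deterministic relabeling of the three-table
CanReg5 schema.  A centre export is a triple of tables
(patient, tumour, source) with composite decimal identifiers:

- patient PK `REGNO` = registration number, `w_p` digits (default 8);
- patient record ID = number + record suffix (`w_r` digits, default 2);
- tumour PK = number + tumour suffix (`w_t`, default 2);
- source PK = tumour PK + source suffix (`w_s`, default 2).

Given the central database's last unique ID `L`, conversion maps the
centre's `n` patients, in input row order, to numbers `L+1 … L+n`, and
every child identifier to (new parent prefix + original suffix).  The
mapping is injective by construction: new patient numbers are fresh and
suffixes are untouched, so distinct old IDs cannot coincide.  Sequential
multi-centre merging threads `L` through the conversions, giving each
centre a disjoint, consecutive, auditable ID range.  The merge report
still *recounts* duplicate PKs on the merged tables rather than assuming
zero.

Suffix preservation (rather than renumbering tumours/sources from 01) was
a genuinely open choice; we preserve them because it keeps within-patient
sequencing semantics intact, makes the conversion invertible through the
emitted ID maps, and means a record's suffix can be cited unchanged in
correspondence with the originating centre.

## Consistency rules

CanReg5 exports carry redundant link information: the tumour table stores
the patient link twice (`PATIENTIDTUMOURTABLE` and
`PATIENTRECORDIDTUMOURTABLE`), and every child PK embeds its parent's
number as a prefix.  The converter treats `PATIENTIDTUMOURTABLE` as the
authoritative patient link and *requires* the redundant copies to agree
(record-FK equal to that patient's record ID; child-PK prefix equal to the
parent FK).  Any disagreement raises an error instead of silently picking
a winner, because prefix/FK divergence would also break injectivity of the
suffix-preserving relabeling.  Duplicate PKs within an input table are an
error: exports from a healthy CanReg5 instance are internally unique.

Orphan children (a tumour whose patient FK matches no patient, a source
whose tumour FK matches no tumour — including sources of a skipped orphan
tumour) are governed by a policy: `fail` (default) aborts listing the
offenders; `report_and_skip` drops them and reports their old PKs.  Count
conservation is therefore guaranteed only under `fail`.

`validate_central` audits any state against four rule classes — duplicate
PK, malformed ID, dangling FK, FK-pair inconsistency — plus registration
numbers exceeding the recorded last unique ID, reporting violations in
deterministic (table, row) order rather than raising.

## Parameters

- `patient_width` (default 8 digits): caps the registry at 10^8 − 1
  patients; conversion refuses to assign a number that would not fit.
- suffix widths (default 2 each): cap records/tumours per patient and
  sources per tumour at 99.
- column names: the seven key columns default to the standard CanReg5
  names (`REGNO`, `PATIENTRECORDID`, `TUMOURID`, …) and are configurable
  in a `key = value` text file, since deployments rename them.
- `last_unique_id`: the highest registration number already assigned
  centrally; the only state the workflow strictly needs.

## File format

Exports are plain tab-delimited UTF-8 text with one header row, no
quoting dialect: quotes are literal data, and a tab or newline inside a
field is unrepresentable (write raises).  CRLF and LF are both accepted
on read; LF is written.  Output filenames follow the CanReg5 convention
`<TableName>_yyyy-MM-dd hh_mm_ss.tsv`; the timestamp is an injected
parameter so filenames are testable, with wall-clock time as the CLI
default.  All columns beyond the seven key columns are carried verbatim.

## Synthetic data

The generator emulates the structure the method depends on and nothing
more: sequential patient numbers from a configurable start (default 1, so
independently generated centres collide by design), per-patient tumour
counts and per-tumour source counts drawn from small integer
distributions, suffixes assigned 01, 02, …, and seeded filler columns
(sex, dates, ICD-O-like topography/morphology codes) with plausible shape
but no epidemiological realism.  The bundled hospital-network scenario
instantiates one centre per Sri Lankan hospital with the record counts
received centrally (22 centres, 47,402 records in total), each record as
one patient with one tumour and one source — the reading under which the
published per-hospital "records" counts are reproduced exactly.

Passing tests on these data therefore demonstrate correctness of the
*relabeling and its guarantees* (conservation, consecutive assignment,
zero collisions, referential integrity) — not robustness to the messiness
of real exports (encoding damage, hand-edited IDs, duplicated people
registered at two hospitals, which is record linkage and out of scope).

## Numerical and design choices

- IDs are strings end to end; leading zeros are significant and numeric
  interpretation happens only inside parse/compose.
- Patient record suffixes other than `01` are accepted and preserved; the
  generator emits `01`, matching the common single-record case.
- Patients with zero tumours and tumours with zero sources are legal
  (one-to-many, not one-to-at-least-one).
- Merge order is the manifest order; totals and link structure are
  order-independent (verified by test), assigned ID values are not.
- Randomized suites use fixed seeds; problem sizes (≤50 patients per
  random dataset, 200 oracle trials, merges of up to 10 centres, the
  47k-record scenario) keep the whole suite around ten seconds while the
  scenario still exercises the full production scale.

## Known limitations

- Only numeric, fixed-width, positional composite IDs are supported — not
  alphanumeric national IDs.
- The tool stops at producing converted TSV files and an audit map; the
  authoritative append into the central database is CanReg5's own import,
  which is not reimplemented.
- No probabilistic record linkage: two centres registering the same
  person remain two patients after merging.
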