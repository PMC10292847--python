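# canregmerge

Collision-free merging of multi-centre CanReg5 cancer-registry exports.

## The problem

A population-based cancer registry often collects data at many hospital
centres, each running its own copy of the CanReg5 registry software.
CanReg5 stores a registry as three linked tables — **patient**, **tumour**
and **source** — where a patient can have several tumours and a tumour
several source (notification) records.  Every centre numbers its patients
sequentially from 1, so when exports arrive at the central office the same
registration number denotes *different* people at different centres.
Concatenating the files corrupts the database; editing the IDs by hand in a
spreadsheet is slow and error-prone, because each patient ID is embedded in
its tumour and source IDs and in three foreign-key columns.

`canregmerge` automates the fix.  It renumbers every identifier of a
centre's export to start *after* the central database's last unique ID,
preserving the patient→tumour→source link structure exactly, so converted
files can be imported into the central CanReg5 instance with no possibility
of an ID collision.

## The ID model

Identifiers are zero-padded decimal strings that nest
(widths configurable per registry; defaults 8/2/2/2):

| identifier           | composition                                   | example (4/2/2/2) |
|----------------------|-----------------------------------------------|-------------------|
| `REGNO`              | patient number, `w_p` digits                  | `0501`            |
| `PATIENTRECORDID`    | patient number + record suffix                | `050101`          |
| `TUMOURID`           | patient number + tumour suffix                | `050102`          |
| `SOURCERECORDID`     | tumour ID + source suffix                     | `05010201`        |

Conversion of a centre against a central database whose last unique ID is
`L` assigns its patients the numbers `L+1, L+2, …` in input row order, then
rewrites each tumour and source ID by replacing the patient-number prefix
while keeping the original suffixes, and rewrites the three foreign-key
columns (`PATIENTIDTUMOURTABLE`, `PATIENTRECORDIDTUMOURTABLE`,
`TUMOURIDSOURCETABLE`) to match.  Non-key columns pass through
byte-identical.  Column names vary between registries and are configurable
in a plain-text file.

## Worked example

Generate a small synthetic centre (3 patients, 1–2 tumours each), then
convert it against a central database whose last unique ID is 500:

```sh
canregmerge generate --label demo --n-patients 3 --tumours 1-2 --sources 1 \
    --seed 5 --out centreA --schema-config registry.conf \
    --clock "2022-10-15T17:32:18"
canregmerge convert \
    --patient "centreA/Patient_2022-10-15 17_32_18.tsv" \
    --tumour  "centreA/Tumour_2022-10-15 17_32_18.tsv" \
    --source  "centreA/Source_2022-10-15 17_32_18.tsv" \
    --last-id 500 --out converted --schema-config registry.conf \
    --clock "2022-10-15T17:32:18"
```

where `registry.conf` sets 4-digit patient numbers
(`patient_width = 4`, other keys defaulted).  The convert command prints
`503` — the new last unique ID to record for the next merge — and the
tumour table shows the renumbering: input row
`000102 000101 0001 … C16.9 8000` (tumour 02 of patient 1) becomes
`050102 050101 0501 … C16.9 8000`: new patient number 501, original
suffixes and clinical fields untouched.  An audit map is written alongside
(`idmap_patient.tsv` etc.), e.g. `0001 → 0501`.

Merging many centres in one run threads the last unique ID automatically:

```sh
canregmerge merge --manifest manifest.tsv --last-id 0 --out merged
```

reads a TSV manifest (`label / patient / tumour / source` paths, in merge
order), writes converted files and ID maps per centre, and a merge report
whose collision count is *recomputed* from the merged tables (always 0 for
valid inputs).  `canregmerge validate` audits any state for duplicate keys,
dangling or disagreeing foreign keys and malformed IDs.

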