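"""Multi-centre merging and central-state validation."""

import pytest

from canregmerge import (
    CentralState,
    CountDistribution,
    GenSpec,
    IDScheme,
    RegistrySchema,
    Table,
    TableKind,
    count_pk_collisions,
    generate_centre,
    generate_scenario,
    merge_centres,
    validate_central,
)
from canregmerge.merge import CentralStateError
from conftest import make_dataset


def random_centres(schema, scheme, n_centres, seed):
    return [
        generate_centre(
            GenSpec(f"centre-{i}", 5 + (seed + i) % 20,
                    CountDistribution.uniform_range(0, 3),
                    CountDistribution.uniform_range(0, 3),
                    seed=seed * 100 + i),
            schema, scheme,
        )
        for i in range(n_centres)
    ]


class TestMergeCentres:
    def test_empty_centre_list_is_identity(self, schema):
        central = CentralState.empty(schema, last_unique_id=5)
        state, report, _ = merge_centres(central, [], schema, IDScheme())
        assert state.last_unique_id == 5
        assert report.total_records == 0
        assert report.collision_count == 0

    def test_identical_centres_get_disjoint_ids(self, schema, small_scheme):
        ds = lambda label: make_dataset(
            schema,
            patients=[("0001", "000101"), ("0002", "000201")],
            tumours=[("000101", "000101", "0001"), ("000201", "000201", "0002")],
            sources=[("00010101", "000101"), ("00020101", "000201")],
            label=label,
        )
        central = CentralState.empty(schema)
        state, report, _ = merge_centres(
            central, [ds("A"), ds("B")], schema, small_scheme
        )
        pks = list(state.patient.data[schema.patient_pk_col])
        assert pks == ["0001", "0002", "0003", "0004"]
        assert len(set(pks)) == 4
        assert report.collision_count == 0

    def test_last_id_monotone_and_ranges_recorded(self, schema):
        scheme = IDScheme()
        centres = random_centres(schema, scheme, 3, seed=5)
        central = CentralState.empty(schema, last_unique_id=100)
        state, report, _ = merge_centres(central, centres, schema, scheme)
        assert state.last_unique_id == 100 + report.total_patients
        expected_first = 101
        for entry in report.entries:
            assert entry.first_assigned_id == expected_first
            expected_first = entry.last_assigned_id + 1

    @pytest.mark.parametrize("n_centres", [2, 5, 10])
    def test_conservation_collisions_and_validity(self, schema, n_centres):
        scheme = IDScheme()
        centres = random_centres(schema, scheme, n_centres, seed=n_centres)
        central = CentralState.empty(schema)
        state, report, _ = merge_centres(central, centres, schema, scheme)
        assert report.total_patients == sum(c.patient.n_rows for c in centres)
        assert report.total_tumours == sum(c.tumour.n_rows for c in centres)
        assert report.total_sources == sum(c.source.n_rows for c in centres)
        assert report.collision_count == 0
        assert count_pk_collisions(state, schema) == 0
        assert validate_central(state, schema, scheme).is_clean

    def test_order_independence_of_totals_and_structure(self, schema):
        """Permuting the centre order changes IDs but not the link structure."""
        scheme = IDScheme()
        centres = random_centres(schema, scheme, 4, seed=9)
        central = CentralState.empty(schema)
        s1, r1, _ = merge_centres(central, centres, schema, scheme)
        s2, r2, _ = merge_centres(central, centres[::-1], schema, scheme)
        assert (r1.total_patients, r1.total_tumours, r1.total_sources) == (
            r2.total_patients, r2.total_tumours, r2.total_sources
        )

        def degree_profile(state):
            """Sorted (tumours-per-patient, sources-per-each-tumour) multiset."""
            tum = state.tumour.data
            src = state.source.data
            srcs_per_tumour = src[schema.source_tumour_fk_col].value_counts()
            profile = []
            for pk in state.patient.data[schema.patient_pk_col]:
                tumours = tum[tum[schema.tumour_patient_fk_col] == pk]
                profile.append(
                    tuple(sorted(
                        int(srcs_per_tumour.get(t, 0))
                        for t in tumours[schema.tumour_pk_col]
                    ))
                )
            return sorted(profile)

        assert degree_profile(s1) == degree_profile(s2)

    def test_invalid_central_state_rejected(self, schema, small_scheme):
        bad = CentralState(
            last_unique_id=10,
            patient=Table.from_rows(
                TableKind.PATIENT,
                [schema.patient_pk_col, schema.patient_record_id_col],
                [["0001", "000101"], ["0001", "000101"]],
            ),
            tumour=CentralState.empty(schema).tumour,
            source=CentralState.empty(schema).source,
        )
        with pytest.raises(CentralStateError, match="duplicate_pk"):
            merge_centres(bad, [], schema, small_scheme)

    def test_merge_into_nonempty_central(self, schema, small_scheme):
        seed_centre = make_dataset(
            schema,
            patients=[("0001", "000101")],
            tumours=[("000101", "000101", "0001")],
            sources=[("00010101", "000101")],
        )
        central0 = CentralState.empty(schema)
        central1, _, _ = merge_centres(
            central0, [seed_centre], schema, small_scheme
        )
        state, report, _ = merge_centres(
            central1, [seed_centre], schema, small_scheme
        )
        assert state.patient.n_rows == 2
        assert list(state.patient.data[schema.patient_pk_col]) == ["0001", "0002"]
        assert report.collision_count == 0


class TestValidateCentral:
    def _clean_state(self, schema, scheme):
        ds = generate_centre(GenSpec("c", 4, seed=2), schema, scheme)
        return CentralState(4, ds.patient, ds.tumour, ds.source)

    def test_clean_state_has_no_violations(self, schema, small_scheme):
        assert validate_central(
            self._clean_state(schema, small_scheme), schema, small_scheme
        ).is_clean

    def test_duplicate_pk_detected(self, schema, small_scheme):
        state = self._clean_state(schema, small_scheme)
        state.patient.data.loc[1, schema.patient_pk_col] = "0001"
        state.patient.data.loc[1, schema.patient_record_id_col] = "000101"
        report = validate_central(state, schema, small_scheme)
        assert any(v.rule == "duplicate_pk" for v in report.violations)

    def test_dangling_source_fk_detected(self, schema, small_scheme):
        state = self._clean_state(schema, small_scheme)
        state.source.data.loc[0, schema.source_tumour_fk_col] = "050199"
        state.source.data.loc[0, schema.source_pk_col] = "05019901"
        report = validate_central(state, schema, small_scheme)
        rules = [v.rule for v in report.violations]
        assert "dangling_fk" in rules

    def test_malformed_id_detected(self, schema, small_scheme):
        state = self._clean_state(schema, small_scheme)
        state.patient.data.loc[0, schema.patient_pk_col] = "XXXX"
        report = validate_central(state, schema, small_scheme)
        assert any(v.rule == "malformed_id" for v in report.violations)

    def test_fk_pair_inconsistency_detected(self, schema, small_scheme):
        state = self._clean_state(schema, small_scheme)
        state.tumour.data.loc[0, schema.tumour_patient_record_fk_col] = "000201"
        report = validate_central(state, schema, small_scheme)
        assert any(v.rule == "fk_pair_inconsistency" for v in report.violations)

    def test_regno_beyond_last_unique_id_detected(self, schema, small_scheme):
        state = self._clean_state(schema, small_scheme)
        state.last_unique_id = 2  # centre has patients 1..4
        report = validate_central(state, schema, small_scheme)
        assert not report.is_clean

    def test_violations_ordered_by_table_then_row(self, schema, small_scheme):
        state = self._clean_state(schema, small_scheme)
        state.source.data.loc[0, schema.source_tumour_fk_col] = "059901"
        state.source.data.loc[0, schema.source_pk_col] = "05990101"
        state.patient.data.loc[2, schema.patient_pk_col] = "BAD!"
        report = validate_central(state, schema, small_scheme)
        kinds = [v.table for v in report.violations]
        assert kinds == sorted(kinds, key=list(TableKind).index)


class TestScenarioMerge:
    def test_scenario_counts_equal_requested(self, schema):
        scheme = IDScheme()
        centres = generate_scenario([("A", 2), ("B", 3)], seed=0)
        assert [c.patient.n_rows for c in centres] == [2, 3]
        pks_a = set(centres[0].patient.data[schema.patient_pk_col])
        pks_b = set(centres[1].patient.data[schema.patient_pk_col])
        assert pks_a <= pks_b  # overlapping, maximally colliding
        state, report, _ = merge_centres(
            CentralState.empty(schema), centres, schema, scheme
        )
        assert report.total_patients == 5
        assert report.collision_count == 0
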