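import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ehrfusion.ehr_data import (
    CohortParseError,
    CohortValidationError,
    LabelSpace,
    PatientRecord,
    Visit,
    build_label_vector,
    extract_temporal_features,
    filter_min_visits,
    load_cohort,
    make_prediction_instances,
    write_cohort,
)


class TestSerialization:
    def test_empty_file_gives_empty_cohort(self, tmp_path):
        path = tmp_path / "empty.jsonl"
        path.write_text("")
        assert load_cohort(path) == []

    def test_round_trip_preserves_cohort(self, small_cohort, tmp_path):
        path = tmp_path / "cohort.jsonl"
        write_cohort(small_cohort, path)
        assert len(path.read_text().strip().splitlines()) == 2
        assert load_cohort(path) == small_cohort

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        path.write_text(
            '{"patient_id": "A", "visits": [{"admission_time": 0, "discharge_time": 1}]}\n'
            "not json\n"
        )
        with pytest.raises(CohortParseError, match="line 2"):
            load_cohort(path)

    def test_discharge_before_admission_rejected(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        path.write_text(
            '{"patient_id": "X", "visits": [{"admission_time": 10, "discharge_time": 5}]}\n'
        )
        with pytest.raises(CohortValidationError, match="X"):
            load_cohort(path)

    def test_visits_resorted_by_admission_time(self):
        rec = PatientRecord(
            "P",
            [Visit(admission_time=50.0, discharge_time=60.0),
             Visit(admission_time=0.0, discharge_time=10.0)],
        )
        assert [v.admission_time for v in rec.visits] == [0.0, 50.0]


class TestFilterMinVisits:
    def test_counts(self):
        cohort = [
            PatientRecord(f"P{i}", [Visit(admission_time=24.0 * t, discharge_time=24.0 * t + 1)
                                    for t in range(n)])
            for i, n in enumerate([1, 2, 3])
        ]
        assert len(filter_min_visits(cohort, 2)) == 2
        assert filter_min_visits(cohort, 1) == cohort
        assert filter_min_visits([], 2) == []


class TestTemporalFeatures:
    def test_hand_computed_durations_and_gaps(self, small_patient):
        tf = extract_temporal_features(small_patient, max_len=4)
        np.testing.assert_allclose(tf.matrix[:3, 0], [48.0, 24.0, 12.0])
        np.testing.assert_allclose(tf.matrix[:3, 1], [0.0, 52.0, 76.0])
        assert tf.mask.tolist() == [True, True, True, False]
        assert np.all(tf.matrix[3] == 0.0)

    def test_108_day_interval_is_2592_hours(self):
        patient = PatientRecord(
            "P",
            [Visit(admission_time=-24.0, discharge_time=0.0),
             Visit(admission_time=108 * 24.0, discharge_time=108 * 24.0 + 48.0)],
        )
        tf = extract_temporal_features(patient, max_len=2)
        assert tf.matrix[1, 1] == 2592.0

    def test_single_zero_duration_visit(self):
        patient = PatientRecord("P", [Visit(admission_time=5.0, discharge_time=5.0)])
        tf = extract_temporal_features(patient, max_len=1)
        np.testing.assert_array_equal(tf.matrix, [[0.0, 0.0]])
        assert tf.mask.tolist() == [True]

    def test_overlapping_visits_clamp_gap_to_zero(self):
        patient = PatientRecord(
            "P",
            [Visit(admission_time=0.0, discharge_time=100.0),
             Visit(admission_time=80.0, discharge_time=130.0)],
        )
        tf = extract_temporal_features(patient, max_len=2)
        assert tf.matrix[1, 1] == 0.0

    def test_truncation_keeps_most_recent_visits(self):
        visits = [Visit(admission_time=100.0 * t, discharge_time=100.0 * t + 10.0)
                  for t in range(5)]
        tf = extract_temporal_features(PatientRecord("P", visits), max_len=3)
        assert tf.mask.sum() == 3
        # rows are the last three visits; their gaps are 90 hours each
        np.testing.assert_allclose(tf.matrix[:, 1], [90.0, 90.0, 90.0])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        offset=st.floats(-1e5, 1e5),
        gaps=st.lists(st.floats(0.0, 500.0), min_size=1, max_size=6),
    )
    def test_translation_invariance(self, offset, gaps):
        t, visits = 0.0, []
        for g in gaps:
            t += g
            visits.append(Visit(admission_time=t, discharge_time=t + 24.0))
            t += 24.0
        base = extract_temporal_features(PatientRecord("P", visits))
        shifted = extract_temporal_features(
            PatientRecord(
                "P",
                [Visit(admission_time=v.admission_time + offset,
                       discharge_time=v.discharge_time + offset) for v in visits],
            )
        )
        np.testing.assert_allclose(base.matrix, shifted.matrix, atol=1e-6)

    def test_cumulative_sums_recompose_admission_times(self, small_patient):
        tf = extract_temporal_features(small_patient, max_len=8)
        n = int(tf.mask.sum())
        rel = [0.0]
        for t in range(1, n):
            rel.append(rel[-1] + tf.matrix[t - 1, 0] + tf.matrix[t, 1])
        expected = [v.admission_time - small_patient.visits[0].admission_time
                    for v in small_patient.visits]
        np.testing.assert_allclose(rel, expected)


class TestLabelsAndInstances:
    def test_label_vector_membership(self, label_space):
        visit = Visit(admission_time=0, discharge_time=1,
                      diagnoses={"DM", "ARRHY", "UNKNOWN"})
        np.testing.assert_array_equal(
            build_label_vector(visit, label_space), [0.0, 1.0, 0.0, 1.0]
        )
        empty = Visit(admission_time=0, discharge_time=1)
        assert build_label_vector(empty, label_space).sum() == 0
        full = Visit(admission_time=0, discharge_time=1, diagnoses=set(label_space.codes))
        assert build_label_vector(full, label_space).sum() == label_space.d

    def test_one_instance_per_patient(self, small_patient, label_space):
        instances = make_prediction_instances(small_patient, label_space)
        assert len(instances) == 1
        assert len(instances[0].history) == 2
        np.testing.assert_array_equal(
            instances[0].target,
            build_label_vector(small_patient.visits[-1], label_space),
        )

    def test_expanding_window_mode(self, small_patient, label_space):
        instances = make_prediction_instances(small_patient, label_space, expanding_window=True)
        assert [len(i.history) for i in instances] == [1, 2]

    def test_single_visit_patient_rejected(self, label_space):
        p = PatientRecord("P", [Visit(admission_time=0, discharge_time=1)])
        with pytest.raises(ValueError, match="filter"):
            make_prediction_instances(p, label_space)

    def test_label_space_rejects_duplicates(self):
        with pytest.raises(ValueError):
            LabelSpace(("A", "A"))
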