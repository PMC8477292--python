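import numpy as np
import pytest

from hvec.data_model import MedicalCode
from hvec.featurization import (
    CodeEmbeddingTable,
    FeatureScaler,
    LAYOUT,
    RecordVector,
    SPAN_SLICES,
    TOTAL_DIM,
    GROUP_SLICES,
    build_record_vector,
    embed_category,
    featurize_cohort_raw,
    history_features,
    make_embedding_table,
    make_table_for_cohort,
    raw_record_vector,
)

from conftest import make_person, make_record


@pytest.fixture()
def table():
    vocab = [("diagnosis", f"D{i:04d}") for i in range(20)] + \
            [("procedure", "99.60"), ("procedure", "99.63"),
             ("medication", "M0001"), ("test", "T0001"), ("other", "O0001")]
    return make_embedding_table(vocab, seed=3)


class TestLayout:
    def test_spans_sum_to_707(self):
        assert TOTAL_DIM == 707
        assert sum(length for _, length in LAYOUT) == 707

    def test_group_slices_partition_the_vector(self):
        # code spans (640) + context (48) + statistics/history (19)
        sizes = {k: s.stop - s.start for k, s in GROUP_SLICES.items()}
        assert sizes == {"codes": 640, "context": 48, "stats": 19}
        assert sizes["codes"] + sizes["context"] + sizes["stats"] == 707


class TestEmbedding:
    def test_empty_category_gives_zero_vector(self, table):
        rec = make_record(codes=[MedicalCode("medication", "M0001")])
        assert np.all(embed_category(rec, "diagnosis", table) == 0)

    def test_sum_is_order_independent(self, table):
        a = MedicalCode("diagnosis", "D0001")
        b = MedicalCode("diagnosis", "D0002")
        r1 = make_record(codes=[a, b])
        r2 = make_record(codes=[b, a])
        v1 = embed_category(r1, "diagnosis", table)
        v2 = embed_category(r2, "diagnosis", table)
        np.testing.assert_array_equal(v1, v2)
        np.testing.assert_allclose(
            v1, table.lookup("diagnosis", "D0001") + table.lookup("diagnosis", "D0002"))

    def test_duplicate_code_counts_twice(self, table):
        a = MedicalCode("diagnosis", "D0003")
        rec = make_record(codes=[a, a])
        np.testing.assert_allclose(
            embed_category(rec, "diagnosis", table),
            2.0 * table.lookup("diagnosis", "D0003"))

    def test_additive_over_disjoint_multisets(self, table):
        a = MedicalCode("diagnosis", "D0001")
        b = MedicalCode("diagnosis", "D0005")
        merged = make_record(codes=[a, b])
        np.testing.assert_allclose(
            embed_category(merged, "diagnosis", table),
            embed_category(make_record(codes=[a]), "diagnosis", table)
            + embed_category(make_record(codes=[b]), "diagnosis", table))

    def test_unknown_code_raises_naming_the_code(self, table):
        rec = make_record(codes=[MedicalCode("diagnosis", "D9999")])
        with pytest.raises(KeyError, match="D9999"):
            embed_category(rec, "diagnosis", table)

    def test_unknown_vector_fallback(self):
        unk = np.zeros(128)
        t = make_embedding_table([], seed=0, unknown_vector=unk)
        rec = make_record(codes=[MedicalCode("diagnosis", "D9999")])
        np.testing.assert_array_equal(embed_category(rec, "diagnosis", t), unk)


class TestEmbeddingTable:
    def test_determinism_across_constructions(self):
        vocab = [("diagnosis", f"D{i}") for i in range(50)]
        t1 = make_embedding_table(vocab, seed=9)
        t2 = make_embedding_table(vocab, seed=9)
        for key in t1.vectors:
            np.testing.assert_array_equal(t1.vectors[key], t2.vectors[key])

    def test_different_seed_changes_vectors(self):
        t1 = make_embedding_table([("diagnosis", "D1")], seed=1)
        t2 = make_embedding_table([("diagnosis", "D1")], seed=2)
        assert not np.allclose(t1.vectors[("diagnosis", "D1")],
                               t2.vectors[("diagnosis", "D1")])

    def test_norms_concentrate_near_sqrt_dimension(self):
        # chi-distribution concentration for unit-variance entries
        vocab = [("diagnosis", f"D{i}") for i in range(500)]
        t = make_embedding_table(vocab, dimension=128, seed=5)
        norms2 = np.array([v @ v for v in t.vectors.values()]) / 128.0
        assert abs(norms2.mean() - 1.0) < 0.02
        assert np.all((norms2 > 0.6) & (norms2 < 1.5))

    def test_distinct_codes_get_distinct_vectors(self):
        vocab = [("diagnosis", f"D{i}") for i in range(1000)]
        t = make_embedding_table(vocab, seed=0)
        mat = np.stack(list(t.vectors.values()))
        assert np.unique(mat[:, 0]).size == 1000


class TestHistory:
    def test_first_record_has_empty_history(self):
        rec = make_record(date=100)
        person = make_person(records=[rec])
        np.testing.assert_array_equal(history_features(person, rec), np.zeros(8))

    def test_recent_admission_in_all_windows(self):
        prior = make_record(record_id="a", date=50, claim_type="inpatient",
                            hospital_stay=7)
        cur = make_record(record_id="b", date=100)
        person = make_person(records=[prior, cur])
        np.testing.assert_array_equal(
            history_features(person, cur), [7, 7, 7, 7, 1, 1, 1, 1])

    def test_old_admission_only_in_widest_window(self):
        prior = make_record(record_id="a", date=0, claim_type="inpatient",
                            hospital_stay=3)
        cur = make_record(record_id="b", date=400)
        person = make_person(records=[prior, cur])
        np.testing.assert_array_equal(
            history_features(person, cur), [0, 0, 0, 3, 0, 0, 0, 1])

    def test_matches_brute_force_on_synthetic_person(self, small_cohort):
        windows = (90, 180, 365, 730)
        for person in small_cohort.persons[:40]:
            for rec in person.records:
                got = history_features(person, rec)
                exp = np.zeros(8)
                for prior in person.records:
                    gap = rec.date - prior.date
                    if prior.claim_type == "inpatient" and gap >= 1:
                        for k, w in enumerate(windows):
                            if gap <= w:
                                exp[k] += prior.hospital_stay
                                exp[4 + k] += 1
                np.testing.assert_array_equal(got, exp)


class TestRecordVector:
    def _fitted(self, cohort, table):
        rows = np.concatenate(list(featurize_cohort_raw(cohort, table).values()))
        return FeatureScaler().fit(rows)

    def test_vector_length_and_one_hot_spans(self, small_cohort):
        table = make_table_for_cohort(small_cohort, seed=0)
        scaler = self._fitted(small_cohort, table)
        person = small_cohort.persons[0]
        rv = build_record_vector(person, person.records[0], table, scaler)
        assert rv.values.shape == (707,)
        for span in ("claim_type", "gender", "care_site_type",
                     "care_site_specialization", "care_site_rank"):
            assert rv.span(span).sum() == pytest.approx(1.0)

    def test_gender_changes_only_gender_span(self, small_cohort):
        table = make_table_for_cohort(small_cohort, seed=0)
        scaler = self._fitted(small_cohort, table)
        person = small_cohort.persons[0]
        rec = person.records[0]
        v1 = build_record_vector(person, rec, table, scaler).values
        flipped = make_person(person_id=person.person_id,
                              gender="male" if person.gender == "female" else "female",
                              birth_year=person.birth_year,
                              records=list(person.records))
        v2 = build_record_vector(flipped, rec, table, scaler).values
        diff = np.nonzero(v1 != v2)[0]
        g = SPAN_SLICES["gender"]
        assert set(diff) <= set(range(g.start, g.stop))
        assert len(diff) > 0

    def test_permuted_codes_give_identical_vector(self, small_cohort):
        table = make_table_for_cohort(small_cohort, seed=0)
        scaler = self._fitted(small_cohort, table)
        person = next(p for p in small_cohort.persons
                      if len(p.records[0].codes) >= 2)
        rec = person.records[0]
        v1 = build_record_vector(person, rec, table, scaler).values
        rec.codes = list(reversed(rec.codes))
        v2 = build_record_vector(person, rec, table, scaler).values
        np.testing.assert_array_equal(v1, v2)

    def test_care_site_out_of_range_rejected(self, small_cohort):
        table = make_table_for_cohort(small_cohort, seed=0)
        person = small_cohort.persons[0]
        rec = make_record(care_site_type=25)
        with pytest.raises(ValueError, match="care_site_type"):
            raw_record_vector(person, rec, table)

    def test_record_vector_validates_length(self):
        with pytest.raises(ValueError):
            RecordVector(np.zeros(700))


class TestScaler:
    def test_frozen_after_fit(self):
        scaler = FeatureScaler().fit(np.random.default_rng(0).normal(size=(10, 707)) ** 2)
        with pytest.raises(RuntimeError):
            scaler.fit(np.zeros((5, 707)))

    def test_transform_before_fit_rejected(self):
        with pytest.raises(RuntimeError):
            FeatureScaler().transform(np.zeros((2, 707)))

    def test_transform_never_updates_statistics(self):
        rng = np.random.default_rng(1)
        scaler = FeatureScaler().fit(np.abs(rng.normal(size=(50, 707))))
        mean0, std0 = scaler.mean_.copy(), scaler.std_.copy()
        scaler.transform(np.abs(rng.normal(size=(30, 707))))
        np.testing.assert_array_equal(scaler.mean_, mean0)
        np.testing.assert_array_equal(scaler.std_, std0)

    def test_code_spans_pass_through_unscaled(self):
        rng = np.random.default_rng(2)
        raw = np.abs(rng.normal(size=(20, 707)))
        scaler = FeatureScaler().fit(raw)
        out = scaler.transform(raw)
        np.testing.assert_array_equal(out[:, :640], raw[:, :640])
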