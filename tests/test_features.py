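"""Confounder representations: vocabulary, one-hot encoding, embedding average."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ehrcausal import (
    CohortPair,
    EmbeddingTable,
    build_design_matrices,
    build_vocabulary,
    embed_patient,
    one_hot_encode,
)


@pytest.fixture
def toy_universe():
    persons = pd.DataFrame(
        {
            "person_id": [1, 2, 3],
            "age": [25, 62, 30],
            "gender": ["F", "M", "F"],
            "race": ["white", "black", "white"],
            "ethnicity": ["not_hispanic"] * 3,
            "zip3": ["021", "110", "021"],
            "history_days": [400, 400, 400],
        }
    )
    events = pd.DataFrame(
        {
            "person_id": [1, 1, 1, 2],
            "code": ["X", "X", "Y", "Z"],
            "days_before_index": [10, 20, 30, 40],
        }
    )
    return persons, events


class TestVocabulary:
    def test_key_count_on_toy_universe(self, toy_universe):
        persons, events = toy_universe
        vocab = build_vocabulary(events, persons)
        # 3 codes + 2 age bins (20s, 60s, 30s -> 3 bins) + 2 genders + 2 races
        # + 1 ethnicity + 2 zips
        assert len(vocab) == 3 + 3 + 2 + 2 + 1 + 2

    def test_empty_event_table_gives_demographics_only(self, toy_universe):
        persons, _ = toy_universe
        vocab = build_vocabulary(pd.DataFrame(columns=["person_id", "code"]), persons)
        assert vocab.code_keys == []
        assert len(vocab.demographic_keys) == len(vocab)

    def test_synthetic_vocabulary_covers_all_codes(self, small_pop, small_cohort):
        vocab = small_cohort["vocab"]
        assert len(vocab.code_keys) == small_pop["events"]["code"].nunique()
        assert len(vocab) > len(vocab.code_keys)

    def test_drop_returns_vocabulary_without_keys(self, small_cohort):
        vocab = small_cohort["vocab"]
        victim = vocab.code_keys[0]
        smaller = vocab.drop([victim])
        assert victim not in smaller
        assert len(smaller) == len(vocab) - 1


class TestOneHot:
    def test_multiplicity_collapses_to_presence(self, toy_universe):
        persons, events = toy_universe
        vocab = build_vocabulary(events, persons)
        row = persons.iloc[0]
        v = one_hot_encode(row, ["X", "X", "Y"], vocab).toarray().ravel()
        assert v[vocab.index["X"]] == 1
        assert v[vocab.index["Y"]] == 1
        assert set(np.unique(v)) <= {0.0, 1.0}
        # 2 distinct codes + age bin + gender + race + ethnicity + zip
        assert v.sum() == 2 + 5

    def test_person_without_codes_has_demographics_only(self, toy_universe):
        persons, events = toy_universe
        vocab = build_vocabulary(events, persons)
        v = one_hot_encode(persons.iloc[2], [], vocab).toarray().ravel()
        assert v.sum() == 5
        assert all(v[vocab.index[k]] == 0 for k in vocab.code_keys)

    def test_unseen_code_ignored_with_warning(self, toy_universe, caplog):
        persons, events = toy_universe
        vocab = build_vocabulary(events, persons)
        with caplog.at_level("WARNING"):
            v = one_hot_encode(persons.iloc[0], ["NOVEL"], vocab).toarray().ravel()
        assert "NOVEL" in caplog.text
        assert v.sum() == 5


class TestEmbedPatient:
    def test_single_code_returns_its_vector_exactly(self):
        t = EmbeddingTable(codes=["c"], vectors=np.array([[1.5, -2.0, 0.25]]))
        np.testing.assert_array_equal(embed_patient(["c"], t), t["c"])

    def test_two_unit_vectors_average_to_half(self):
        t = EmbeddingTable(codes=["a", "b"], vectors=np.array([[1.0, 0.0], [0.0, 1.0]]))
        np.testing.assert_allclose(embed_patient(["a", "b"], t), [0.5, 0.5])

    def test_permutation_invariance_and_duplicate_collapse(self):
        rng = np.random.default_rng(0)
        t = EmbeddingTable(codes=list("abcd"), vectors=rng.normal(size=(4, 6)))
        v1 = embed_patient(["a", "b", "c"], t)
        v2 = embed_patient(["c", "a", "b", "a", "a"], t)
        np.testing.assert_allclose(v1, v2)

    @settings(max_examples=30, deadline=None)
    @given(k=st.floats(-5, 5, allow_nan=False), n=st.integers(1, 4))
    def test_scaling_all_vectors_scales_the_average(self, k, n):
        rng = np.random.default_rng(42)
        vecs = rng.normal(size=(4, 3))
        codes = list("abcd")[:n]
        t1 = EmbeddingTable(codes=list("abcd"), vectors=vecs)
        t2 = EmbeddingTable(codes=list("abcd"), vectors=k * vecs)
        np.testing.assert_allclose(
            embed_patient(codes, t2), k * embed_patient(codes, t1), atol=1e-12
        )

    def test_identical_vectors_give_that_vector(self):
        v = np.array([0.3, -0.7])
        t = EmbeddingTable(codes=["a", "b", "c"], vectors=np.tile(v, (3, 1)))
        np.testing.assert_allclose(embed_patient(["a", "b", "c"], t), v)

    def test_unrepresentable_patient_raises(self):
        t = EmbeddingTable(codes=["a"], vectors=np.array([[1.0]]))
        with pytest.raises(ValueError, match="representable"):
            embed_patient(["zzz"], t)


class TestDesignMatrices:
    def test_one_hot_shape_and_label_sum(self, toy_universe):
        persons, events = toy_universe
        vocab = build_vocabulary(events, persons)
        pair = CohortPair("toy", frozenset({1}), frozenset({2, 3}))
        X, labels, ids = build_design_matrices(pair, "one_hot", persons, events, vocab)
        assert X.shape == (3, len(vocab))
        assert labels.sum() == 1
        assert list(ids) == [1, 2, 3]

    def test_one_hot_batch_matches_per_person_encoding(self, toy_universe):
        persons, events = toy_universe
        vocab = build_vocabulary(events, persons)
        pair = CohortPair("toy", frozenset({1}), frozenset({2, 3}))
        X, labels, ids = build_design_matrices(pair, "one_hot", persons, events, vocab)
        for i, pid in enumerate(ids):
            codes = events.loc[events["person_id"] == pid, "code"].tolist()
            row = persons.set_index("person_id").loc[pid]
            expected = one_hot_encode(row, codes, vocab).toarray().ravel()
            np.testing.assert_array_equal(np.asarray(X[i].todense()).ravel(), expected)

    def test_embedding_mode_column_count(self, toy_universe):
        persons, events = toy_universe
        vocab = build_vocabulary(events, persons)
        rng = np.random.default_rng(1)
        table = EmbeddingTable(codes=["X", "Y", "Z"], vectors=rng.normal(size=(3, 128)))
        pair = CohortPair("toy", frozenset({1}), frozenset({2}))
        X, labels, ids = build_design_matrices(
            pair, "embedding", persons, events, vocab, table=table
        )
        # 128 embedding dims + 7 demographic columns (age + 2 genders + 2
        # races + 1 ethnicity + 2 zips minus the levels only person 3 carries)
        n_demo_levels = len([k for k in vocab.demographic_keys if not k.startswith("age:")])
        assert X.shape[1] == 128 + 1 + n_demo_levels

    def test_embedding_rows_match_embed_patient_average(self, toy_universe):
        persons, events = toy_universe
        vocab = build_vocabulary(events, persons)
        rng = np.random.default_rng(2)
        table = EmbeddingTable(codes=["X", "Y", "Z"], vectors=rng.normal(size=(3, 4)))
        pair = CohortPair("toy", frozenset({1}), frozenset({2}))
        X, labels, ids = build_design_matrices(
            pair, "embedding", persons, events, vocab, table=table
        )
        for i, pid in enumerate(ids):
            codes = events.loc[events["person_id"] == pid, "code"].tolist()
            np.testing.assert_allclose(X[i, :4], embed_patient(codes, table))

    def test_unembeddable_patients_are_dropped_and_counted(self, toy_universe, caplog):
        persons, events = toy_universe
        vocab = build_vocabulary(events, persons)
        table = EmbeddingTable(codes=["X", "Y"], vectors=np.eye(2))
        pair = CohortPair("toy", frozenset({1}), frozenset({2, 3}))
        with caplog.at_level("WARNING"):
            X, labels, ids = build_design_matrices(
                pair, "embedding", persons, events, vocab, table=table
            )
        # persons 2 (only code Z, unembeddable) and 3 (no codes) are dropped
        assert list(ids) == [1]
        assert "unembeddable" in caplog.text

    def test_missing_person_rejected(self, toy_universe):
        persons, events = toy_universe
        vocab = build_vocabulary(events, persons)
        pair = CohortPair("toy", frozenset({1}), frozenset({99}))
        with pytest.raises(ValueError, match="missing from persons"):
            build_design_matrices(pair, "one_hot", persons, events, vocab)

    def test_matrix_cache_roundtrip(self, toy_universe, tmp_path):
        from ehrcausal.features import load_matrix, save_matrix

        persons, events = toy_universe
        vocab = build_vocabulary(events, persons)
        pair = CohortPair("toy", frozenset({1}), frozenset({2, 3}))
        X, _, _ = build_design_matrices(pair, "one_hot", persons, events, vocab)
        save_matrix(X, tmp_path / "x.triplet")
        X2 = load_matrix(tmp_path / "x.triplet")
        assert (X != X2).nnz == 0
        dense = np.arange(6.0).reshape(2, 3)
        save_matrix(dense, tmp_path / "d.csv")
        np.testing.assert_allclose(load_matrix(tmp_path / "d.csv"), dense)

    def test_rows_reproducible(self, small_pop, small_cohort):
        args = (
            small_cohort["pair"], "one_hot", small_pop["persons"],
            small_pop["events"], small_cohort["vocab"],
        )
        X1, l1, i1 = build_design_matrices(*args)
        X2, l2, i2 = build_design_matrices(*args)
        assert (X1 != X2).nnz == 0
        np.testing.assert_array_equal(l1, l2)
        np.testing.assert_array_equal(i1, i2)
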