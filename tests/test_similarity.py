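import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gsompul.errors import (
    DegenerateInputError,
    DrugMissingError,
    DuplicateDrugError,
    LengthMismatchError,
    NonBinaryValueError,
    SelfPairError,
)
from gsompul.similarity import (
    DrugFeatureMatrix,
    apply_projection,
    build_pair_feature_table,
    build_sfr1,
    build_sfr2,
    enumerate_pairs,
    fit_variance_projection,
    individual_similarity,
    jaccard_index,
    pair_key,
    project_table,
)


class TestPairEnumeration:
    @pytest.mark.parametrize(
        "n, expected",
        [(548, 149878), (1, 0), (5, 10), (2, 1)],
    )
    def test_pair_count_is_n_choose_2(self, n, expected):
        ids = [f"d{i:03d}" for i in range(n)]
        assert len(enumerate_pairs(ids)) == expected

    def test_matches_brute_force_double_loop(self):
        ids = [f"x{i}" for i in range(7)]
        brute = {tuple(sorted((a, b))) for a in ids for b in ids if a != b}
        assert set(enumerate_pairs(ids).pairs) == brute

    def test_pairs_canonical_and_unique(self):
        pairs = enumerate_pairs(["b", "a", "c"]).pairs
        assert all(a < b for a, b in pairs)
        assert len(set(pairs)) == len(pairs)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(DuplicateDrugError):
            enumerate_pairs(["a", "b", "a"])

    def test_self_pair_key_rejected(self):
        with pytest.raises(SelfPairError):
            pair_key("a", "a")

    def test_pair_key_is_order_invariant(self):
        assert pair_key("b", "a") == pair_key("a", "b") == ("a", "b")


class TestJaccard:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((1, 0, 1), (1, 0, 1), 1.0),
            ((1, 0, 0), (0, 1, 0), 0.0),
            ((1, 1, 0), (1, 0, 1), 1 / 3),
            ((0, 0, 0), (0, 0, 0), 0.0),  # empty union convention
        ],
    )
    def test_known_values(self, a, b, expected):
        assert jaccard_index(np.array(a), np.array(b)) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(LengthMismatchError):
            jaccard_index(np.array([1, 0]), np.array([1, 0, 1]))

    def test_non_binary_rejected(self):
        with pytest.raises(NonBinaryValueError):
            jaccard_index(np.array([2, 0]), np.array([1, 0]))

    @given(
        st.lists(st.booleans(), min_size=1, max_size=30),
        st.data(),
    )
    @settings(deadline=None, max_examples=100)
    def test_symmetric_bounded_and_identity(self, a_bits, data):
        b_bits = data.draw(
            st.lists(st.booleans(), min_size=len(a_bits), max_size=len(a_bits))
        )
        a = np.array(a_bits, dtype=int)
        b = np.array(b_bits, dtype=int)
        j_ab = jaccard_index(a, b)
        assert j_ab == jaccard_index(b, a)
        assert 0.0 <= j_ab <= 1.0
        # equals 1 iff supports identical and non-empty
        assert (j_ab == 1.0) == (a.any() and (a == b).all())


class TestIndividualSimilarity:
    def test_elementwise_average(self):
        out = individual_similarity(np.array([1, 0, 1]), np.array([1, 1, 0]))
        assert np.allclose(out, [1, 0.5, 0.5])

    def test_average_of_equal_vectors_is_identity(self):
        a = np.array([0, 1, 1, 0])
        assert np.array_equal(individual_similarity(a, a), a.astype(float))

    def test_all_zero_inputs(self):
        z = np.zeros(4)
        assert np.array_equal(individual_similarity(z, z), z)

    @given(st.integers(2, 20), st.integers(0, 2**32 - 1))
    @settings(deadline=None, max_examples=50)
    def test_symmetric_and_bounded_by_elementwise_max(self, n, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 2, n)
        b = rng.integers(0, 2, n)
        s = individual_similarity(a, b)
        assert np.array_equal(s, individual_similarity(b, a))
        assert (s <= np.maximum(a, b)).all()
        assert set(np.unique(s)) <= {0.0, 0.5, 1.0}


class TestSFRBuilders:
    def test_sfr1_one_value_per_source(self, two_source_matrices):
        v = build_sfr1(("A", "B"), two_source_matrices)
        assert v.shape == (2,)
        # oracle: per-source jaccard of the hand-set rows
        assert v[0] == pytest.approx(1 / 3)  # {f1,f2} vs {f1,f3}
        assert v[1] == pytest.approx(1.0)  # {g1} vs {g1}

    def test_sfr1_identical_rows_give_all_ones(self):
        m = DrugFeatureMatrix(
            "s", ("X", "Y"), ("f1", "f2"), np.array([[1, 0], [1, 0]])
        )
        assert np.allclose(build_sfr1(("X", "Y"), [m, m]), 1.0)

    def test_sfr2_concatenates_sources(self, two_source_matrices):
        v = build_sfr2(("A", "B"), two_source_matrices)
        assert v.shape == (5,)
        expected = np.concatenate(
            [
                individual_similarity(
                    two_source_matrices[0].row("A"), two_source_matrices[0].row("B")
                ),
                individual_similarity(
                    two_source_matrices[1].row("A"), two_source_matrices[1].row("B")
                ),
            ]
        )
        assert np.array_equal(v, expected)

    def test_sfr2_length_is_sum_of_dims(self):
        dims = (881, 719, 775, 1385)
        mats = [
            DrugFeatureMatrix(
                f"s{i}", ("A", "B"), tuple(f"s{i}f{j}" for j in range(d)),
                np.zeros((2, d), dtype=np.uint8),
            )
            for i, d in enumerate(dims)
        ]
        assert build_sfr2(("A", "B"), mats).shape == (3760,)

    def test_missing_drug_names_drug_and_source(self, two_source_matrices):
        with pytest.raises(DrugMissingError, match="'Z'.*'chem'"):
            build_sfr1(("A", "Z"), two_source_matrices)

    def test_batch_table_matches_per_pair_builders(self, two_source_matrices):
        t1 = build_pair_feature_table(two_source_matrices, "SFR1")
        t2 = build_pair_feature_table(two_source_matrices, "SFR2")
        for pair in t1.pairs:
            assert np.allclose(t1.vector_for(pair), build_sfr1(pair, two_source_matrices))
            assert np.allclose(t2.vector_for(pair), build_sfr2(pair, two_source_matrices))
        assert set(np.unique(t2.vectors)) <= {0.0, 0.5, 1.0}

    @given(st.integers(0, 2**32 - 1))
    @settings(deadline=None, max_examples=30)
    def test_same_jaccard_different_sfr2(self, seed):
        """Pairs with equal intersection/union counts share SFR1 but SFR2
        still separates them when the overlapping features differ."""
        rng = np.random.default_rng(seed)
        n = 8
        # pair 1: drugs share feature 0, each has one private feature
        a1 = np.zeros(n, int); b1 = np.zeros(n, int)
        a1[[0, 1]] = 1; b1[[0, 2]] = 1
        # pair 2: same counts but the shared feature sits elsewhere
        a2 = np.zeros(n, int); b2 = np.zeros(n, int)
        shared = int(rng.integers(3, n))
        priv = [i for i in range(n) if i != shared]
        a2[[shared, priv[0]]] = 1; b2[[shared, priv[1]]] = 1
        assert jaccard_index(a1, b1) == jaccard_index(a2, b2)
        assert not np.array_equal(
            individual_similarity(a1, b1), individual_similarity(a2, b2)
        )


class TestVarianceProjection:
    def test_full_rank_fraction_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 4))
        proj = fit_variance_projection(X, 1.0)
        assert proj.n_components == 4  # min(rows - 1, cols) here = 4... rank check below
        back = apply_projection(proj, X) @ proj.component_matrix + proj.mean_vector
        assert np.allclose(back, X, atol=1e-8)

    def test_planar_data_needs_two_components(self):
        rng = np.random.default_rng(1)
        basis = np.linalg.qr(rng.normal(size=(5, 2)))[0].T  # 2 orthonormal 5-vectors
        scores = rng.normal(size=(40, 2)) * [3.0, 1.5]
        X = scores @ basis + 0.7
        proj = fit_variance_projection(X, 0.9)
        assert proj.n_components == 2
        # eigen-decomposition oracle: covariance has exactly two non-null directions
        w = np.linalg.eigvalsh(np.cov(X.T))
        assert (w > 1e-10).sum() == 2

    def test_projecting_mean_gives_zero(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 3))
        proj = fit_variance_projection(X, 0.9)
        assert np.allclose(apply_projection(proj, proj.mean_vector), 0.0)

    def test_scores_match_manual_centering_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 6))
        proj = fit_variance_projection(X, 0.8)
        scores = apply_projection(proj, X)
        manual = (X - X.mean(axis=0)) @ proj.component_matrix.T
        assert np.allclose(scores, manual, atol=1e-10)

    def test_constant_table_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_variance_projection(np.ones((5, 3)), 0.9)

    def test_dimension_mismatch_rejected(self):
        proj = fit_variance_projection(np.random.default_rng(4).normal(size=(8, 3)), 0.9)
        with pytest.raises(LengthMismatchError):
            apply_projection(proj, np.zeros((2, 5)))

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 4))
        p1 = fit_variance_projection(X, 0.95)
        p2 = fit_variance_projection(X.copy(), 0.95)
        assert np.array_equal(p1.component_matrix, p2.component_matrix)
        for row in p1.component_matrix:
            assert row[np.argmax(np.abs(row))] > 0


class TestDrugFeatureMatrixValidation:
    def test_non_binary_cell_named(self):
        with pytest.raises(NonBinaryValueError, match="'B'.*'f2'"):
            DrugFeatureMatrix("s", ("A", "B"), ("f1", "f2"), np.array([[0, 1], [1, 2]]))

    def test_duplicate_drugs_rejected(self):
        with pytest.raises(DuplicateDrugError):
            DrugFeatureMatrix("s", ("A", "A"), ("f1",), np.array([[0], [1]]))
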