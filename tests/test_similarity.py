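import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from bucketeval import (
    FitnessMatrix,
    all_pairs_similarity,
    assign_buckets,
    build_bucket_scheme,
    build_scoring_matrix,
    normalize_similarity,
    pair_similarity,
    split_signed_matrix,
)
from bucketeval.core import BucketScheme, SimilarityMatrix
from bucketeval.errors import (
    EmptyInputError,
    IncompatibleSchemeError,
    NormalizationError,
    ParameterError,
)


def scheme_from_sizes(sizes):
    return BucketScheme(
        num_genes=sum(sizes),
        sizes=tuple(sizes),
        initial_fraction=0.1,
        growth_factor=2.0,
        max_buckets=max(len(sizes), 2),
    )


class TestPairSimilarity:
    def test_self_comparison_is_per_bucket_maximum(self):
        scheme = scheme_from_sizes([1, 2, 4])
        sm = build_scoring_matrix(3)
        profile = pd.Series(
            {"g1": 9.0, "g2": 5.0, "g3": 4.0, "g4": 1.0, "g5": 0.0, "g6": -1.0, "g7": -2.0}
        )
        a = assign_buckets(profile, scheme)
        expected = sum(
            size * sm.score(b, b) for b, size in enumerate(scheme.sizes, start=1)
        )
        assert pair_similarity(a, a, sm) == pytest.approx(expected)

    def test_two_bucket_brute_force(self):
        # n=2 matrix: S(1,1)=2, S(2,2)=1, S(1,2)=0.5; a={g1:1,g2:2,g3:2},
        # b={g2:1,g1:2,g3:2} -> 0.5 + 0.5 + 1 = 2.0
        scheme = scheme_from_sizes([1, 2])
        sm = build_scoring_matrix(2)
        assert sm.score(1, 1) == 2.0
        assert sm.score(2, 2) == 1.0
        assert sm.score(1, 2) == 0.5
        a = assign_buckets(pd.Series({"g1": 9.0, "g2": 5.0, "g3": 4.0}), scheme)
        b = assign_buckets(pd.Series({"g1": 5.0, "g2": 9.0, "g3": 4.0}), scheme)
        assert pair_similarity(a, b, sm) == pytest.approx(2.0)

    def test_symmetry(self, rng):
        scheme = build_bucket_scheme(50, 0.05, 2, 5)
        sm = build_scoring_matrix(scheme.n_buckets)
        genes = [f"g{i}" for i in range(50)]
        a = assign_buckets(pd.Series(rng.normal(size=50), index=genes), scheme)
        b = assign_buckets(pd.Series(rng.normal(size=50), index=genes), scheme)
        assert pair_similarity(a, b, sm) == pair_similarity(b, a, sm)

    def test_shared_top_bucket_scores_higher(self):
        # Exp1 and Exp3 share top-bucket genes, Exp2 does not
        scheme = scheme_from_sizes([1, 2, 4])
        sm = build_scoring_matrix(3)
        exp1 = pd.Series({"g1": 22.0, "g2": 9.0, "g3": 8.0, "g4": 1.0,
                          "g5": 0.5, "g6": 0.2, "g7": -1.0})
        exp2 = pd.Series({"g1": 0.1, "g2": 2.0, "g3": 1.0, "g4": 31.0,
                          "g5": 10.0, "g6": 9.0, "g7": -0.5})
        exp3 = pd.Series({"g1": 28.0, "g2": 10.0, "g3": 7.0, "g4": 0.8,
                          "g5": 0.3, "g6": 0.1, "g7": -2.0})
        a1, a2, a3 = (assign_buckets(p, scheme) for p in (exp1, exp2, exp3))
        assert pair_similarity(a1, a3, sm) > pair_similarity(a2, a3, sm)

    def test_scheme_mismatch_rejected(self):
        sm = build_scoring_matrix(2)
        a = assign_buckets(pd.Series({"g1": 1.0, "g2": 0.0, "g3": -1.0}),
                           scheme_from_sizes([1, 2]))
        b = assign_buckets(pd.Series({"g1": 1.0, "g2": 0.0, "g3": -1.0}),
                           scheme_from_sizes([1, 1, 1]))
        with pytest.raises(IncompatibleSchemeError):
            pair_similarity(a, b, sm)

    def test_gene_set_mismatch_rejected(self):
        sm = build_scoring_matrix(2)
        scheme = scheme_from_sizes([1, 2])
        a = assign_buckets(pd.Series({"g1": 1.0, "g2": 0.0, "g3": -1.0}), scheme)
        b = assign_buckets(pd.Series({"g1": 1.0, "g2": 0.0, "g4": -1.0}), scheme)
        with pytest.raises(IncompatibleSchemeError):
            pair_similarity(a, b, sm)

    def test_self_maximality_randomized(self, rng):
        # dominance: S(i,j) <= S(i,i) implies self-similarity is maximal
        for sizes in ([1, 2, 4], [2, 2, 5, 8], [1, 1, 1, 1, 1]):
            scheme = scheme_from_sizes(sizes)
            sm = build_scoring_matrix(scheme.n_buckets)
            genes = [f"g{i}" for i in range(scheme.num_genes)]
            for _ in range(20):
                a = assign_buckets(
                    pd.Series(rng.normal(size=len(genes)), index=genes), scheme
                )
                b = assign_buckets(
                    pd.Series(rng.normal(size=len(genes)), index=genes), scheme
                )
                assert pair_similarity(a, a, sm) >= pair_similarity(a, b, sm)


class TestAllPairs:
    def test_identical_columns_all_maximal(self):
        column = [5.0, 3.0, 1.0, 0.0, -1.0, 2.0, 4.0]
        fm = FitnessMatrix.from_arrays(
            [f"g{i}" for i in range(7)], ["e1", "e2", "e3"],
            np.column_stack([column] * 3),
        )
        sim = all_pairs_similarity(fm, 0.14, 2, 3)
        values = sim.data.to_numpy()
        assert np.allclose(values, values[0, 0])

    def test_matches_pairwise_calls(self, toy_fitness):
        sim = all_pairs_similarity(toy_fitness, 0.2, 2, 2)
        scheme = build_bucket_scheme(3, 0.2, 2, 2)
        sm = build_scoring_matrix(scheme.n_buckets)
        assignments = {
            e: assign_buckets(toy_fitness.profile(e), scheme, e)
            for e in toy_fitness.experiment_ids
        }
        for a in toy_fitness.experiment_ids:
            for b in toy_fitness.experiment_ids:
                assert sim.pair(a, b) == pytest.approx(
                    pair_similarity(assignments[a], assignments[b], sm)
                )

    def test_symmetric_and_labelled(self, toy_fitness):
        sim = all_pairs_similarity(toy_fitness, 0.2, 2, 2)
        assert sim.method == "BE"
        assert not sim.normalized
        values = sim.data.to_numpy()
        assert np.array_equal(values, values.T)

    def test_pairwise_complete_with_missing(self):
        frame = pd.DataFrame(
            {
                "e1": [9.0, 5.0, 4.0, 1.0, np.nan],
                "e2": [8.0, np.nan, 5.0, 2.0, 0.0],
                "e3": [7.0, 4.0, 3.0, 2.0, 1.0],
            },
            index=[f"g{i}" for i in range(5)],
        )
        sim = all_pairs_similarity(FitnessMatrix(frame), 0.3, 2, 3)
        values = sim.data.to_numpy()
        assert np.array_equal(values, values.T)
        assert np.isfinite(values).all()
        # e1/e2 overlap on 3 genes only; identical ordering there
        assert sim.pair("e1", "e2") > 0

    def test_rank_invariance_of_be_scores(self, rng):
        genes = [f"g{i}" for i in range(60)]
        values = rng.normal(size=(60, 4))
        fm = FitnessMatrix.from_arrays(genes, list("abcd"), values)
        base = all_pairs_similarity(fm, 0.05, 2, 5).data.to_numpy()
        transformed = values.copy()
        transformed[:, 1] = np.tanh(transformed[:, 1]) * 3 + 7
        fm2 = FitnessMatrix.from_arrays(genes, list("abcd"), transformed)
        again = all_pairs_similarity(fm2, 0.05, 2, 5).data.to_numpy()
        assert np.array_equal(base, again)

    def test_single_experiment_rejected(self):
        fm = FitnessMatrix.from_arrays(["g1", "g2"], ["only"], [[1.0], [2.0]])
        with pytest.raises(ParameterError):
            all_pairs_similarity(fm)

    def test_disjoint_gene_sets_rejected(self):
        frame = pd.DataFrame(
            {"e1": [1.0, 2.0, np.nan, np.nan], "e2": [np.nan, np.nan, 1.0, 2.0]},
            index=["g1", "g2", "g3", "g4"],
        )
        with pytest.raises(EmptyInputError):
            all_pairs_similarity(FitnessMatrix(frame), 0.3, 2, 2)


class TestNormalize:
    def test_percent_of_maximum(self):
        frame = pd.DataFrame(
            [[4.0, 2.0], [2.0, 1.0]], index=["a", "b"], columns=["a", "b"]
        )
        sim = SimilarityMatrix(frame, method="BE")
        normalized = normalize_similarity(sim)
        assert normalized.normalized
        assert normalized.data.to_numpy().max() == 100.0
        assert normalized.pair("a", "b") == 50.0
        assert normalized.pair("b", "b") == 25.0

    def test_idempotent(self, toy_fitness):
        sim = all_pairs_similarity(toy_fitness, 0.2, 2, 2)
        once = normalize_similarity(sim)
        twice = normalize_similarity(once)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_recomputation_oracle(self, toy_fitness):
        sim = all_pairs_similarity(toy_fitness, 0.2, 2, 2)
        normalized = normalize_similarity(sim)
        top = sim.data.to_numpy().max()
        expected = sim.data.to_numpy() / top * 100.0
        assert np.allclose(normalized.data.to_numpy(), expected)

    def test_nonpositive_maximum_rejected(self):
        frame = pd.DataFrame(
            [[-1.0, -2.0], [-2.0, -1.0]], index=["a", "b"], columns=["a", "b"]
        )
        with pytest.raises(NormalizationError):
            normalize_similarity(SimilarityMatrix(frame, method="BE"))


class TestSplitSigned:
    def test_literal_rule(self):
        fm = FitnessMatrix.from_arrays(
            ["g1", "g2", "g3"], ["e"], [[-2.0], [3.0], [0.0]]
        )
        positive, negative_abs = split_signed_matrix(fm)
        assert positive.data["e"].tolist() == [0.0, 3.0, 0.0]
        assert negative_abs.data["e"].tolist() == [2.0, 0.0, 0.0]

    def test_all_positive_input_warns(self):
        fm = FitnessMatrix.from_arrays(["g1", "g2"], ["e"], [[1.0], [2.0]])
        with pytest.warns(UserWarning, match="no negative"):
            positive, negative_abs = split_signed_matrix(fm)
        pd.testing.assert_frame_equal(positive.data, fm.data)
        assert (negative_abs.data.to_numpy() == 0).all()

    @settings(max_examples=50, deadline=None)
    @given(
        values=arrays(
            float,
            (4, 3),
            elements=st.floats(-100, 100, allow_nan=False),
        )
    )
    def test_reconstruction_identity(self, values):
        fm = FitnessMatrix.from_arrays(
            [f"g{i}" for i in range(4)], ["a", "b", "c"], values
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            positive, negative_abs = split_signed_matrix(fm)
        recovered = positive.data - negative_abs.data
        assert np.allclose(recovered.to_numpy(), fm.data.to_numpy())
        assert list(positive.data.index) == fm.gene_ids
        assert list(negative_abs.data.columns) == fm.experiment_ids
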