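"""Model core: node/category probabilities, decomposition, likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.special import expit

from mpptree import (
    ItemParams,
    LatentTraits,
    LikertMatrix,
    MppValidationError,
    PseudoItemMatrix,
    category_probabilities,
    category_probability_array,
    decompose,
    mpp_loglik,
    node_probability,
    recompose,
)


class TestNodeProbability:
    def test_zero_logodds_is_half(self):
        assert node_probability(1.0, 0.0, 0.0) == 0.5

    def test_direct_logistic_evaluation(self):
        # alpha*theta + d = 2*1 - 1 = 1 -> logistic(1)
        assert node_probability(2.0, -1.0, 1.0) == pytest.approx(
            1 / (1 + np.exp(-1)), abs=1e-12
        )

    @given(
        alpha=st.floats(0.1, 5),
        d=st.floats(-3, 3),
        t1=st.floats(-3, 3),
        t2=st.floats(-3, 3),
    )
    def test_monotone_in_theta(self, alpha, d, t1, t2):
        lo, hi = sorted([t1, t2])
        if hi - lo > 1e-3:
            assert node_probability(alpha, d, lo) < node_probability(alpha, d, hi)

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(MppValidationError):
            node_probability(0.0, 0.0, 0.0)
        with pytest.raises(MppValidationError):
            node_probability(-1.0, 0.0, 0.0)

    def test_strictly_inside_unit_interval(self):
        p = node_probability(1.0, 30.0, 5.0)
        assert 0 < p < 1


class TestCategoryProbabilities:
    def test_symmetric_half_probabilities(self):
        # all node probabilities 0.5 -> (1/8, 1/8, 1/2, 1/8, 1/8)
        p = category_probabilities(np.ones(3), np.zeros(3), np.zeros(3))
        np.testing.assert_allclose(p, [0.125, 0.125, 0.5, 0.125, 0.125])

    def test_midpoint_node_alone_sets_category3(self):
        # P3 equals the midpoint yes-probability whatever A and E do
        alpha = np.array([1.0, 2.5, 0.3])
        theta = np.array([0.7, -1.2, 2.0])
        for dA, dE in [(-3, 1), (0, 0), (4, -2)]:
            d = np.array([1.5, dA, dE])
            p = category_probabilities(alpha, d, theta)
            assert p[2] == pytest.approx(expit(1.0 * 0.7 + 1.5), abs=1e-14)

    def test_against_independent_tree_formulas(self):
        # oracle: code the five branch products directly from node probabilities
        alpha = np.array([1.0, 1.0, 1.0])
        d = np.array([0.0, 0.0, 0.0])
        theta = np.array([1.0, -1.0, 0.5])
        pM, pA, pE = expit(theta)
        expected = np.array(
            [
                (1 - pM) * (1 - pA) * pE,
                (1 - pM) * (1 - pA) * (1 - pE),
                pM,
                (1 - pM) * pA * (1 - pE),
                (1 - pM) * pA * pE,
            ]
        )
        np.testing.assert_allclose(
            category_probabilities(alpha, d, theta), expected, atol=1e-14
        )
        assert expected.sum() == pytest.approx(1.0, abs=1e-12)

    def test_normalization_over_random_draws(self, rng):
        # probabilities must sum to one for any parameters and traits
        for _ in range(1000):
            alpha = np.exp(rng.normal(0, 1, 3))
            d = rng.normal(0, 2, 3)
            theta = rng.normal(0, 1, 3)
            assert abs(category_probabilities(alpha, d, theta).sum() - 1) < 1e-12

    def test_saturated_midpoint_boundary(self):
        # d_M -> +inf forces category 3
        p = category_probabilities(
            np.ones(3), np.array([500.0, 0.0, 0.0]), np.zeros(3)
        )
        np.testing.assert_allclose(p, [0, 0, 1, 0, 0], atol=1e-12)

    def test_vectorized_matches_scalar(self, small_params, small_traits):
        arr = category_probability_array(small_params, small_traits)
        v, i = 3, 2
        scalar = category_probabilities(
            small_params.alpha[:, i], small_params.d[:, i], small_traits.theta[v]
        )
        np.testing.assert_allclose(arr[v, i], scalar, atol=1e-14)


class TestDecomposition:
    # category -> (M, A, E); NaN = structurally missing
    CODEBOOK = {
        1: (0, 0, 1),
        2: (0, 0, 0),
        3: (1, np.nan, np.nan),
        4: (0, 1, 0),
        5: (0, 1, 1),
    }

    @pytest.mark.parametrize("cat,pattern", sorted(CODEBOOK.items()))
    def test_codebook(self, cat, pattern):
        codes = decompose(LikertMatrix([[cat]])).codes[0, 0]
        np.testing.assert_array_equal(codes, np.array(pattern, dtype=float))

    def test_missing_iff_midpoint(self, small_codes):
        c = small_codes.codes
        midpoint_chosen = c[..., 0] == 1
        assert (np.isnan(c[..., 1]) == midpoint_chosen).all()
        assert (np.isnan(c[..., 2]) == midpoint_chosen).all()
        assert not np.isnan(c[..., 0]).any()

    @given(
        arrays(
            np.int64,
            st.tuples(st.integers(1, 8), st.integers(1, 6)),
            elements=st.integers(1, 5),
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, responses):
        likert = LikertMatrix(responses)
        assert (recompose(decompose(likert)).responses == responses).all()

    def test_recompose_then_decompose_identity(self, small_codes):
        back = decompose(recompose(small_codes))
        np.testing.assert_array_equal(
            np.isnan(back.codes), np.isnan(small_codes.codes)
        )
        obs = ~np.isnan(small_codes.codes)
        np.testing.assert_array_equal(back.codes[obs], small_codes.codes[obs])

    def test_out_of_range_category_names_position(self):
        with pytest.raises(MppValidationError, match="person 1.*item 0"):
            LikertMatrix([[1, 2], [6, 3]])

    def test_illegal_pattern_rejected(self):
        # M=1 with observed agreement code is not a legal tree outcome
        with pytest.raises(MppValidationError, match="illegal"):
            PseudoItemMatrix(np.array([[[1.0, 1.0, np.nan]]]))


class TestLoglik:
    def test_half_probability_cells(self):
        # alpha*theta + d = 0 everywhere -> each observed cell adds ln(1/2)
        params = ItemParams(alpha=np.ones((3, 2)), b=np.zeros((3, 2)))
        traits = LatentTraits(theta=np.zeros((3, 3)))
        likert = LikertMatrix([[1, 2], [4, 5], [2, 1]])  # no midpoints: 18 cells
        ll = mpp_loglik(params, traits, decompose(likert))
        assert ll == pytest.approx(18 * np.log(0.5), abs=1e-12)

    def test_midpoint_response_contributes_only_midpoint_node(self):
        alpha = np.array([[2.0], [1.0], [1.0]])
        b = np.array([[0.5], [0.0], [0.0]])
        params = ItemParams(alpha=alpha, b=b)
        traits = LatentTraits(theta=np.array([[0.3, 5.0, -5.0]]))
        ll = mpp_loglik(params, traits, decompose(LikertMatrix([[3]])))
        p_m = expit(2.0 * 0.3 + 2.0 * 0.5)
        assert ll == pytest.approx(np.log(p_m), abs=1e-12)

    def test_equals_category_loglik(self, small_params, small_traits, small_likert):
        # decomposition must not change the likelihood
        codes = decompose(small_likert)
        ll_tree = mpp_loglik(small_params, small_traits, codes)
        probs = category_probability_array(small_params, small_traits)
        idx = small_likert.responses - 1
        ll_cat = np.log(
            np.take_along_axis(probs, idx[..., None], axis=-1)[..., 0]
        ).sum()
        assert ll_tree == pytest.approx(ll_cat, abs=1e-10)

    def test_overflow_safe_at_extreme_logodds(self):
        params = ItemParams(alpha=np.full((3, 1), 50.0), b=np.ones((3, 1)))
        traits = LatentTraits(theta=np.array([[-3.0, -3.0, -3.0]]))
        ll = mpp_loglik(params, traits, decompose(LikertMatrix([[5]])))
        assert np.isfinite(ll)

    def test_dimension_mismatch(self, small_params, small_traits):
        with pytest.raises(MppValidationError, match="mismatch"):
            mpp_loglik(small_params, small_traits, decompose(LikertMatrix([[1, 2]])))


class TestItemParams:
    def test_d_is_alpha_times_b(self, small_params):
        np.testing.assert_allclose(
            small_params.d, small_params.alpha * small_params.b, atol=1e-14
        )

    def test_positive_alpha_enforced(self):
        with pytest.raises(MppValidationError):
            ItemParams(alpha=np.array([[1.0], [-0.1], [1.0]]), b=np.zeros((3, 1)))

    def test_frame_round_trip(self, small_params):
        back = ItemParams.from_frame(small_params.to_frame())
        np.testing.assert_allclose(back.alpha, small_params.alpha)
        np.testing.assert_allclose(back.b, small_params.b)


class TestCsvIO:
    def test_likert_round_trip(self, tmp_path, small_likert):
        path = tmp_path / "responses.csv"
        small_likert.to_csv(path)
        back = LikertMatrix.from_csv(path)
        assert (back.responses == small_likert.responses).all()

    def test_pseudo_items_round_trip_with_na(self, tmp_path, small_codes):
        path = tmp_path / "codes.csv"
        small_codes.to_csv(path)
        text = path.read_text()
        assert "item1_M" in text and "NA" in text
        back = PseudoItemMatrix.from_csv(path)
        obs = ~np.isnan(small_codes.codes)
        np.testing.assert_array_equal(np.isnan(back.codes), ~obs)
        np.testing.assert_array_equal(back.codes[obs], small_codes.codes[obs])
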