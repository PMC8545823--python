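"""Deterministic model mathematics: ALR transform, expectations, likelihood."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats

from limcomp.core_model import (
    CompositionMatrix,
    LIMParams,
    LinkageDesign,
    LogRatioArray,
    TMCParams,
    alr_inverse,
    alr_transform,
    expected_log_ratio,
    expected_log_ratios,
    lim_log_likelihood,
    tmc_expected_log_ratio,
)


def one_item_design(D: int = 3) -> LinkageDesign:
    return LinkageDesign(
        item_ids=("i1",),
        dim_names=tuple(f"d{k}" for k in range(D)),
        slots=np.arange(D)[None, :],
        statement_ids=tuple(f"s{k}" for k in range(D)),
        statement_dim=np.arange(D),
    )


def as_composition(rows, total=100.0) -> CompositionMatrix:
    arr = np.asarray(rows, dtype=float)
    if arr.ndim == 2:  # persons x D, single item
        arr = arr[:, None, :]
    return CompositionMatrix(arr, total)


class TestALR:
    def test_hand_worked_ratios(self):
        X = as_composition([[50.0, 30.0, 20.0]])
        Y = alr_transform(X, one_item_design(3))
        np.testing.assert_allclose(Y.values[0, 0], [np.log(2.5), np.log(1.5)], atol=1e-12)

    def test_equal_shares_give_zero_ratios(self):
        X = as_composition([[25.0, 25.0, 25.0, 25.0]])
        Y = alr_transform(X, one_item_design(4))
        np.testing.assert_array_equal(Y.values, 0.0)

    def test_zero_score_raises_with_person_and_item(self):
        X = as_composition([[0.0, 50.0, 50.0]])
        with pytest.raises(ValueError, match="unimputed zero.*person '1'.*item '1'"):
            alr_transform(X, one_item_design(3))

    def test_inverse_of_zero_ratios_is_equal_split(self):
        X = alr_inverse(np.zeros((1, 1, 3)), 100.0)
        np.testing.assert_allclose(X.scores, 25.0, atol=1e-12)

    def test_inverse_of_hand_example(self):
        Y = np.array([[[np.log(2.5), np.log(1.5)]]])
        X = alr_inverse(Y, 100.0)
        np.testing.assert_allclose(X.scores[0, 0], [50.0, 30.0, 20.0], atol=1e-10)

    def test_nonfinite_ratio_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            alr_inverse(np.array([[[np.inf, 0.0]]]), 100.0)

    @given(
        hnp.arrays(
            float,
            (3, 2, 4),
            elements=st.floats(0.2, 95.0, allow_nan=False),
        )
    )
    def test_round_trip_identity(self, raw):
        scores = 100.0 * raw / raw.sum(axis=2, keepdims=True)
        design = LinkageDesign(
            item_ids=("i1", "i2"),
            dim_names=("a", "b", "c", "d"),
            slots=np.arange(8).reshape(2, 4),
            statement_ids=tuple(f"s{k}" for k in range(8)),
            statement_dim=np.tile(np.arange(4), 2),
        )
        X = CompositionMatrix(scores, 100.0)
        back = alr_inverse(alr_transform(X, design), 100.0)
        np.testing.assert_allclose(back.scores, X.scores, rtol=1e-10)
        np.testing.assert_allclose(back.scores.sum(axis=2), 100.0, rtol=1e-12)


class TestExpectedLogRatio:
    def test_high_utility_first_statement(self):
        # a person at the origin answering an item whose first statement is
        # 1.5 utility units above the other two
        design = one_item_design(3)
        params = LIMParams(
            theta=np.zeros((1, 3)), delta=np.array([1.5, 0.0, 0.0]), sigma2=1.0
        )
        np.testing.assert_allclose(
            expected_log_ratio([0.0, 0.0, 0.0], "i1", params, design), [1.5, 0.0]
        )

    def test_all_zero_parameters(self):
        design = one_item_design(4)
        params = LIMParams(theta=np.zeros((1, 4)), delta=np.zeros(4), sigma2=1.0)
        np.testing.assert_array_equal(
            expected_log_ratio([0.0] * 4, 0, params, design), 0.0
        )

    def test_two_dimensional_contrast(self):
        design = one_item_design(2)
        params = LIMParams(theta=np.array([[1.0, -1.0]]), delta=np.array([0.3, 0.3]), sigma2=1.0)
        np.testing.assert_allclose(
            expected_log_ratio([1.0, -1.0], "i1", params, design), [2.0]
        )

    def test_unknown_item_raises(self):
        design = one_item_design(3)
        params = LIMParams(theta=np.zeros((1, 3)), delta=np.zeros(3), sigma2=1.0)
        with pytest.raises(KeyError):
            expected_log_ratio([0.0] * 3, "nope", params, design)

    def test_person_contrasts_are_item_free(self, toy_design):
        # the between-person contrast of expected log ratios must not move
        # when the statement utilities are arbitrarily perturbed
        rng = np.random.default_rng(42)
        th_n = np.array([0.8, -0.3, -0.5])
        th_m = np.array([-0.2, 0.7, -0.5])
        base = None
        for _ in range(100):
            delta = rng.normal(0, 2, size=6)
            p = LIMParams(theta=np.vstack([th_n, th_m]), delta=delta, sigma2=1.0)
            contrast = expected_log_ratio(th_n, 0, p, toy_design) - expected_log_ratio(
                th_m, 0, p, toy_design
            )
            if base is None:
                base = contrast
            np.testing.assert_allclose(contrast, base, atol=1e-12)

    def test_item_contrasts_are_sample_free(self, toy_design):
        rng = np.random.default_rng(43)
        delta = rng.normal(0, 1, size=6)
        base = None
        for _ in range(100):
            raw = rng.normal(0, 2, size=3)
            theta = raw - raw.mean()
            p = LIMParams(theta=theta[None, :], delta=delta, sigma2=1.0)
            contrast = expected_log_ratio(theta, 0, p, toy_design) - expected_log_ratio(
                theta, 1, p, toy_design
            )
            if base is None:
                base = contrast
            np.testing.assert_allclose(contrast, base, atol=1e-12)


class TestLikelihood:
    def make_params(self, toy_design, rng):
        raw = rng.normal(size=(2, 3))
        theta = raw - raw.mean(axis=1, keepdims=True)
        # per-dimension slot-sum-zero utilities for the 2-item toy design
        half = rng.normal(size=3)
        delta = np.concatenate([half, -half])
        return LIMParams(theta=theta, delta=delta, sigma2=0.3)

    def test_matches_independent_normal_product(self, toy_design):
        rng = np.random.default_rng(7)
        params = self.make_params(toy_design, rng)
        Y = rng.normal(size=(2, 2, 2))
        expected = expected_log_ratios(params.theta, params.delta, toy_design)
        oracle = stats.norm.logpdf(Y, loc=expected, scale=np.sqrt(params.sigma2)).sum()
        assert lim_log_likelihood(Y, params, toy_design) == pytest.approx(oracle, abs=1e-10)

    def test_zero_residual_term(self, toy_design):
        rng = np.random.default_rng(8)
        params = self.make_params(toy_design, rng)
        Y = expected_log_ratios(params.theta, params.delta, toy_design)
        expected = -0.5 * Y.size * (np.log(params.sigma2) + np.log(2 * np.pi))
        assert lim_log_likelihood(Y, params, toy_design) == pytest.approx(expected, abs=1e-10)

    def test_local_independence_over_items(self, toy_design):
        rng = np.random.default_rng(9)
        params = self.make_params(toy_design, rng)
        Y = rng.normal(size=(2, 2, 2))
        total = lim_log_likelihood(Y, params, toy_design)

        def item_design(i):
            sl = toy_design.slots[i : i + 1]
            return LinkageDesign(
                item_ids=(toy_design.item_ids[i],),
                dim_names=toy_design.dim_names,
                slots=sl - sl.min(),
                statement_ids=toy_design.statement_ids[sl.min() : sl.min() + 3],
                statement_dim=np.arange(3),
            )

        parts = 0.0
        for i in range(2):
            sub = item_design(i)
            p = LIMParams(
                theta=params.theta,
                delta=params.delta[toy_design.slots[i]],
                sigma2=params.sigma2,
            )
            parts += lim_log_likelihood(Y[:, i : i + 1], p, sub)
        assert total == pytest.approx(parts, abs=1e-10)

    def test_invalid_sigma2_rejected(self):
        with pytest.raises(ValueError, match="sigma2"):
            LIMParams(theta=np.zeros((1, 3)), delta=np.zeros(3), sigma2=0.0)

    def test_noise_free_data_maximized_at_truth(self, toy_design):
        # coarse grid over both persons' free trait coordinates
        delta = np.array([0.3, -0.2, -0.1, -0.3, 0.2, 0.1])
        grid = np.array([-0.5, -0.25, 0.0, 0.25, 0.5])
        t_true = np.array([[0.5, -0.25], [-0.5, 0.25]])
        theta_true = np.column_stack([t_true, -t_true.sum(axis=1)])
        truth = LIMParams(theta=theta_true, delta=delta, sigma2=0.01)
        Y = expected_log_ratios(theta_true, delta, toy_design)
        best = lim_log_likelihood(Y, truth, toy_design)
        for a in grid:
            for b in grid:
                for c in grid:
                    for d in grid:
                        t = np.array([[a, b], [c, d]])
                        theta = np.column_stack([t, -t.sum(axis=1)])
                        ll = lim_log_likelihood(
                            Y, LIMParams(theta=theta, delta=delta, sigma2=0.01), toy_design
                        )
                        assert ll <= best + 1e-9


class TestTMCExpectation:
    def test_equal_slopes_reduce_to_lim(self, toy_design):
        rng = np.random.default_rng(11)
        raw = rng.normal(size=3)
        theta = raw - raw.mean()
        half = rng.normal(size=3)
        delta = np.concatenate([half, -half])
        lim = LIMParams(theta=theta[None], delta=delta, sigma2=1.0)
        loc = delta[toy_design.nonref_slots] - delta[toy_design.ref_slots][:, None]
        tmc = TMCParams(
            pair_location=loc, slope=np.ones(6), theta=theta[None], sigma2=1.0
        )
        for item in range(2):
            np.testing.assert_allclose(
                tmc_expected_log_ratio(theta, item, tmc, toy_design),
                expected_log_ratio(theta, item, lim, toy_design),
                atol=1e-12,
            )

    def test_zero_traits_return_locations(self, toy_design):
        loc = np.array([[0.4, -0.2], [0.1, 0.3]])
        tmc = TMCParams(pair_location=loc, slope=np.ones(6), theta=np.zeros((1, 3)), sigma2=1.0)
        for item in range(2):
            np.testing.assert_allclose(
                tmc_expected_log_ratio(np.zeros(3), item, tmc, toy_design), loc[item]
            )

    def test_hand_worked_two_dimensional_case(self):
        design = one_item_design(2)
        tmc = TMCParams(
            pair_location=np.zeros((1, 1)),
            slope=np.array([2.0, 1.0]),
            theta=np.array([[0.5, 0.5]]),
            sigma2=1.0,
        )
        np.testing.assert_allclose(
            tmc_expected_log_ratio([0.5, 0.5], 0, tmc, design), [0.5]
        )


class TestContainers:
    def test_row_sum_violation_names_offender(self):
        with pytest.raises(ValueError, match="person '1'"):
            CompositionMatrix(np.array([[[40.0, 30.0, 20.0]]]), 100.0)

    def test_design_requires_one_slot_per_dimension(self):
        with pytest.raises(ValueError, match="one slot per dimension"):
            LinkageDesign(
                item_ids=("i1",),
                dim_names=("a", "b"),
                slots=np.array([[0, 1]]),
                statement_ids=("s1", "s2"),
                statement_dim=np.array([0, 0]),
            )

    def test_theta_rows_must_be_ipsative(self):
        with pytest.raises(ValueError, match="sum to zero"):
            LIMParams(theta=np.array([[1.0, 1.0, 1.0]]), delta=np.zeros(3), sigma2=1.0)

    def test_log_ratio_array_requires_finite(self):
        with pytest.raises(ValueError, match="finite"):
            LogRatioArray(np.full((1, 1, 2), np.nan), 2)
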