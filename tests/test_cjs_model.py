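import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import all_single_histories, brute_marginal_single, enumerate_marginal
from resight import (
    CaptureHistory,
    CovariateTable,
    ModelSpec,
    ParameterVector,
    Priors,
    chi_probabilities,
    complete_data_loglik,
    inv_logit,
    linear_predictors,
    log_posterior,
    log_prior,
    logit,
    make_log_posterior,
    marginal_loglik,
)


def _covs(n, sex=None, wing=None, e=None):
    return CovariateTable(
        pd.DataFrame(
            {
                "individual_id": [f"i{k}" for k in range(n)],
                "sex": sex if sex is not None else ["F"] * n,
                "wing_length": wing if wing is not None else [48.0] * n,
                "first_occasion": e if e is not None else [1] * n,
            }
        )
    )


class TestLink:
    def test_symmetry_at_half(self):
        assert inv_logit(0.0) == 0.5

    @given(st.floats(-10, 10))
    def test_mutually_inverse(self, x):
        assert logit(inv_logit(x)) == pytest.approx(x, abs=1e-8)

    def test_roundtrip_precision_in_moderate_range(self):
        assert logit(inv_logit(3.7)) == pytest.approx(3.7, abs=1e-12)

    @given(st.floats(-30, 30))
    def test_complement_symmetry(self, x):
        assert inv_logit(-x) == pytest.approx(1 - inv_logit(x), abs=1e-12)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.3])
    def test_logit_domain(self, bad):
        with pytest.raises(ValueError):
            logit(bad)


class TestModelSpec:
    def test_intercept_mandatory(self):
        with pytest.raises(ValueError, match="intercept"):
            ModelSpec(phi_terms=("sex",))

    def test_unknown_terms_rejected(self):
        with pytest.raises(ValueError, match="unknown phi terms"):
            ModelSpec(phi_terms=("intercept", "weather"))
        with pytest.raises(ValueError, match="unknown p terms"):
            ModelSpec(p_terms=("intercept", "age"))

    def test_from_data_standardizes_wing_and_age(self):
        covs = _covs(3, wing=[46.0, 48.0, 50.0])
        spec = ModelSpec.from_data(
            ("intercept", "age", "wing_length"), ("intercept",), covs,
            e=np.array([1, 1, 2]), T=5,
        )
        m, s = spec.standardization["wing_length"]
        assert m == pytest.approx(48.0)
        assert s == pytest.approx(np.std([46, 48, 50]))
        assert "age" in spec.standardization


class TestLinearPredictors:
    def test_null_coefficients_give_half(self):
        spec = ModelSpec(("intercept", "sex"), ("intercept", "sex"))
        covs = _covs(3, sex=["F", "M", "F"])
        phi, p = linear_predictors(
            ParameterVector([0.0, 0.0], [0.0, 0.0]), spec, covs, np.array([1, 1, 1]), 4
        )
        assert np.all(phi == 0.5) and np.all(p == 0.5)
        assert phi.shape == (3, 3) and p.shape == (3, 4)

    def test_intercept_only_is_constant(self):
        phi, p = linear_predictors(
            ParameterVector([1.2], [-0.4]), ModelSpec(), _covs(4), np.array([1, 2, 3, 1]), 6
        )
        assert np.unique(phi).size == 1 and np.unique(p).size == 1
        assert phi[0, 0] == pytest.approx(inv_logit(1.2))

    def test_age_slope_evaluates_linear_predictor(self):
        # age slope 0.1, intercept 2, unstandardized: at t - e = 5, phi = inv_logit(2.5)
        spec = ModelSpec(("intercept", "age"), ("intercept",))
        phi, _ = linear_predictors(
            ParameterVector([2.0, 0.1], [0.0]), spec, _covs(1), np.array([1]), 8
        )
        # column for the interval starting at occasion 6 (age 5)
        assert phi[0, 5] == pytest.approx(inv_logit(2.5))

    def test_missing_wing_length_is_an_error(self):
        spec = ModelSpec(("intercept", "wing_length"), ("intercept",))
        covs = _covs(2, wing=[48.0, np.nan])
        with pytest.raises(ValueError, match="missing wing_length"):
            linear_predictors(
                ParameterVector([0.0, 0.0], [0.0]), spec, covs, np.array([1, 1]), 4
            )


class TestCompleteDataLoglik:
    def test_detection_while_dead_is_impossible(self):
        Y = np.array([[1, 0, 1]])
        X = np.array([[1, 0, 0]])
        out = complete_data_loglik(
            Y, X, np.full((1, 2), 0.9), np.full((1, 3), 0.5), np.array([1])
        )
        assert out == -np.inf

    def test_two_occasion_hand_value(self):
        # survive (0.9) then be detected (0.5); first capture contributes nothing
        out = complete_data_loglik(
            np.array([[1, 1]]), np.array([[1, 1]]),
            np.full((1, 1), 0.9), np.full((1, 2), 0.5), np.array([1]),
        )
        assert out == pytest.approx(math.log(0.9 * 0.5))

    def test_certain_survival_contributes_nothing(self):
        Y = np.array([[1, 0, 1]])
        X = np.ones((1, 3), dtype=int)
        p = np.full((1, 3), 0.5)
        with_states = complete_data_loglik(Y, X, np.ones((1, 2)), p, np.array([1]))
        assert with_states == pytest.approx(math.log(0.5 * 0.5))

    def test_inadmissible_latent_states_raise(self):
        Y = np.array([[1, 0, 0]])
        resurrection = np.array([[1, 0, 1]])
        with pytest.raises(ValueError, match="absorbing"):
            complete_data_loglik(
                Y, resurrection, np.full((1, 2), 0.9), np.full((1, 3), 0.5), np.array([1])
            )
        dead_at_marking = np.array([[0, 0, 0]])
        with pytest.raises(ValueError, match="first capture"):
            complete_data_loglik(
                Y, dead_at_marking, np.full((1, 2), 0.9), np.full((1, 3), 0.5),
                np.array([1]),
            )


class TestMarginalLoglik:
    def test_hand_value_one_zero_one(self):
        # phi^2 * (1-p) * p, last detection at T so chi = 1
        out = marginal_loglik(
            np.array([[1, 0, 1]]), np.full((1, 2), 0.9), np.full((1, 3), 0.5),
            np.array([1]),
        )
        assert out == pytest.approx(math.log(0.2025), abs=1e-12)

    def test_chi_boundary_and_range(self):
        rng = np.random.default_rng(1)
        phi, p = rng.random((4, 6)), rng.random((4, 7))
        chi = chi_probabilities(phi, p)
        assert np.all(chi[:, -1] == 1.0)
        assert np.all((chi >= 0) & (chi <= 1))

    def test_chi_decreases_when_detection_improves(self):
        phi = np.full((1, 5), 0.8)
        lo = chi_probabilities(phi, np.full((1, 6), 0.2))
        hi = chi_probabilities(phi, np.full((1, 6), 0.6))
        assert np.all(hi[:, :-1] <= lo[:, :-1])

    @given(st.integers(0, 2_000))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, T = int(rng.integers(1, 4)), int(rng.integers(2, 9))
        e = rng.integers(1, T + 1, size=n)
        Y = np.zeros((n, T), dtype=int)
        Y[np.arange(n), e - 1] = 1
        later = (np.arange(1, T + 1)[None, :] > e[:, None]) & (rng.random((n, T)) < 0.4)
        Y[later] = 1
        phi = rng.random((n, T - 1))
        p = rng.random((n, T))
        assert marginal_loglik(Y, phi, p, e) == pytest.approx(
            enumerate_marginal(Y, phi, p, e), abs=1e-10
        )

    def test_matches_independent_brute_force(self):
        rng = np.random.default_rng(7)
        for T in (2, 3, 5):
            for e in range(1, T + 1):
                phi = rng.random(T - 1)
                p = rng.random(T)
                for y in all_single_histories(T, e):
                    ours = marginal_loglik(
                        np.array([y]), phi[None, :], p[None, :], np.array([e])
                    )
                    ref = brute_marginal_single(y, phi, p, e)
                    assert ours == pytest.approx(ref, abs=1e-10) or (
                        ours == -np.inf and ref == -np.inf
                    )

    def test_certain_survival_reduces_to_pure_detection(self):
        rng = np.random.default_rng(3)
        T, e = 6, 2
        y = [0, 1, 1, 0, 1, 0]
        p = rng.random(T)
        out = marginal_loglik(
            np.array([y]), np.ones((1, T - 1)), p[None, :], np.array([e])
        )
        expected = sum(
            math.log(p[t - 1]) if y[t - 1] else math.log(1 - p[t - 1])
            for t in range(e + 1, T + 1)
        )
        assert out == pytest.approx(expected, abs=1e-12)

    def test_certain_detection_kills_gappy_histories(self):
        phi = np.full((1, 3), 0.8)
        p = np.full((1, 4), 1.0)
        gap = marginal_loglik(np.array([[1, 0, 1, 0]]), phi, p, np.array([1]))
        assert gap == -np.inf
        # contiguous run then never seen again: survive twice, then chi = death
        run = marginal_loglik(np.array([[1, 1, 1, 0]]), phi, p, np.array([1]))
        assert run == pytest.approx(math.log(0.8 * 0.8 * 0.2), abs=1e-12)

    def test_invariant_to_individual_order(self):
        rng = np.random.default_rng(11)
        n, T = 6, 7
        e = rng.integers(1, T + 1, size=n)
        Y = np.zeros((n, T), dtype=int)
        Y[np.arange(n), e - 1] = 1
        later = (np.arange(1, T + 1)[None, :] > e[:, None]) & (rng.random((n, T)) < 0.5)
        Y[later] = 1
        phi, p = rng.random((n, T - 1)), rng.random((n, T))
        perm = rng.permutation(n)
        assert marginal_loglik(Y, phi, p, e) == pytest.approx(
            marginal_loglik(Y[perm], phi[perm], p[perm], e[perm]), abs=1e-10
        )


class TestPriorAndPosterior:
    def test_prior_mode_value(self):
        params = ParameterVector([0.0, 0.0], [0.0])
        expected = 3 * math.log(1.0 / (10.0 * math.sqrt(2 * math.pi)))
        assert log_prior(params) == pytest.approx(expected)

    def test_one_sd_shift_costs_half(self):
        at_zero = log_prior(ParameterVector([0.0], [0.0]))
        at_ten = log_prior(ParameterVector([10.0], [0.0]))
        assert at_ten - at_zero == pytest.approx(-0.5)

    def test_symmetric_under_negation(self):
        rng = np.random.default_rng(0)
        b = rng.normal(size=3)
        assert log_prior(ParameterVector(b[:2], b[2:])) == pytest.approx(
            log_prior(ParameterVector(-b[:2], -b[2:]))
        )

    def test_precision_must_be_positive(self):
        with pytest.raises(ValueError):
            Priors(precision=0.0)

    def test_posterior_is_sum_of_parts(self):
        rng = np.random.default_rng(5)
        Y = np.array([[1, 0, 1, 0], [0, 1, 1, 0]])
        e = np.array([1, 2])
        h = CaptureHistory(["i0", "i1"], 4, Y, e)
        covs = _covs(2, e=e)
        spec = ModelSpec()
        for _ in range(5):
            params = ParameterVector(rng.normal(size=1), rng.normal(size=1))
            phi, p = linear_predictors(params, spec, covs, e, 4)
            expected = marginal_loglik(Y, phi, p, e) + log_prior(params)
            assert log_posterior(params, spec, h, covs) == pytest.approx(expected)
            # the compiled closure agrees with the reference composition
            fast = make_log_posterior(spec, h, covs)
            assert fast(params.flatten()) == pytest.approx(expected, abs=1e-9)

    def test_all_detected_data_favors_high_p_until_prior_dominates(self):
        Y = np.ones((5, 6), dtype=int)
        e = np.ones(5, dtype=int)
        h = CaptureHistory([f"i{k}" for k in range(5)], 6, Y, e)
        fast = make_log_posterior(ModelSpec(), h, _covs(5))
        grid = np.linspace(-2, 60, 40)
        vals = [fast(np.array([2.0, b])) for b in grid]
        peak = int(np.argmax(vals))
        assert 0 < peak < len(grid) - 1
        assert vals[peak] > vals[0] and vals[peak] > vals[-1]
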