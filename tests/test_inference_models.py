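import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq
from scipy.stats import kstest

from transinfer.inference_models import (
    ModelFit,
    build_likelihood,
    expected_correct,
    fit_model,
    generalisation_prob,
    inference_prob,
    mediating_sets,
    premise_prob,
    premise_prob_sum,
    sample_r,
    spearman_observed_expected,
)
from transinfer.task_design import inferred_pairs, premise_pairs


class TestPremiseProbability:
    def test_sum_over_m_equals_closed_binomial_form(self):
        # The two-stage sum and the collapsed binomial agree to 1e-10.
        for n in range(1, 13):
            for k in range(n + 1):
                for r in np.linspace(0.0, 1.0, 21):
                    assert premise_prob_sum(k, n, r) == pytest.approx(
                        float(premise_prob(k, n, r)), abs=1e-10
                    )

    @pytest.mark.parametrize(
        "k,n,r,expected",
        [(8, 8, 1.0, 1.0),
         (4, 8, 0.0, 70 / 256),
         (6, 8, 0.6, 28 * 0.8**6 * 0.2**2)],
    )
    def test_point_values(self, k, n, r, expected):
        assert premise_prob(k, n, r) == pytest.approx(expected, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            premise_prob(9, 8, 0.5)
        with pytest.raises(ValueError):
            premise_prob(4, 8, 1.5)

    def test_inference_prob_is_same_functional_form(self):
        g = np.linspace(0, 1, 11)
        for k in range(9):
            assert np.allclose(inference_prob(k, 8, g), premise_prob(k, 8, g))


class TestLikelihood:
    def test_normalising_constant_closed_form(self):
        # c(8|8) = int ((1+r)/2)^8 dr = (2/9)(1 - 2^-9).
        L = build_likelihood(8, 8)
        assert L.c == pytest.approx((2 / 9) * (1 - 2**-9), abs=1e-6)
        assert L.L[-1] == pytest.approx(1 / L.c, rel=1e-6)

    def test_constants_sum_to_one_over_k(self):
        total = sum(build_likelihood(k, 8).c for k in range(9))
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_likelihood_integrates_to_one_and_cdf_monotone(self):
        for k in (0, 3, 8):
            L = build_likelihood(k, 8)
            assert np.trapezoid(L.L, L.r_grid) == pytest.approx(1.0, abs=1e-6)
            assert L.cdf[0] == 0.0 and L.cdf[-1] == pytest.approx(1.0)
            assert np.all(np.diff(L.cdf) >= 0)

    def test_inverse_transform_median_matches_root_finder(self):
        # Median of L(r|8,8) solves (2/9)[((1+r)/2)^9 - 2^-9] = c/2.
        L = build_likelihood(8, 8)
        target = brentq(
            lambda r: (2 / 9) * (((1 + r) / 2) ** 9 - 2**-9) - L.c / 2, 0, 1
        )
        assert sample_r(L, 0.5) == pytest.approx(target, abs=1e-3)
        assert target == pytest.approx(0.8522, abs=1e-4)

    def test_samples_match_likelihood_distribution(self, rng):
        L = build_likelihood(6, 8)
        samples = sample_r(L, rng.uniform(size=10_000))
        res = kstest(samples, lambda x: np.interp(x, L.r_grid, L.cdf))
        assert res.pvalue > 0.01

    def test_sample_bounds(self):
        L = build_likelihood(5, 8)
        assert sample_r(L, 0.0) == 0.0
        assert sample_r(L, 1.0) == 1.0


class TestMediatingSets:
    @pytest.mark.parametrize(
        "pair,exp_a,exp_o",
        [("B>E", ["B>C", "C>D", "D>E"], ["B>C", "D>E"]),
         ("B>D", ["B>C", "C>D"], ["B>C", "C>D"]),
         ("B>F", ["B>C", "C>D", "D>E", "E>F"], ["B>C", "E>F"])],
    )
    def test_chains(self, pair, exp_a, exp_o):
        disc = next(d for d in inferred_pairs("recent") if d.name == pair)
        a, o = mediating_sets(disc)
        assert a == exp_a and o == exp_o
        assert len(a) == disc.distance

    def test_premise_input_rejected(self):
        with pytest.raises(ValueError):
            mediating_sets(premise_pairs("recent")[0])


class TestGeneralisationProbability:
    @pytest.mark.parametrize(
        "model,kappa,a,o,expected",
        [("AND", 1.0, [1, 1, 1], None, 1.0),
         ("AND", 0.9, [0.9, 0.8], None, 0.648),
         ("OR", 0.9, [0.9, 0.8], [0.9, 0.8], 0.9 * (1 - 0.02))],
    )
    def test_point_values(self, model, kappa, a, o, expected):
        assert generalisation_prob(model, kappa, a, o) == pytest.approx(expected)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        kappa=st.floats(0, 1),
        rs=st.lists(st.floats(0, 1), min_size=2, max_size=4),
    )
    def test_or_dominates_and_at_matched_samples(self, kappa, rs):
        g_and = generalisation_prob("AND", kappa, rs)
        g_or = generalisation_prob("OR", kappa, rs, [rs[0], rs[-1]])
        assert g_or >= g_and - 1e-12

    def test_and_nonincreasing_in_distance_at_fixed_r(self):
        r = 0.8
        gs = [generalisation_prob("AND", 1.0, [r] * d) for d in (2, 3, 4)]
        assert gs[0] >= gs[1] >= gs[2]

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            generalisation_prob("AND", 0.5, [])


class TestModelFitting:
    @staticmethod
    def _counts(k_premise, k_inference):
        prem = {d.name: k_premise for d in premise_pairs("recent")}
        infs = [(d, k_inference) for d in inferred_pairs("recent")]
        return prem, infs

    def test_perfect_data_drives_kappa_to_one(self):
        prem, infs = self._counts(8, 8)
        fit = fit_model(prem, infs, "OR", n_iter=500, seed=1)
        assert fit.kappa_hat > 0.98
        assert fit.H < 0.2

    def test_chance_data_drives_kappa_to_zero(self):
        prem, infs = self._counts(8, 4)
        fit = fit_model(prem, infs, "AND", n_iter=500, seed=1)
        assert fit.kappa_hat < 0.02
        assert fit.H == pytest.approx(-np.log(70 / 256), abs=1e-3)

    def test_fitted_kappa_beats_fixed_grid(self):
        prem, infs = self._counts(7, 6)
        for model in ("AND", "OR"):
            fit = fit_model(prem, infs, model, n_iter=400, seed=3)
            rng = np.random.default_rng(3)
            from transinfer.inference_models import _iteration_factors

            q = _iteration_factors(prem, infs, model, 400, rng)
            k_obs = np.array([k for _, k in infs])
            for kappa in (0.0, 0.25, 0.5, 0.75, 1.0):
                h = -np.mean(
                    [np.log(inference_prob(k_obs[i], 8, kappa * q[i]).mean())
                     for i in range(len(infs))]
                )
                assert fit.H <= h + 1e-9

    def test_fits_reproducible_given_seed(self):
        prem, infs = self._counts(7, 6)
        a = fit_model(prem, infs, "OR", n_iter=300, seed=11)
        b = fit_model(prem, infs, "OR", n_iter=300, seed=11)
        assert a.kappa_hat == b.kappa_hat and a.H == b.H

    def test_expected_correct_formula(self):
        assert expected_correct(1.0) == 8
        assert expected_correct(0.0) == 4
        assert expected_correct(0.648) == pytest.approx(6.592)

    def test_spearman_flags_constant_expectations(self):
        import pandas as pd

        fit = ModelFit(
            model="OR", kappa_hat=0.5, H=1.0,
            per_inference=pd.DataFrame(
                {"k_obs": [5, 6, 7], "expected_k": [6.0, 6.0, 6.0]}
            ),
            n_iter=10, seed=0, I=3, converged=True,
        )
        assert np.isnan(spearman_observed_expected(fit))
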