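"""Unit and property tests of the Bayes-factor model machinery."""
from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import special, stats

from twinase import (
    ASEParams,
    AllelicCountRecord,
    GridSpec,
    PriorSpec,
    bayes_factor,
    brute_force_log_marginal,
    fit_mode,
    importance_sample_log_marginal,
    log_marginal,
    loglik,
)

from conftest import random_instance, swap_alleles


def rec(pair, member, alt, ref):
    return AllelicCountRecord(pair, member, "snpX", "txX", alt, ref)


class TestLoglik:
    def test_balanced_single_record_closed_form(self):
        r = [rec("p0", "affected", 1, 1)]
        value = loglik(r, ASEParams(0.0, 0.0, np.zeros(1)), "M1")
        assert value == pytest.approx(math.log(0.5), abs=1e-12)

    def test_matches_binomial_pmf_at_shifted_logit(self):
        r = [rec("p0", "affected", 3, 1)]
        value = loglik(r, ASEParams(float(special.logit(0.75)), 0.0, np.zeros(1)), "M1")
        expected = stats.binom.logpmf(3, 4, 0.75)
        assert value == pytest.approx(expected, abs=1e-10)

    def test_m0_ignores_betas_and_affected_status(self):
        r = [rec("p0", "affected", 7, 3), rec("p0", "unaffected", 2, 8)]
        with_effect = loglik(r, ASEParams(0.3, 5.0, np.array([0.1])), "M0")
        without = loglik(r, ASEParams(0.3, 0.0, np.array([0.1])), "M0")
        assert with_effect == without

    def test_beta_binomial_limit_matches_binomial(self):
        rng = np.random.default_rng(0)
        r = random_instance(rng, 2)
        base = loglik(r, ASEParams(0.2, 0.5, np.array([0.1, -0.3])), "M1")
        near = loglik(r, ASEParams(0.2, 0.5, np.array([0.1, -0.3]), rho=1e-8), "M1")
        assert near == pytest.approx(base, abs=1e-5)

    def test_overdispersion_lowers_peak_density(self):
        r = [rec("p0", "affected", 50, 50)]
        crisp = loglik(r, ASEParams(0.0, 0.0, np.zeros(1)), "M1")
        wide = loglik(r, ASEParams(0.0, 0.0, np.zeros(1), rho=0.2), "M1")
        assert wide < crisp

    def test_gamma_length_mismatch_rejected(self):
        r = [rec("p0", "affected", 1, 1), rec("p1", "affected", 2, 2)]
        with pytest.raises(ValueError, match="gamma"):
            loglik(r, ASEParams(0.0, 0.0, np.zeros(1)), "M1")

    def test_empty_and_zero_depth_records(self):
        with pytest.raises(ValueError):
            loglik([], ASEParams(0.0, 0.0, np.zeros(0)), "M1")
        with pytest.raises(ValueError, match="zero total depth"):
            loglik(
                [AllelicCountRecord("p0", "affected", "s", "t", 0, 0)],
                ASEParams(0.0, 0.0, np.zeros(1)),
                "M1",
            )


class TestFitMode:
    def test_balanced_counts_give_symmetric_mode(self):
        r = [rec(f"p{i}", m, 20, 20) for i in range(3) for m in ("affected", "unaffected")]
        fit = fit_mode(r, "M1")
        assert abs(fit.mode[0]) < 1e-3  # beta0
        assert abs(fit.mode[1]) < 1e-3  # betas
        assert fit.converged

    def test_recovers_generating_effect(self):
        rng = np.random.default_rng(7)
        recs = []
        for i in range(9):
            for m, s in (("affected", 1.0), ("unaffected", 0.0)):
                a = int(rng.binomial(1000, special.expit(2.0 * s)))
                recs.append(rec(f"p{i}", m, a, 1000 - a))
        fit = fit_mode(recs, "M1")
        assert fit.converged
        assert fit.mode[1] == pytest.approx(2.0, abs=0.3)

    def test_empty_record_list_rejected(self):
        with pytest.raises(ValueError):
            fit_mode([], "M1")


class TestLogMarginal:
    def test_tiny_instance_matches_oracle_and_methods_rank(self):
        # one pair, depth-2 records: the refined method tracks the grid
        # oracle closely; plain nested Laplace is within its cruder remit
        r = [rec("p0", "affected", 1, 1), rec("p0", "unaffected", 1, 1)]
        for model in ("M1", "M0"):
            a = log_marginal(r, model, method="laplace_aghq")
            l = log_marginal(r, model, method="laplace")
            oracle = brute_force_log_marginal(r, model)
            assert a.converged and l.converged
            assert a.log_marginal == pytest.approx(oracle, abs=0.05)
            assert l.log_marginal == pytest.approx(oracle, abs=0.25)

    def test_methods_agree_on_the_bayes_factor(self):
        # plain nested Laplace biases both models' marginals the same way
        # (its outer-Gaussian error is shared), so the BF it implies
        # coincides with the refined method's to high accuracy
        r = [rec("p0", "affected", 104, 96), rec("p0", "unaffected", 99, 101),
             rec("p1", "affected", 110, 90), rec("p1", "unaffected", 95, 105)]
        diffs = {}
        for method in ("laplace_aghq", "laplace"):
            m1 = log_marginal(r, "M1", method=method)
            m0 = log_marginal(r, "M0", method=method)
            assert m1.converged and m0.converged
            diffs[method] = m1.log_marginal - m0.log_marginal
        assert diffs["laplace"] == pytest.approx(diffs["laplace_aghq"], abs=0.05)

    def test_random_effect_collapse_limit(self):
        # with the sigma_gamma prior collapsed, the marginal reduces to
        # the fixed-effect-only model: lik(gamma=0) integrated over beta0
        r = [rec("p0", "affected", 12, 8), rec("p0", "unaffected", 9, 11),
             rec("p1", "affected", 15, 10), rec("p1", "unaffected", 11, 9)]
        priors = PriorSpec(beta_sd=3.0, sigma_gamma_prior=1e-3)
        got = log_marginal(r, "M0", priors).log_marginal
        # independent 1-D quadrature over beta0 alone
        b = np.linspace(-12, 12, 4001)
        alt = np.array([12, 9, 15, 11]); tot = np.array([20, 20, 25, 20])
        logC = special.gammaln(tot + 1) - special.gammaln(alt + 1) - special.gammaln(tot - alt + 1)
        ll = (logC[None, :] + alt[None, :] * special.log_expit(b[:, None])
              + (tot - alt)[None, :] * special.log_expit(-b[:, None])).sum(axis=1)
        prior = -0.5 * (b / 3.0) ** 2 - math.log(3.0) - 0.5 * math.log(2 * math.pi)
        oracle = special.logsumexp(ll + prior + math.log(b[1] - b[0]))
        assert got == pytest.approx(float(oracle), abs=0.05)

    def test_bic_mode_penalizes_parameters(self):
        rng = np.random.default_rng(3)
        r = random_instance(rng, 2)
        m1 = log_marginal(r, "M1", method="bic").log_marginal
        m0 = log_marginal(r, "M0", method="bic").log_marginal
        assert np.isfinite(m1) and np.isfinite(m0)


class TestBruteForce:
    def test_degenerate_priors_reduce_to_pointmass_likelihood(self):
        r = [rec("p0", "affected", 6, 4), rec("p0", "unaffected", 5, 5)]
        priors = PriorSpec(beta_sd=1e-3, sigma_gamma_prior=1e-3)
        grid = GridSpec(beta_half_range=0.01, n_beta=81, gamma_half_range=0.01,
                        sigma_max=0.008, n_sigma=40, sigma_low=0.0008,
                        n_sigma_low=8, sigma_low_min=5e-5)
        got = brute_force_log_marginal(r, "M1", priors, grid)
        at_zero = loglik(r, ASEParams(0.0, 0.0, np.zeros(1)), "M1")
        assert got == pytest.approx(at_zero, abs=0.05)

    def test_grid_refinement_is_converged(self):
        rng = np.random.default_rng(5)
        r = random_instance(rng, 2)
        base = brute_force_log_marginal(r, "M1")
        fine = brute_force_log_marginal(r, "M1", grid=GridSpec().refine())
        assert abs(fine - base) < 0.02

    def test_importance_sampling_second_oracle(self):
        r = [rec("p0", "affected", 20, 29), rec("p0", "unaffected", 18, 1),
             rec("p1", "affected", 1, 21), rec("p1", "unaffected", 21, 5)]
        for model in ("M1", "M0"):
            grid_val = brute_force_log_marginal(r, model)
            mc = importance_sample_log_marginal(r, model, n_draws=300_000, seed=1)
            assert mc == pytest.approx(grid_val, abs=0.1)

    def test_refuses_high_dimension(self):
        rng = np.random.default_rng(1)
        r = random_instance(rng, 4)
        with pytest.raises(ValueError, match="3 pairs"):
            brute_force_log_marginal(r, "M1")


class TestBayesFactor:
    def test_identical_counts_in_both_members_is_no_call(self):
        # M1's extra parameter buys nothing; the Occam penalty keeps BF low
        r = []
        for i in range(9):
            r += [rec(f"p{i}", "affected", 30, 20), rec(f"p{i}", "unaffected", 30, 20)]
        b = bayes_factor(r)
        assert b.converged
        assert not b.call
        assert b.bf < 5.0

    def test_bf_is_exp_of_logml_difference(self):
        rng = np.random.default_rng(9)
        r = random_instance(rng, 3)
        b = bayes_factor(r)
        assert b.bf == pytest.approx(math.exp(b.logml_m1 - b.logml_m0), rel=1e-12)
        assert b.n_informative_pairs == 3

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_allele_swap_leaves_bf_unchanged(self, seed):
        rng = np.random.default_rng(seed)
        r = random_instance(rng, int(rng.integers(1, 4)))
        b1 = bayes_factor(r)
        b2 = bayes_factor(swap_alleles(r))
        assert b2.bf == pytest.approx(b1.bf, rel=1e-6)

    def test_strong_discordance_is_called(self):
        rng = np.random.default_rng(2)
        r = []
        for i in range(9):
            a_aff = int(rng.binomial(500, special.expit(2.0)))
            a_un = int(rng.binomial(500, 0.5))
            r += [rec(f"p{i}", "affected", a_aff, 500 - a_aff),
                  rec(f"p{i}", "unaffected", a_un, 500 - a_un)]
        b = bayes_factor(r)
        assert b.call and b.bf > 5.0

    def test_profile_rho_runs_on_overdispersed_counts(self):
        rng = np.random.default_rng(4)
        r = []
        for i in range(4):
            for m in ("affected", "unaffected"):
                p = rng.beta(8, 8)  # extra-binomial variation
                a = int(rng.binomial(300, p))
                r += [rec(f"p{i}", m, a, 300 - a)]
        b = bayes_factor(r, priors=PriorSpec(rho_mode="profile"))
        assert np.isfinite(b.logml_m0) and np.isfinite(b.logml_m1)

    def test_fixed_rho_matches_brute_force(self):
        rng = np.random.default_rng(6)
        r = random_instance(rng, 2, max_depth=40)
        priors = PriorSpec(rho_mode="fixed_value", rho_value=0.05)
        got = log_marginal(r, "M0", priors).log_marginal
        oracle = brute_force_log_marginal(r, "M0", priors)
        assert got == pytest.approx(oracle, abs=0.1)
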