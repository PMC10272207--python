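import math

import numpy as np
import pytest
from scipy import special, stats

import slamkin as sk
from slamkin.snapshot import (AbundancePrior, NtrHyperPrior, SnapshotInput,
                              estimate_condition_samples, fit_abundance_prior,
                              fold_change_posterior, halflife_change_from_old_fc,
                              sample_abundance_posterior, sample_ntr_posterior,
                              transform_snapshot, _ntr_grid_logdens)

LN2 = math.log(2)


class TestTransformSnapshot:
    def test_steady_state_half_survival(self):
        # F = 1/2 at t = 1 h: delta = ln 2; with a_new = a_ref/2: sigma = a_ref*ln2
        sigma, delta = transform_snapshot(0.5, 0.5, 1.0, t=1.0)
        assert delta == pytest.approx(LN2)
        assert sigma == pytest.approx(LN2)

    def test_no_decay_limit(self):
        _, delta = transform_snapshot(0.1, 1.0 - 1e-9, 1.0, t=1.0)
        assert delta == pytest.approx(0.0, abs=1e-6)

    def test_grown_old_rna_rejected(self):
        with pytest.raises(ValueError, match="cannot grow"):
            transform_snapshot(0.1, 1.2, 1.0, t=1.0)

    def test_earlier_reference_round_trip(self):
        sigma, delta, t, t_ref = 8.0, 0.6, 2.0, -1.0
        a_prime = 11.0
        a0 = a_prime * math.exp(t_ref * delta) + sigma / delta * (
            1 - math.exp(t_ref * delta))
        a_new = sigma / delta * (1 - math.exp(-t * delta))
        a_old = a0 * math.exp(-t * delta)
        s_est, d_est = transform_snapshot(a_new, a_old, a_prime, t, t_ref)
        assert d_est == pytest.approx(delta, abs=1e-8)
        assert s_est == pytest.approx(sigma, rel=1e-8)


class TestOldRnaFoldChange:
    def test_unit_fold_change_identity(self):
        assert halflife_change_from_old_fc(1.0, 2.0, 3.0) == pytest.approx(3.0)

    def test_direct_arithmetic(self):
        # f = 2 over t = 4 h removes half the degradation of a 2 h half-life:
        # t1/2' = 2 / (1 - 2*1/4) = 4
        assert halflife_change_from_old_fc(2.0, 4.0, 2.0) == pytest.approx(4.0)

    def test_fully_compensating_fold_change_is_degenerate(self):
        # f = 2 over t = 2 h cancels a ln2/2 degradation rate entirely
        with pytest.raises(ValueError):
            halflife_change_from_old_fc(2.0, 2.0, 2.0)

    def test_exponential_fold_change_adds_to_delta(self):
        delta, extra, t = 0.3, 0.25, 2.0
        f = math.exp(-t * extra)
        hl_new = halflife_change_from_old_fc(f, t, LN2 / delta)
        assert LN2 / hl_new == pytest.approx(delta + extra, rel=1e-12)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            halflife_change_from_old_fc(10.0, 1.0, 5.0)


class TestAbundancePosterior:
    def test_prior_moment_recovery(self):
        rng = np.random.default_rng(0)
        p = rng.beta(2.0, 5.0, size=100_000)
        d = 0.1
        c = (1 - p) / (p * d)  # expressions whose p-transform is Beta(2,5)
        prior = fit_abundance_prior(c, np.full_like(c, d))
        assert prior.alpha == pytest.approx(2.0, rel=0.02)
        assert prior.beta == pytest.approx(5.0, rel=0.02)

    def test_degenerate_moments_fall_back_to_flat(self):
        with pytest.warns(UserWarning, match="Beta"):
            prior = fit_abundance_prior(np.full(20, 100.0), np.full(20, 0.1))
        assert (prior.alpha, prior.beta) == (1.0, 1.0)

    def test_conjugate_update_example(self):
        # c=10, d=0.1 (s=10), flat prior: posterior Beta(11, 11) on p,
        # so E[mu] = E[(1-p)/p]/d = (11/10)/0.1 = 11
        rng = np.random.default_rng(1)
        draws = sample_abundance_posterior(
            np.array([10.0]), 0.1, AbundancePrior(1.0, 1.0), 400_000, rng)
        assert np.mean(draws) == pytest.approx(11.0, rel=0.01)

    def test_zero_counts_concentrate_near_zero(self):
        rng = np.random.default_rng(2)
        draws = sample_abundance_posterior(
            np.zeros(3), 0.05, AbundancePrior(1.0, 1.0), 5000, rng)
        assert np.median(draws) < 1.0

    @pytest.mark.parametrize("case", range(10))
    def test_conjugacy_matches_quadrature_oracle(self, case):
        rng = np.random.default_rng(100 + case)
        d = float(rng.uniform(0.02, 0.3))
        s = 1.0 / d
        mu_true = float(rng.uniform(20, 400))
        counts = rng.negative_binomial(s, s / (s + mu_true), size=3).astype(float)
        prior = AbundancePrior(float(rng.uniform(0.5, 4)),
                               float(rng.uniform(0.5, 4)))
        n = 80_000
        draws = sample_abundance_posterior(counts, d, prior, n, rng)
        # brute-force quadrature over mu
        mu = np.linspace(1e-3, mu_true * 6 + 200, 6000)
        p = s / (s + mu)
        ll = np.sum([stats.nbinom.logpmf(c, s, p) for c in counts], axis=0)
        lp = stats.beta.logpdf(p, prior.alpha, prior.beta) + np.log(
            s / (s + mu) ** 2)
        w = np.exp(ll + lp - np.max(ll + lp))
        w /= np.trapezoid(w, mu)
        mean_q = np.trapezoid(w * mu, mu)
        se = np.std(draws) / math.sqrt(n)
        assert np.mean(draws) == pytest.approx(mean_q, abs=max(3 * se, 1e-3 * mean_q))


class TestNtrGridSampler:
    def test_jacobian_at_origin_is_quarter(self):
        prior = NtrHyperPrior(offset=10.0, scale=1.0)
        ld = _ntr_grid_logdens(np.array(0.0), np.array(0.0),
                               np.array([1.0]), np.array([1.0]), prior)
        # remove prior and replicate terms to isolate log |J| = -log 4
        ll = special.betaln(1.5, 1.5) - special.betaln(0.5, 0.5)
        log_jac = float(ld) - float(prior.logpdf(1.0)) - ll
        assert math.exp(log_jac) == pytest.approx(0.25, rel=1e-9)

    def test_sigmoid_normalizer_closed_form(self):
        assert NtrHyperPrior(offset=1e-9, scale=1.0).normalizer == pytest.approx(
            math.log(2), abs=1e-6)
        # generic value: C = s*log(1+e^(o/s))
        pr = NtrHyperPrior(offset=3.0, scale=2.0)
        assert pr.normalizer == pytest.approx(2 * math.log1p(math.exp(1.5)))

    def test_single_replicate_diffuse_prior_matches_beta_mean(self):
        rng = np.random.default_rng(3)
        draws = sample_ntr_posterior(
            np.array([20.0]), np.array([60.0]), 40_000, rng,
            prior=NtrHyperPrior(offset=1e6, scale=1e5))
        assert np.mean(draws) == pytest.approx(0.25, abs=0.01)

    def test_precise_symmetric_replicates_concentrate_at_half(self):
        rng = np.random.default_rng(4)
        a = np.array([500.0, 500.0, 500.0])
        draws = sample_ntr_posterior(a, a, 5000, rng)
        assert np.mean(draws) == pytest.approx(0.5, abs=0.005)
        assert np.std(draws) < 0.05


class TestConditionSampling:
    def _input(self, count, ref, alpha, beta, t=2.0, d=0.01):
        return SnapshotInput(
            counts=np.full(3, count), ref_counts=np.full(3, ref),
            alphas=np.full(3, alpha), betas=np.full(3, beta), t=t,
            dispersion=d)

    def test_concentration_limit_matches_deterministic_transform(self):
        rng = np.random.default_rng(5)
        # huge counts and Beta shapes: posterior collapses onto the inputs
        ntr = 0.4
        inp = self._input(50_000, 50_000, 4000 * ntr, 4000 * (1 - ntr),
                          d=1e-4)
        prior = AbundancePrior(1.0, 1.0)
        sig, dlt, rej = estimate_condition_samples(inp, prior, 2000, rng)
        s_exp, d_exp = transform_snapshot(50_000 * ntr, 50_000 * (1 - ntr),
                                          50_000.0, 2.0)
        assert rej < 0.01
        assert np.median(dlt) == pytest.approx(d_exp, rel=0.05)
        assert np.median(sig) == pytest.approx(s_exp, rel=0.05)

    def test_sigma_delta_draws_positively_correlated_short_labeling(self):
        rng = np.random.default_rng(6)
        inp = self._input(200, 200, 30.0, 90.0, t=0.5)
        sig, dlt, _ = estimate_condition_samples(
            inp, AbundancePrior(1.0, 1.0), 4000, rng)
        assert np.corrcoef(np.log(sig), np.log(dlt))[0, 1] > 0.2

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            estimate_condition_samples(
                self._input(100, 100, 10, 30), AbundancePrior(), 0,
                np.random.default_rng(0))


class TestFoldChangePosterior:
    def test_identical_draws_give_null(self):
        draws = (np.full(500, 2.0), np.full(500, 0.3))
        s = fold_change_posterior(draws, draws)
        assert s.map_lfc_sigma == pytest.approx(0.0)
        assert s.map_lfc_halflife == pytest.approx(0.0)
        assert s.p_sigma == 0.0 and s.p_delta == 0.0

    def test_exact_doubling_detected(self):
        rng = np.random.default_rng(7)
        sig_b = rng.lognormal(0, 0.01, 1000)
        dlt = rng.lognormal(-1, 0.01, 1000)
        s = fold_change_posterior((2 * sig_b, dlt), (sig_b, dlt))
        assert s.map_lfc_sigma == pytest.approx(1.0, abs=0.02)
        assert s.p_sigma == 1.0

    def test_halflife_sign_convention(self):
        # smaller delta in A = more stable = positive half-life lfc
        rng = np.random.default_rng(8)
        dlt_b = rng.lognormal(0, 0.01, 500)
        s = fold_change_posterior((np.ones(500), 0.5 * dlt_b),
                                  (np.ones(500), dlt_b))
        assert s.map_lfc_halflife == pytest.approx(1.0, abs=0.05)

    def test_rope_invariant_under_joint_permutation(self):
        rng = np.random.default_rng(9)
        a = (rng.lognormal(0, 0.4, 600), rng.lognormal(0, 0.4, 600))
        b = (rng.lognormal(0, 0.4, 600), rng.lognormal(0, 0.4, 600))
        s1 = fold_change_posterior(a, b)
        perm = rng.permutation(600)
        s2 = fold_change_posterior((a[0][perm], a[1][perm]),
                                   (b[0][perm], b[1][perm]))
        assert s1.p_sigma == pytest.approx(s2.p_sigma)
        assert s1.p_delta == pytest.approx(s2.p_delta)

    def test_few_draws_flagged_low_confidence(self):
        a = (np.ones(10), np.ones(10))
        assert fold_change_posterior(a, a).low_confidence
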