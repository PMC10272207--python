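import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

import slamkin as sk
from slamkin.kinetics import (fit_lm, fit_nlls, fit_ntr_bayes, fit_pulser,
                              fit_kinetics, ntr_log_posterior,
                              ntr_point_estimates)

LN2 = math.log(2)


class TestLM:
    def test_exact_log_linear_data(self):
        t = np.array([1.0, 2.0, 4.0])
        old = 10.0 * np.exp(-0.5 * t)
        fit = fit_lm(old, t)
        assert fit.delta == pytest.approx(0.5, abs=1e-12)
        assert fit.a0 == pytest.approx(10.0, rel=1e-12)
        assert fit.sigma == pytest.approx(5.0, rel=1e-10)

    def test_flat_old_rna_gives_zero_delta(self):
        fit = fit_lm(np.full(4, 7.0), np.array([1.0, 2.0, 4.0, 8.0]))
        assert fit.delta == pytest.approx(0.0, abs=1e-12)

    def test_zero_old_value_excluded(self):
        t = np.array([1.0, 2.0, 4.0, 8.0])
        old = 10.0 * np.exp(-0.5 * t)
        old[3] = 0.0
        fit = fit_lm(old, t)
        assert fit.converged
        assert fit.delta == pytest.approx(0.5, abs=1e-10)

    def test_single_point_not_converged(self):
        assert not fit_lm(np.array([5.0]), np.array([2.0])).converged


class TestNLLS:
    def test_noise_free_steady_state_recovery(self):
        sigma, delta = 100.0, LN2
        t = np.array([1.0, 2.0, 4.0])
        new = sigma / delta * (1 - np.exp(-t * delta))
        old = sigma / delta * np.exp(-t * delta)
        fit = fit_nlls(new, old, t, steady=True)
        assert fit.sigma == pytest.approx(sigma, rel=1e-6)
        assert fit.delta == pytest.approx(delta, rel=1e-6)
        assert np.max(np.abs(fit.residuals)) < 1e-6

    def test_noise_free_non_steady_recovery(self):
        sigma, delta = 30.0, 0.4
        a0 = 2 * sigma / delta
        t = np.array([0.5, 1.0, 2.0, 4.0, 8.0])
        new = sigma / delta * (1 - np.exp(-t * delta))
        old = a0 * np.exp(-t * delta)
        fit = fit_nlls(new, old, t, steady=False)
        assert fit.sigma == pytest.approx(sigma, rel=1e-6)
        assert fit.delta == pytest.approx(delta, rel=1e-6)
        assert fit.a0 == pytest.approx(a0, rel=1e-6)

    def test_steady_assumption_biases_non_steady_data(self):
        sigma, delta = 30.0, 0.4
        a0 = 2 * sigma / delta
        t = np.array([0.5, 1.0, 2.0, 4.0, 8.0])
        new = sigma / delta * (1 - np.exp(-t * delta))
        old = a0 * np.exp(-t * delta)
        fit = fit_nlls(new, old, t, steady=True)
        assert abs(fit.delta - delta) / delta > 0.05  # misspecified model

    def test_too_few_samples_not_converged(self):
        assert not fit_nlls(np.array([1.0]), np.array([1.0]),
                            np.array([1.0])).converged


class TestNtrBayes:
    def test_transformed_map_closed_form(self):
        # alpha=3, beta=2, t=2: -(1/2) log(1/3) = log(3)/2
        d_map, d_trans = ntr_point_estimates(3.0, 2.0, 2.0)
        assert d_trans == pytest.approx(math.log(3) / 2, abs=1e-12)
        assert d_trans == pytest.approx(0.5493, abs=1e-4)

    def test_delta_map_closed_form(self):
        d_map, _ = ntr_point_estimates(3.0, 2.0, 2.0)
        assert d_map == pytest.approx(-0.5 * math.log(2.0 / 4.0), abs=1e-12)
        assert d_map == pytest.approx(0.3466, abs=1e-4)

    def test_chi2_drop_at_95_percent(self):
        from scipy.stats import chi2
        assert 0.5 * chi2.ppf(0.95, 1) == pytest.approx(1.9207, abs=1e-4)

    @settings(derandomize=True, max_examples=30)
    @given(alpha=st.floats(1.5, 400.0), beta=st.floats(1.5, 400.0),
           t=st.floats(0.25, 12.0))
    def test_single_sample_numeric_max_equals_closed_form(self, alpha, beta, t):
        # root of dg/d(delta) located numerically must equal the closed form
        _, d_trans = ntr_point_estimates(alpha, beta, t)
        grad = lambda d: ((alpha - 1) * t * math.exp(-t * d)
                          / -math.expm1(-t * d) - t * (beta - 1))
        root = optimize.brentq(grad, d_trans / 100, d_trans * 100,
                               xtol=1e-16, rtol=1e-14)
        assert root == pytest.approx(d_trans, rel=1e-8)

    def test_fit_matches_closed_form_and_sigma(self):
        fit = fit_ntr_bayes(np.array([3.0]), np.array([2.0]),
                            np.array([120.0]), np.array([2.0]))
        assert fit.delta == pytest.approx(math.log(3) / 2, rel=1e-6)
        assert fit.sigma == pytest.approx(120.0 * fit.delta, rel=1e-9)
        lo, hi = fit.ci["delta"]
        assert lo < fit.delta < hi

    def test_flat_posterior_flagged(self):
        fit = fit_ntr_bayes(np.array([1.0]), np.array([1.0]),
                            np.array([10.0]), np.array([2.0]))
        assert not fit.converged
        assert fit.extra.get("flat")


class TestPulser:
    def test_noise_free_self_consistency(self):
        sigma, delta, disp = 400.0, 0.5, 0.05
        t = np.array([1.0, 2.0, 4.0, 8.0])
        a0 = sigma / delta
        unlab = np.round(a0 * np.exp(-t * delta))
        lab = np.round(sigma / delta * (1 - np.exp(-t * delta)))
        fit = fit_pulser(unlab, lab, t, steady=True)
        assert fit.converged
        assert fit.delta == pytest.approx(delta, rel=0.05)
        assert fit.sigma == pytest.approx(sigma, rel=0.05)
        assert fit.extra["mu1"] < 5.0 and fit.extra["mu2"] < 5.0

    def test_all_zero_labeled_degenerate(self):
        t = np.array([1.0, 2.0, 4.0, 8.0])
        fit = fit_pulser(np.array([100, 90, 80, 70]), np.zeros(4), t)
        assert not fit.converged


class TestDispatch:
    def test_unknown_method_lists_options(self, tiny_experiment):
        with pytest.raises(ValueError, match="nlls"):
            fit_kinetics(tiny_experiment, method="bogus")

    def test_no4su_sample_counts_as_pure_old_rna(self):
        # one no4sU sample at t=0 plus two labeled: LM on old RNA sees t=0
        designs = [
            sk.SampleDesign("a.no4sU.A", is_no4sU=True),
            sk.SampleDesign("a.2h.A", labeling_time_nominal=2.0),
            sk.SampleDesign("a.4h.A", labeling_time_nominal=4.0),
        ]
        delta = 0.3
        total = 50.0
        old = total * np.exp(-delta * np.array([0.0, 2.0, 4.0]))
        ntr = np.array([[np.nan, 1 - old[1] / total, 1 - old[2] / total]])
        counts = np.array([[old[0], total, total]])
        # keep totals equal so size factors stay 1
        data = sk.ExperimentData(["g"], designs,
                                 {"count": counts, "ntr": ntr})
        data.slots["count"][0, 0] = old[0]
        fits = fit_kinetics(data, method="lm")
        assert fits[0].delta == pytest.approx(delta, rel=1e-6)

    def test_dispatch_runs_per_gene(self, steady_course):
        _, data, truth = steady_course
        sub = data.subset_genes(np.arange(10))
        fits = fit_kinetics(sub, method="nlls")
        assert len(fits) == 10
        assert all(f.converged for f in fits)
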