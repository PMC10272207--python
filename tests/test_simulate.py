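import numpy as np
import pytest

import slamkin as sk
from slamkin.simulate import (SaturatingRate, SimProfile, beta_from_moments,
                              perturb_rates, rate_noise_sd, sample_halflives,
                              simulate_reads_for_sample, simulate_time_course,
                              simulate_time_course_nonconstant)


class TestRateNoise:
    def test_sd_for_v_1_05(self):
        assert rate_noise_sd(1.05) == pytest.approx(0.04280, abs=2e-5)

    def test_v_one_means_exact_rates(self):
        kin = sk.GeneKinetics(sigma=np.array([3.0]), delta=np.array([0.5]))
        truth = simulate_time_course(kin, 2.0, 1.0, 1.0,
                                     np.random.default_rng(0))
        assert truth.sigma_real == pytest.approx([3.0])
        assert truth.delta_real == pytest.approx([0.5])


class TestTimeCourse:
    def test_steady_state_conservation(self):
        kin = sk.GeneKinetics(sigma=np.array([10.0, 2.0]),
                              delta=np.array([0.2, 1.5]))
        for t in (0.5, 2.0, 8.0):
            truth = simulate_time_course(kin, t, 1.0, 1.0, None)
            assert np.allclose(truth.a_new + truth.a_old, kin.steady_state)

    def test_ntr_identity(self):
        rng = np.random.default_rng(3)
        kin = sk.sample_gene_kinetics(50, rng)
        truth = simulate_time_course(kin, 2.0, 1.05, 1.05, rng)
        assert np.allclose(
            truth.ntr, truth.a_new / (truth.a_new + truth.a_old), atol=1e-12)

    def test_negative_time_rejected(self):
        kin = sk.GeneKinetics(sigma=np.array([1.0]), delta=np.array([1.0]))
        with pytest.raises(ValueError):
            simulate_time_course(kin, -1.0, 1.0, 1.0, None)


class TestNonConstantRates:
    def test_constant_limit_matches_closed_form(self):
        sigma = np.array([5.0, 1.0])
        delta = np.array([0.3, 1.2])
        a0 = np.array([4.0, 2.0])
        fns = [SaturatingRate(s, 1.0) for s in sigma]  # c=1: no change
        a_new, a_old = simulate_time_course_nonconstant(
            fns, None, 2.0, a0, delta=delta)
        expect_new = sigma / delta * (1 - np.exp(-2.0 * delta))
        expect_old = a0 * np.exp(-2.0 * delta)
        assert np.allclose(a_new, expect_new, rtol=1e-6)
        assert np.allclose(a_old, expect_old, rtol=1e-6)

    def test_saturation_half_way_after_30_minutes(self):
        # exponent 1 - exp(-0.5 * 1.39) = 0.5009: half-way in log space
        r = SaturatingRate(1.0, 4.0, 1.39)
        assert np.log(r(0.5)) / np.log(4.0) == pytest.approx(0.5009, abs=1e-4)

    def test_fast_degradation_clears_old_rna(self):
        fns = [SaturatingRate(50.0, 1.0)]
        a_new, a_old = simulate_time_course_nonconstant(
            None, fns, 2.0, np.array([10.0]), sigma=np.array([1.0]))
        assert a_old[0] < 1e-10


class TestPerturbRates:
    def test_sd_for_five_percent_over_twofold(self):
        rng = np.random.default_rng(0)
        rates = np.ones(200_000)
        _, eta = perturb_rates(rates, rng, 0.05)
        assert np.std(eta) == pytest.approx(0.5102, abs=0.01)
        assert np.mean(np.abs(eta) > 1.0) == pytest.approx(0.05, abs=0.005)

    def test_noise_shrinks_as_fraction_vanishes(self):
        rng = np.random.default_rng(1)
        sds = []
        for frac in (0.3, 0.05, 1e-3, 1e-8):
            _, eta = perturb_rates(np.ones(50_000), rng, frac)
            sds.append(np.std(eta))
        assert np.all(np.diff(sds) < 0)
        assert sds[-1] < 0.2


class TestReadSimulation:
    def _profile(self, n, **kw):
        rel = np.full(n, 1.0 / n)
        return SimProfile(rel_abundance=rel, **kw)

    def test_zero_dispersion_counts_are_poisson(self):
        rng = np.random.default_rng(9)
        profile = self._profile(4000, dispersion=0.0, total_reads=400_000)
        counts, _, _ = simulate_reads_for_sample(
            profile, np.zeros(4000), rng, estimate=False)
        ratio = np.var(counts) / np.mean(counts)
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_background_only_conversion_rate(self):
        rng = np.random.default_rng(10)
        profile = self._profile(50, total_reads=20_000)
        _, stats_list, _ = simulate_reads_for_sample(
            profile, np.zeros(50), rng, estimate=False)
        conv = sum(float(np.sum(rs.tc * rs.mult)) for rs in stats_list)
        urid = sum(float(np.sum(rs.u * rs.mult)) for rs in stats_list)
        assert conv / urid == pytest.approx(1e-4, rel=0.5)

    def test_perfect_separation_recovers_ntr(self):
        rng = np.random.default_rng(11)
        profile = self._profile(
            5, total_reads=50_000, mixture=sk.MixtureParams(0.0, 1.0))
        ntrs = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        _, stats_list, posts = simulate_reads_for_sample(profile, ntrs, rng)
        for rs, p, truth in zip(stats_list, posts, ntrs):
            conv = rs.mult[rs.tc == rs.u].sum()  # tc = u whenever u > 0
            assert np.all((rs.tc == 0) | (rs.tc == rs.u))
            assert p.map == pytest.approx(truth, abs=0.02)

    def test_seeded_runs_are_bit_reproducible(self):
        profile = self._profile(20, total_reads=2000)
        ntrs = np.linspace(0.05, 0.9, 20)
        out1 = simulate_reads_for_sample(profile, ntrs,
                                         np.random.default_rng(123))
        out2 = simulate_reads_for_sample(profile, ntrs,
                                         np.random.default_rng(123))
        assert np.array_equal(out1[0], out2[0])
        assert all(np.array_equal(a.tc, b.tc) and np.array_equal(a.mult, b.mult)
                   for a, b in zip(out1[1], out2[1]))

    def test_infeasible_uridine_beta_rejected(self):
        with pytest.raises(ValueError, match="[Ii]nfeasible"):
            beta_from_moments(0.25, 0.5)


class TestGenePopulation:
    def test_halflife_class_proportions(self):
        rng = np.random.default_rng(4)
        hl = sample_halflives(50_000, rng)
        frac_0_1 = np.mean((hl >= 0) & (hl < 1))
        frac_gt8 = np.mean(hl >= 8)
        assert frac_0_1 == pytest.approx(204 / 10835, abs=0.005)
        assert frac_gt8 == pytest.approx(3096 / 10835, abs=0.01)
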