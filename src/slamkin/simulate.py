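"""In-silico nucleotide-conversion RNA-seq experiments with ground truth.

The generator produces everything a real experiment would: negative-binomial
read counts per gene, per-read (uridine, conversion) sufficient statistics
drawn from the binomial mixture at each gene's true NTR, and the NTR
posterior estimated back from those statistics.  Higher-level drivers compute
true NTRs and abundances from first-order kinetics (constant rates, with
per-sample biological rate variability) or by numerically integrating the
kinetics under smoothly time-varying rates, and can perturb rates between
conditions.

Units: rates in 1/h (delta) and abundance/h (sigma), times in hours,
abundances in arbitrary expression units (interpretable as expected
normalized read counts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import integrate, stats

from .datamodel import GeneKinetics
from .ntrquant import MixtureParams, NtrPosterior, ReadStats, estimate_ntr

__all__ = [
    "SimProfile",
    "SimTruth",
    "SaturatingRate",
    "beta_from_moments",
    "sample_halflives",
    "sample_gene_kinetics",
    "simulate_reads_for_sample",
    "simulate_time_course",
    "simulate_time_course_nonconstant",
    "perturb_rates",
    "rate_noise_sd",
]

#: one-sided 95% standard normal quantile used to scale biological rate noise
_Z95 = stats.norm.ppf(0.95)

#: half-life classes (hours) with gene counts as used for the reference
#: half-life distribution of the simulation benchmark (total 10,835)
HALFLIFE_CLASSES: tuple[tuple[float, float, int], ...] = (
    (0.25, 1.0, 204),
    (1.0, 2.0, 1417),
    (2.0, 4.0, 2996),
    (4.0, 8.0, 3122),
    (8.0, 48.0, 3096),
)


def beta_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Beta shape parameters matching a given mean and standard deviation."""
    var = sd * sd
    bound = mean * (1.0 - mean)
    if not 0 < mean < 1:
        raise ValueError("mean must lie in (0, 1)")
    if var <= 0 or var >= bound:
        raise ValueError(
            f"infeasible Beta moments: need 0 < sd^2 < mean*(1-mean) = {bound:.4g}"
        )
    nu = bound / var - 1.0
    return mean * nu, (1.0 - mean) * nu


@dataclass
class SimProfile:
    """Per-sample read simulation settings.

    ``rel_abundance`` are simplex weights (sum 1); expected counts are
    ``rel_abundance * total_reads``, drawn from negative binomials with the
    mean/dispersion parameterization (variance mu + d*mu^2).  Per read, the
    uridine count is Binom(read_len, p_u) with p_u drawn from a Beta
    moment-matched to (u_content_mean, u_content_sd); conversions come from
    the binomial mixture at the gene's NTR.
    """

    rel_abundance: np.ndarray
    dispersion: np.ndarray | float = 0.05
    total_reads: int | None = None
    read_len: int = 75
    u_content_mean: float = 0.25
    u_content_sd: float = 0.05
    mixture: MixtureParams = field(default_factory=MixtureParams)

    def __post_init__(self) -> None:
        self.rel_abundance = np.asarray(self.rel_abundance, dtype=float)
        if abs(float(self.rel_abundance.sum()) - 1.0) > 1e-9:
            raise ValueError("relative abundances must sum to 1")
        n = len(self.rel_abundance)
        self.dispersion = np.broadcast_to(
            np.asarray(self.dispersion, dtype=float), (n,)
        ).copy()
        if np.any(self.dispersion < 0):
            raise ValueError("dispersions must be >= 0")
        if self.total_reads is None:
            # default mean coverage ~200 reads per gene
            self.total_reads = 200 * n
        # validates feasibility of the uridine-content Beta
        self.u_beta = beta_from_moments(self.u_content_mean, self.u_content_sd)

    @property
    def n_genes(self) -> int:
        return len(self.rel_abundance)


@dataclass
class SimTruth:
    """Ground truth of one simulated sample.

    ``sigma``/``delta`` are the base rates, ``sigma_real``/``delta_real`` the
    realized per-sample rates after biological variability, ``a_new``/``a_old``
    the abundances of new and old RNA at the labeling time and ``ntr`` the
    true new-to-total ratio.
    """

    time: float
    sigma: np.ndarray
    delta: np.ndarray
    a0: np.ndarray
    sigma_real: np.ndarray
    delta_real: np.ndarray
    a_new: np.ndarray
    a_old: np.ndarray

    @property
    def abundance(self) -> np.ndarray:
        return self.a_new + self.a_old

    @property
    def ntr(self) -> np.ndarray:
        total = self.abundance
        out = np.zeros_like(total)
        pos = total > 0
        out[pos] = self.a_new[pos] / total[pos]
        return out


@dataclass(frozen=True)
class SaturatingRate:
    """Smoothly saturating rate change rate(t) = s * c^(1 - exp(-t*d)).

    Starts at ``s`` and approaches ``s*c`` with speed ``d`` (1/h); the default
    d = 1.39 puts the rate half-way (in log space) to the perturbed state
    after 30 min.
    """

    s: float
    c: float
    d: float = 1.39

    def __call__(self, t) -> np.ndarray | float:
        return self.s * self.c ** (1.0 - np.exp(-np.asarray(t, dtype=float) * self.d))


def rate_noise_sd(v: float) -> float:
    """Standard deviation of log2 rate noise for a fold-variability v >= 1.

    Chosen such that the one-sided 95% quantile of the gaussian equals
    log2(v): 90% of realized rates lie within v-fold of the base rate.
    """
    if v < 1:
        raise ValueError("fold variability must be >= 1")
    return math.log2(v) / _Z95


def sample_halflives(
    n_genes: int,
    rng: np.random.Generator,
    classes: Sequence[tuple[float, float, int]] = HALFLIFE_CLASSES,
) -> np.ndarray:
    """Half-lives (hours) drawn log-uniformly within weighted classes.

    Class proportions follow the reference benchmark distribution; within a
    class, half-lives are log-uniform.
    """
    weights = np.array([c[2] for c in classes], dtype=float)
    weights /= weights.sum()
    which = rng.choice(len(classes), size=n_genes, p=weights)
    lo = np.array([c[0] for c in classes])[which]
    hi = np.array([c[1] for c in classes])[which]
    return np.exp(rng.uniform(np.log(lo), np.log(hi)))


def sample_gene_kinetics(
    n_genes: int,
    rng: np.random.Generator,
    abundance_log_sd: float = 1.0,
) -> GeneKinetics:
    """Steady-state gene kinetics for a benchmark population.

    Half-lives follow the weighted class distribution; steady-state abundances
    are log-normal (log-mean 0, log-sd ``abundance_log_sd``) in arbitrary
    units, and sigma = abundance * delta.
    """
    halflife = sample_halflives(n_genes, rng)
    delta = math.log(2) / halflife
    abundance = rng.lognormal(mean=0.0, sigma=abundance_log_sd, size=n_genes)
    sigma = abundance * delta
    return GeneKinetics(sigma=sigma, delta=delta, a0=abundance)


def _negbinom_counts(
    mean: np.ndarray, dispersion: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Counts with variance mu + d*mu^2 (Poisson when d = 0)."""
    counts = np.empty(len(mean), dtype=np.int64)
    pois = dispersion <= 0
    counts[pois] = rng.poisson(mean[pois])
    if np.any(~pois):
        r = 1.0 / dispersion[~pois]
        p = r / (r + mean[~pois])
        counts[~pois] = rng.negative_binomial(r, p)
    return counts


def _simulate_conversions(
    c: int,
    ntr: float,
    profile: SimProfile,
    rng: np.random.Generator,
) -> ReadStats:
    """Sufficient statistics (u, tc) for c reads of one gene."""
    a_u, b_u = profile.u_beta
    p_u = rng.beta(a_u, b_u, size=c)
    u = rng.binomial(profile.read_len, p_u)
    new = rng.random(c) < ntr
    p = np.where(new, profile.mixture.p_c, profile.mixture.p_e)
    tc = rng.binomial(u, p)
    return ReadStats.from_reads(u, tc)


def simulate_reads_for_sample(
    profile: SimProfile,
    ntrs: np.ndarray,
    rng: np.random.Generator,
    estimate: bool = True,
    max_reads_per_gene: int | None = None,
) -> tuple[np.ndarray, list[ReadStats], list[NtrPosterior] | None]:
    """Simulate one sequencing sample: counts, read statistics, NTR posteriors.

    Per-gene counts are negative binomial; per-read sufficient statistics are
    drawn from the binomial mixture at the gene's true NTR, and (optionally)
    the NTR posterior is estimated back from them with the true mixture
    parameters.  ``max_reads_per_gene`` caps the number of reads carrying
    conversion statistics (counts are unaffected) for scaled-down runs.
    """
    ntrs = np.asarray(ntrs, dtype=float)
    if ntrs.shape != (profile.n_genes,):
        raise ValueError("one NTR per gene required")
    if np.any((ntrs < 0) | (ntrs > 1)):
        raise ValueError("NTRs must lie in [0, 1]")
    mean = profile.rel_abundance * profile.total_reads
    counts = _negbinom_counts(mean, profile.dispersion, rng)
    stats_list: list[ReadStats] = []
    posteriors: list[NtrPosterior] | None = [] if estimate else None
    for i in range(profile.n_genes):
        c = int(counts[i])
        if max_reads_per_gene is not None:
            c = min(c, max_reads_per_gene)
        rs = _simulate_conversions(c, float(ntrs[i]), profile, rng)
        stats_list.append(rs)
        if estimate:
            if rs.n_reads == 0:
                posteriors.append(NtrPosterior(float("nan"), 1.0, 1.0, flat=True))
            else:
                posteriors.append(estimate_ntr(rs, profile.mixture))
    return counts.astype(float), stats_list, posteriors


def simulate_time_course(
    kinetics: GeneKinetics,
    t: float,
    v_sigma: float = 1.05,
    v_delta: float = 1.05,
    rng: np.random.Generator | None = None,
) -> SimTruth:
    """Abundances and true NTRs after labeling for t hours at constant rates.

    Biological variability multiplies each gene's rates by 2^eps with
    eps ~ Normal(0, log2(v)/z_0.95), realized independently per sample; the
    new and old RNA abundances follow first-order kinetics at the realized
    rates, with ntr = a_new / (a_new + a_old).
    """
    if t < 0:
        raise ValueError("labeling time must be >= 0")
    sigma = np.atleast_1d(np.asarray(kinetics.sigma, dtype=float))
    delta = np.atleast_1d(np.asarray(kinetics.delta, dtype=float))
    a0 = np.atleast_1d(np.asarray(kinetics.a0, dtype=float))
    n = len(sigma)
    if rng is None or (v_sigma == 1.0 and v_delta == 1.0):
        eps_s = np.zeros(n)
        eps_d = np.zeros(n)
    else:
        eps_s = rng.normal(0.0, rate_noise_sd(v_sigma), size=n)
        eps_d = rng.normal(0.0, rate_noise_sd(v_delta), size=n)
    sig = sigma * np.exp2(eps_s)
    del_ = delta * np.exp2(eps_d)
    a_new = sig / del_ * -np.expm1(-t * del_)
    a_old = a0 * np.exp(-t * del_)
    return SimTruth(
        time=t, sigma=sigma, delta=delta, a0=a0,
        sigma_real=sig, delta_real=del_, a_new=a_new, a_old=a_old,
    )


def simulate_time_course_nonconstant(
    sigma_fn: Sequence[SaturatingRate] | None,
    delta_fn: Sequence[SaturatingRate] | None,
    t: float,
    a0: np.ndarray,
    sigma: np.ndarray | None = None,
    delta: np.ndarray | None = None,
    rtol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """New and old RNA after labeling under time-varying rates.

    Integrates da/dt = sigma(t) - delta(t) * a numerically for old RNA
    (synthesis off, start a0) and new RNA (start 0).  Either rate may be a
    sequence of :class:`SaturatingRate` (one per gene); a constant rate is
    supplied through ``sigma``/``delta`` instead.  Returns (a_new, a_old).
    """
    if t <= 0:
        raise ValueError("labeling time must be > 0")
    a0 = np.asarray(a0, dtype=float)
    n = len(a0)

    def rate(fns, const, tt):
        if fns is not None:
            return np.array([f(tt) for f in fns])
        return np.broadcast_to(np.asarray(const, dtype=float), (n,))

    def rhs(tt, y):
        a_new = y[:n]
        a_old = y[n:]
        s = rate(sigma_fn, sigma, tt)
        d = rate(delta_fn, delta, tt)
        return np.concatenate([s - d * a_new, -d * a_old])

    y0 = np.concatenate([np.zeros(n), a0])
    sol = integrate.solve_ivp(
        rhs, (0.0, t), y0, rtol=rtol, atol=1e-12, method="LSODA", t_eval=[t]
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    y = sol.y[:, -1]
    return y[:n], y[n:]


def perturb_rates(
    rates: np.ndarray,
    rng: np.random.Generator,
    expected_frac_over_2fold: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly perturb rates, returning (perturbed rates, true log2 FCs).

    Each rate is multiplied by 2^eta with eta ~ Normal(0, sd), sd chosen so
    that the expected fraction of genes perturbed by more than 2-fold
    (|eta| > 1) equals ``expected_frac_over_2fold``.
    """
    if not 0 < expected_frac_over_2fold < 1:
        raise ValueError("expected_frac_over_2fold must lie in (0, 1)")
    rates = np.asarray(rates, dtype=float)
    sd = 1.0 / stats.norm.ppf(1.0 - expected_frac_over_2fold / 2.0)
    eta = rng.normal(0.0, sd, size=rates.shape)
    return rates * np.exp2(eta), eta
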