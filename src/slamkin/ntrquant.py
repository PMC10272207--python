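"""Binomial-mixture inference of the new-to-total RNA ratio (NTR).

In nucleotide-conversion RNA-seq, a read from labeled (new) RNA covers some
number of uridines u, each of which shows a T-to-C mismatch with the
conversion probability p_c; a read from unlabeled (old) RNA shows mismatches
only through the error probability p_e.  The number of conversions on a read
therefore follows the two-component binomial mixture

    P(k; u, p_e, p_c, ntr) = (1-ntr) B(k; u, p_e) + ntr B(k; u, p_c)

whose mixture weight is the gene's NTR.  Given the per-read sufficient
statistics (u, tc) of a gene, this module computes the maximum-a-posteriori
NTR under a uniform prior and a Beta(alpha, beta) approximation of the
posterior by matching the mean and variance of the numerically normalized
posterior (quadrature on [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import optimize, stats

__all__ = ["MixtureParams", "ReadStats", "NtrPosterior", "binom_mix_pmf",
           "ntr_loglik", "estimate_ntr"]

#: lower bound used when maximizing the log likelihood on the open interval
_EPS = 1e-9


@dataclass(frozen=True)
class MixtureParams:
    """Global T-to-C mismatch probabilities: sequencing error and conversion."""

    p_e: float = 1e-4
    p_c: float = 0.04

    def __post_init__(self) -> None:
        if not (0 <= self.p_e < self.p_c <= 1):
            raise ValueError("require 0 <= p_e < p_c <= 1")


class ReadStats:
    """Per-gene sufficient statistics: multiset of (u, tc) pairs.

    Stored sparsely as (u, tc) -> multiplicity; ``u`` is the number of
    uridines covered by a read and ``tc`` the number of observed T-to-C
    conversions on it.
    """

    __slots__ = ("u", "tc", "mult")

    def __init__(self, pairs: Mapping[tuple[int, int], int] | None = None):
        pairs = pairs or {}
        u, tc, mult = [], [], []
        for (uu, cc), m in sorted(pairs.items()):
            if cc > uu:
                raise ValueError(f"conversions tc={cc} exceed uridines u={uu}")
            if uu < 0 or cc < 0 or m < 0:
                raise ValueError("u, tc and multiplicities must be >= 0")
            if m > 0:
                u.append(uu)
                tc.append(cc)
                mult.append(m)
        self.u = np.asarray(u, dtype=np.int64)
        self.tc = np.asarray(tc, dtype=np.int64)
        self.mult = np.asarray(mult, dtype=np.int64)

    @classmethod
    def from_reads(cls, u: Iterable[int], tc: Iterable[int]) -> "ReadStats":
        u = np.asarray(list(u), dtype=np.int64)
        tc = np.asarray(list(tc), dtype=np.int64)
        if u.shape != tc.shape:
            raise ValueError("u and tc must have equal length")
        if np.any(tc > u):
            raise ValueError("conversions exceed uridines for some read")
        keys = np.stack([u, tc], axis=1)
        uniq, counts = np.unique(keys, axis=0, return_counts=True)
        obj = cls.__new__(cls)
        obj.u = uniq[:, 0].copy()
        obj.tc = uniq[:, 1].copy()
        obj.mult = counts.astype(np.int64)
        return obj

    @property
    def n_reads(self) -> int:
        return int(self.mult.sum())

    def __len__(self) -> int:
        return len(self.u)

    def __add__(self, other: "ReadStats") -> "ReadStats":
        pairs: dict[tuple[int, int], int] = {}
        for s in (self, other):
            for uu, cc, m in zip(s.u, s.tc, s.mult):
                pairs[(int(uu), int(cc))] = pairs.get((int(uu), int(cc)), 0) + int(m)
        return ReadStats(pairs)


@dataclass
class NtrPosterior:
    """NTR MAP estimate with Beta(alpha, beta) posterior approximation.

    ``flat`` marks a degenerate case (no read covered a uridine), where the
    likelihood carries no information on the NTR and ``map`` is undefined
    (NaN); alpha = beta = 1 then reproduce the uniform prior.
    """

    map: float
    alpha: float
    beta: float
    flat: bool = False

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def variance(self) -> float:
        s = self.alpha + self.beta
        return self.alpha * self.beta / (s * s * (s + 1.0))


def binom_mix_pmf(k, u, params: MixtureParams, ntr) -> np.ndarray | float:
    """Probability of k conversions on a read with u uridines.

    Mixture of Binom(u, p_e) (old RNA, weight 1-ntr) and Binom(u, p_c)
    (new RNA, weight ntr).  Broadcasts over array arguments.
    """
    k = np.asarray(k)
    u = np.asarray(u)
    ntr_arr = np.asarray(ntr, dtype=float)
    if np.any(k > u) or np.any(k < 0):
        raise ValueError("require 0 <= k <= u")
    if np.any((ntr_arr < 0) | (ntr_arr > 1)):
        raise ValueError("ntr must lie in [0, 1]")
    p_old = stats.binom.pmf(k, u, params.p_e)
    p_new = stats.binom.pmf(k, u, params.p_c)
    out = (1.0 - ntr_arr) * p_old + ntr_arr * p_new
    if out.ndim == 0:
        return float(out)
    return out


def _component_pmfs(stats_: ReadStats, params: MixtureParams):
    p_old = stats.binom.pmf(stats_.tc, stats_.u, params.p_e)
    p_new = stats.binom.pmf(stats_.tc, stats_.u, params.p_c)
    return p_old, p_new


def ntr_loglik(stats_: ReadStats, params: MixtureParams, ntr) -> np.ndarray | float:
    """Binomial-mixture log likelihood of the NTR.

    Additive over reads; returns -inf (not an exception) where some read has
    zero mixture probability, e.g. tc > 0 with ntr = 0 and p_e = 0.
    Accepts a scalar or an array of NTR values.
    """
    if len(stats_) == 0:
        raise ValueError("empty ReadStats")
    p_old, p_new = _component_pmfs(stats_, params)
    ntr_arr = np.atleast_1d(np.asarray(ntr, dtype=float))
    mix = (1.0 - ntr_arr[:, None]) * p_old[None, :] + ntr_arr[:, None] * p_new[None, :]
    with np.errstate(divide="ignore"):
        ll = np.log(mix) @ stats_.mult.astype(float)
    if np.isscalar(ntr) or np.asarray(ntr).ndim == 0:
        return float(ll[0])
    return ll


def estimate_ntr(
    stats_: ReadStats,
    params: MixtureParams,
    grid_size: int = 512,
) -> NtrPosterior:
    """MAP estimate and Beta posterior approximation of the NTR.

    Under the uniform prior, the posterior is proportional to the likelihood;
    it is normalized by quadrature on a regular grid over [0, 1] (trapezoid
    rule, log-space evaluation with max subtraction for stability), and
    Beta(alpha, beta) is fitted to the posterior mean and variance.  The MAP
    is located by bounded scalar optimization on [eps, 1-eps], compared
    against the boundary values.
    """
    if len(stats_) == 0:
        raise ValueError("empty ReadStats")
    if np.all(stats_.u == 0):
        return NtrPosterior(map=float("nan"), alpha=1.0, beta=1.0, flat=True)

    grid = np.linspace(0.0, 1.0, grid_size)
    ll = ntr_loglik(stats_, params, grid)

    # posterior moments by quadrature (uniform prior)
    m = np.max(ll)
    w = np.exp(ll - m)
    norm = np.trapezoid(w, grid)
    mean = np.trapezoid(w * grid, grid) / norm
    var = np.trapezoid(w * grid * grid, grid) / norm - mean * mean

    # MAP: refine the best grid point by bounded optimization
    i = int(np.argmax(ll))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid_size - 1)]
    lo = max(lo, _EPS)
    hi = min(hi, 1.0 - _EPS)
    res = optimize.minimize_scalar(
        lambda x: -ntr_loglik(stats_, params, float(x)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    map_est = float(res.x)
    cand = [(float(-res.fun), map_est)]
    for b in (0.0, 1.0):
        lb = ntr_loglik(stats_, params, b)
        if np.isfinite(lb):
            cand.append((float(lb), b))
    map_est = max(cand)[1]

    # moment matching: Beta with the quadrature mean and variance
    bound = mean * (1.0 - mean)
    if var <= 0 or var >= bound:
        alpha, beta = 1.0, 1.0
    else:
        nu = bound / var - 1.0
        alpha = mean * nu
        beta = (1.0 - mean) * nu
    return NtrPosterior(map=map_est, alpha=float(alpha), beta=float(beta))
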