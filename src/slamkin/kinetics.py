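"""Per-gene RNA synthesis/degradation rate estimation from progressive labeling.

A progressive labeling experiment measures old RNA O_k = C_k (1 - NTR_k) and
new RNA N_k = C_k NTR_k at increasing labeling durations t_k.  Under
first-order kinetics the expectations are a0 exp(-t delta) and
(sigma/delta)(1 - exp(-t delta)); four estimation strategies differing only
in their error model are provided:

* ``fit_lm`` -- ordinary least squares on log old RNA (homoscedastic
  log-normal errors).
* ``fit_nlls`` -- nonlinear least squares on old and new RNA jointly
  (homoscedastic gaussian errors); the recommended default.
* ``fit_ntr_bayes`` -- Bayesian estimate using the Beta posterior of the NTR
  directly; assumes steady state, where delta = -log(1 - ntr)/t.
* ``fit_pulser`` -- negative-binomial likelihood on counts of reads with and
  without observed conversions, with nuisance means for conversion leakage in
  either direction.

``fit_kinetics`` dispatches one of these per gene over an ExperimentData.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .datamodel import ExperimentData

__all__ = [
    "KineticFit",
    "DELTA_BOUNDS",
    "fit_lm",
    "fit_nlls",
    "fit_ntr_bayes",
    "fit_pulser",
    "fit_kinetics",
    "ntr_point_estimates",
    "ntr_log_posterior",
]

#: search bounds for the degradation rate (1/h): half-lives from 36 s to 1 week
DELTA_BOUNDS = (math.log(2) / 168.0, math.log(2) / 0.01)

LN2 = math.log(2)


@dataclass
class KineticFit:
    """Fitted first-order kinetics of one gene."""

    method: str
    sigma: float = float("nan")
    delta: float = float("nan")
    a0: float = float("nan")
    ci: dict = field(default_factory=dict)  # param -> (lower, upper)
    residuals: np.ndarray | None = None
    converged: bool = False
    level: float = 0.95
    extra: dict = field(default_factory=dict)

    @property
    def halflife(self) -> float:
        return LN2 / self.delta

    def halflife_ci(self) -> tuple[float, float]:
        lo, hi = self.ci.get("delta", (float("nan"), float("nan")))
        return (LN2 / hi if hi > 0 else 0.0, LN2 / lo if lo > 0 else float("inf"))


def _usable(old: np.ndarray, times: np.ndarray) -> np.ndarray:
    return np.isfinite(old) & (old > 0) & np.isfinite(times)


def fit_lm(
    old: np.ndarray,
    times: np.ndarray,
    steady: bool = True,
    level: float = 0.95,
) -> KineticFit:
    """Log-linear regression of old RNA: log O = log a0 - delta * t.

    Samples with non-positive old RNA are dropped (log undefined); at least
    two distinct usable time points are required.  Confidence intervals come
    from standard regression interval theory; sigma = a0 * delta is reported
    under the steady-state assumption.
    """
    old = np.asarray(old, dtype=float)
    times = np.asarray(times, dtype=float)
    use = _usable(old, times)
    if np.sum(use) < 2 or len(np.unique(times[use])) < 2:
        return KineticFit(method="LM", converged=False, level=level)
    t = times[use]
    y = np.log(old[use])
    res = stats.linregress(t, y)
    delta = -res.slope
    a0 = math.exp(res.intercept)
    dof = len(t) - 2
    tq = stats.t.ppf(0.5 + level / 2.0, dof) if dof > 0 else float("inf")
    ci = {
        "delta": (-res.slope - tq * res.stderr, -res.slope + tq * res.stderr),
        "a0": (
            math.exp(res.intercept - tq * res.intercept_stderr),
            math.exp(res.intercept + tq * res.intercept_stderr),
        ),
    }
    fit = KineticFit(
        method="LM",
        delta=delta,
        a0=a0,
        ci=ci,
        residuals=y - (res.intercept + res.slope * t),
        converged=True,
        level=level,
    )
    if steady:
        fit.sigma = a0 * delta
    return fit


def _nlls_model(params: np.ndarray, times: np.ndarray, steady: bool):
    """Expected (new, old) at each time for log-scale parameters."""
    sigma, delta = np.exp(params[0]), np.exp(params[1])
    a0 = sigma / delta if steady else np.exp(params[2])
    e = np.exp(-times * delta)
    return sigma / delta * (1.0 - e), a0 * e


def fit_nlls(
    new: np.ndarray,
    old: np.ndarray,
    times: np.ndarray,
    steady: bool = True,
    level: float = 0.95,
) -> KineticFit:
    """Nonlinear least squares on new and old RNA jointly.

    Minimizes the summed squared deviations of new and old RNA from their
    kinetic expectations (Levenberg-Marquardt on log-scale parameters, which
    keeps rates positive).  Starting values come from the log-linear fit;
    on failure, restarts over a coarse grid of degradation rates.  Confidence
    intervals use the linearized covariance at the optimum (homoscedastic
    gaussian errors).
    """
    new = np.asarray(new, dtype=float)
    old = np.asarray(old, dtype=float)
    times = np.asarray(times, dtype=float)
    use = np.isfinite(new) & np.isfinite(old) & np.isfinite(times)
    n_par = 2 if steady else 3
    if np.sum(use) < n_par:
        return KineticFit(method="NLLS", converged=False, level=level)
    t, nn, oo = times[use], new[use], old[use]

    def residuals(params):
        m_new, m_old = _nlls_model(params, t, steady)
        return np.concatenate([nn - m_new, oo - m_old])

    # starting values: LM estimates for delta/a0, sigma from new RNA
    lm = fit_lm(oo, t, steady=False, level=level)
    starts = []
    if lm.converged and DELTA_BOUNDS[0] < lm.delta < DELTA_BOUNDS[1]:
        d0, a00 = lm.delta, lm.a0
    else:
        d0, a00 = LN2, max(np.mean(oo), 1e-6)
    pos = t > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        s_guess = nn[pos] * d0 / (1.0 - np.exp(-t[pos] * d0))
    s0 = float(np.nanmean(s_guess)) if np.any(pos) else a00 * d0
    if not np.isfinite(s0) or s0 <= 0:
        s0 = a00 * d0
    starts.append((s0, d0, a00))
    for d_alt in (0.05, LN2, 2.0):
        starts.append((max(np.mean(nn), 1e-6) * d_alt + 1e-12, d_alt,
                       max(np.mean(oo), 1e-6)))

    best = None
    for s0, d0, a00 in starts:
        p0 = np.log([s0, d0] if steady else [s0, d0, a00])
        try:
            sol = optimize.least_squares(residuals, p0, method="lm", xtol=1e-12,
                                         ftol=1e-12, max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.success and best is sol:
            break
    if best is None or not np.all(np.isfinite(best.x)):
        return KineticFit(method="NLLS", converged=False, level=level)

    sigma, delta = float(np.exp(best.x[0])), float(np.exp(best.x[1]))
    a0 = sigma / delta if steady else float(np.exp(best.x[2]))

    # linearized covariance of the log-scale parameters
    dof = 2 * len(t) - n_par
    ci: dict = {}
    if dof > 0:
        s2 = 2.0 * best.cost / dof
        try:
            cov = s2 * np.linalg.inv(best.jac.T @ best.jac)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
            tq = stats.t.ppf(0.5 + level / 2.0, dof)
            names = ["sigma", "delta"] + ([] if steady else ["a0"])
            for i, name in enumerate(names):
                center = best.x[i]
                ci[name] = (math.exp(center - tq * se[i]),
                            math.exp(center + tq * se[i]))
        except np.linalg.LinAlgError:
            pass
    return KineticFit(
        method="NLLS", sigma=sigma, delta=delta, a0=a0, ci=ci,
        residuals=residuals(best.x), converged=True, level=level,
    )


def ntr_point_estimates(alpha: float, beta: float, t: float) -> tuple[float, float]:
    """Single-sample degradation-rate point estimates from a Beta NTR posterior.

    Returns ``(delta_map, delta_transformed)``: the mode of the transformed
    density on delta, and the transformed mode of the NTR posterior
    (-log(1 - ntr_map)/t).  The two differ because the MAP is not invariant
    under the change of variables; the transformed estimator is the default
    used throughout.
    """
    if t <= 0:
        raise ValueError("labeling time must be > 0")
    delta_map = -math.log(beta / (alpha + beta - 1.0)) / t
    delta_trans = -math.log((beta - 1.0) / (alpha + beta - 2.0)) / t
    return delta_map, delta_trans


def ntr_log_posterior(
    delta: np.ndarray | float,
    alphas: np.ndarray,
    betas: np.ndarray,
    times: np.ndarray,
) -> np.ndarray | float:
    """Log posterior g(delta) of the steady-state NTR model (up to a constant).

    g(delta) = sum_k (alpha_k - 1) log(1 - exp(-t_k delta))
               - t_k (beta_k - 1) delta
    """
    d = np.atleast_1d(np.asarray(delta, dtype=float))[:, None]
    with np.errstate(divide="ignore"):
        terms = (alphas - 1.0) * np.log(-np.expm1(-times * d)) \
            - times * (betas - 1.0) * d
    out = np.sum(terms, axis=1)
    if np.isscalar(delta) or np.asarray(delta).ndim == 0:
        return float(out[0])
    return out


def _exact_ci(
    grid: np.ndarray, dens: np.ndarray, i_map: int, level: float,
    equal_tailed: bool = False,
) -> tuple[float, float]:
    """Credible interval from a tabulated density.

    Default: outward mass accumulation from the MAP, extending at each step
    the side with the higher density until the target mass is enclosed.
    """
    w = np.empty_like(grid)
    w[1:-1] = 0.5 * (grid[2:] - grid[:-2])
    w[0] = 0.5 * (grid[1] - grid[0])
    w[-1] = 0.5 * (grid[-1] - grid[-2])
    mass = dens * w
    mass /= mass.sum()
    if equal_tailed:
        cum = np.cumsum(mass)
        lo = grid[np.searchsorted(cum, (1.0 - level) / 2.0)]
        hi = grid[min(np.searchsorted(cum, 1.0 - (1.0 - level) / 2.0),
                      len(grid) - 1)]
        return float(lo), float(hi)
    i_lo = i_hi = i_map
    acc = mass[i_map]
    while acc < level and (i_lo > 0 or i_hi < len(grid) - 1):
        left = dens[i_lo - 1] if i_lo > 0 else -np.inf
        right = dens[i_hi + 1] if i_hi < len(grid) - 1 else -np.inf
        if left >= right:
            i_lo -= 1
            acc += mass[i_lo]
        else:
            i_hi += 1
            acc += mass[i_hi]
    return float(grid[i_lo]), float(grid[i_hi])


def fit_ntr_bayes(
    alphas: np.ndarray,
    betas: np.ndarray,
    counts: np.ndarray,
    times: np.ndarray,
    level: float = 0.95,
    exact_ci: bool = False,
    equal_tailed: bool = False,
) -> KineticFit:
    """Bayesian degradation-rate estimate from NTR Beta posteriors.

    Assumes steady state.  The posterior g(delta) pools all labeled samples;
    the point estimate maximizes g numerically (for a single sample this
    equals the transformed NTR MAP).  Approximate credible intervals use the
    likelihood-drop criterion c = chi2_1(level)/2; exact intervals integrate
    exp(g) numerically and accumulate mass outward from the MAP.
    sigma = mean(normalized count) * delta.
    """
    alphas = np.asarray(alphas, dtype=float)
    betas = np.asarray(betas, dtype=float)
    counts = np.asarray(counts, dtype=float)
    times = np.asarray(times, dtype=float)
    use = (np.isfinite(alphas) & np.isfinite(betas) & (times > 0)
           & (alphas > 0) & (betas > 0))
    if not np.any(use):
        return KineticFit(method="NTR", converged=False, level=level)
    a, b, t = alphas[use], betas[use], times[use]
    if np.all(a <= 1.0) and np.all(b <= 1.0):
        return KineticFit(method="NTR", converged=False, level=level,
                          extra={"flat": True})

    lo, hi = DELTA_BOUNDS
    res = optimize.minimize_scalar(
        lambda d: -ntr_log_posterior(d, a, b, t),
        bounds=(lo, hi), method="bounded", options={"xatol": 1e-12},
    )
    delta = float(res.x)
    g_max = -float(res.fun)

    # approximate CI: drop in log posterior of c = chi2_1(level)/2
    c = 0.5 * stats.chi2.ppf(level, df=1)

    def drop(d):
        return g_max - ntr_log_posterior(d, a, b, t) - c

    try:
        ci_lo = optimize.brentq(drop, lo, delta) if drop(lo) > 0 else lo
    except ValueError:
        ci_lo = lo
    try:
        ci_hi = optimize.brentq(drop, delta, hi) if drop(hi) > 0 else hi
    except ValueError:
        ci_hi = hi
    ci = {"delta": (float(ci_lo), float(ci_hi))}

    if exact_ci:
        grid = np.geomspace(lo, hi, 4001)
        g = ntr_log_posterior(grid, a, b, t)
        dens = np.exp(g - g_max)
        i_map = int(np.argmin(np.abs(grid - delta)))
        ci["delta_exact"] = _exact_ci(grid, dens, i_map, level,
                                      equal_tailed=equal_tailed)

    use_c = np.isfinite(counts) & use
    sigma = float(np.mean(counts[use_c])) * delta if np.any(use_c) else float("nan")
    return KineticFit(
        method="NTR", sigma=sigma, delta=delta, a0=sigma / delta, ci=ci,
        converged=True, level=level,
    )


def _nb_logpmf(k: np.ndarray, mu: np.ndarray, disp: float) -> np.ndarray:
    r = 1.0 / disp
    p = r / (r + mu)
    return stats.nbinom.logpmf(k, r, p)


def fit_pulser(
    unlabeled_reads: np.ndarray,
    labeled_reads: np.ndarray,
    times: np.ndarray,
    steady: bool = True,
    level: float = 0.95,
) -> KineticFit:
    """Negative-binomial fit on counts of reads with/without conversions.

    Models the unlabeled-looking mean as mu1 + a0 exp(-t delta) and the
    labeled-looking mean as mu2 + (sigma/delta)(1 - exp(-t delta)), where the
    nuisance means mu1 (conversion-free reads from new RNA) and mu2
    (conversion-carrying reads from old RNA, e.g. sequencing errors) absorb
    the leakage between the two read classes.  A gene-wise dispersion is
    profiled jointly; all parameters are log-parameterized.
    """
    unlab = np.round(np.asarray(unlabeled_reads, dtype=float))
    lab = np.round(np.asarray(labeled_reads, dtype=float))
    times = np.asarray(times, dtype=float)
    use = np.isfinite(unlab) & np.isfinite(lab) & np.isfinite(times)
    if np.sum(use) < 4:
        return KineticFit(method="PULSER", converged=False, level=level)
    if np.all(lab[use] == 0):
        return KineticFit(method="PULSER", converged=False, level=level,
                          extra={"degenerate": "all labeled counts zero"})
    t, uu, ll_ = times[use], unlab[use], lab[use]
    n_kin = 2 if steady else 3

    def unpack(p):
        sigma, delta = np.exp(p[0]), np.exp(p[1])
        a0 = sigma / delta if steady else np.exp(p[2])
        mu1, mu2, disp = np.exp(p[n_kin]), np.exp(p[n_kin + 1]), np.exp(p[n_kin + 2])
        return sigma, delta, a0, mu1, mu2, disp

    def nll(p):
        sigma, delta, a0, mu1, mu2, disp = unpack(p)
        e = np.exp(-t * delta)
        m_un = mu1 + a0 * e
        m_la = mu2 + sigma / delta * (1.0 - e)
        val = -(np.sum(_nb_logpmf(uu, m_un, disp))
                + np.sum(_nb_logpmf(ll_, m_la, disp)))
        return val if np.isfinite(val) else 1e12

    lm = fit_lm(uu, t, steady=False)
    if lm.converged and DELTA_BOUNDS[0] < lm.delta < DELTA_BOUNDS[1]:
        d0, a00 = lm.delta, max(lm.a0, 1.0)
    else:
        d0, a00 = LN2, max(float(np.mean(uu)), 1.0)
    bounds = [(-25, 25)] * n_kin + [(-14, 25), (-14, 25), (math.log(1e-5), math.log(10))]
    best = None
    for d_start in (d0, 0.05, LN2, 2.0):
        s_start = max(float(np.mean(ll_)), 1.0) * d_start
        p0 = [math.log(s_start), math.log(d_start)]
        if not steady:
            p0.append(math.log(a00))
        p0 += [0.0, 0.0, math.log(0.1)]
        try:
            sol = optimize.minimize(nll, p0, method="L-BFGS-B", bounds=bounds,
                                    options={"maxiter": 500})
        except Exception:
            continue
        if best is None or sol.fun < best.fun:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        return KineticFit(method="PULSER", converged=False, level=level)
    sigma, delta, a0, mu1, mu2, disp = unpack(best.x)
    return KineticFit(
        method="PULSER", sigma=float(sigma), delta=float(delta), a0=float(a0),
        converged=bool(best.success or best.fun < 1e11), level=level,
        extra={"mu1": float(mu1), "mu2": float(mu2), "dispersion": float(disp)},
    )


METHODS = ("lm", "nlls", "ntr", "pulser")


def fit_kinetics(
    data: ExperimentData,
    method: str = "nlls",
    steady: bool = True,
    level: float = 0.95,
    exact_ci: bool = False,
) -> list[KineticFit]:
    """Fit per-gene kinetics over an experiment with the chosen method.

    Old and new RNA are derived as O_k = C_k (1 - NTR_k), N_k = C_k NTR_k
    from normalized expression; 4sU-naive samples contribute pure old RNA at
    t = 0.  Per-gene failures yield unconverged fits, never exceptions.
    """
    method = method.lower()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose one of {METHODS}")
    times = data.labeling_times()
    expr = data.expression()
    no4su = np.array([s.is_no4sU for s in data.samples])
    ntr = data.slots.get("ntr")
    if ntr is None and method != "pulser":
        raise ValueError("experiment lacks an 'ntr' slot")

    fits: list[KineticFit] = []
    for i in range(data.n_genes):
        try:
            if method == "pulser":
                conv = data.slots.get("conv")
                if conv is None:
                    raise ValueError(
                        "pulser method requires a 'conv' slot with counts of "
                        "conversion-carrying reads"
                    )
                counts = data.slots["count"][i]
                fits.append(fit_pulser(counts - conv[i], conv[i], times,
                                       steady=steady, level=level))
                continue
            ntr_i = ntr[i].copy()
            ntr_i[no4su] = 0.0
            new = expr[i] * ntr_i
            old = expr[i] * (1.0 - ntr_i)
            if method == "lm":
                fits.append(fit_lm(old, times, steady=steady, level=level))
            elif method == "nlls":
                fits.append(fit_nlls(new, old, times, steady=steady, level=level))
            else:
                fits.append(fit_ntr_bayes(
                    data.slots["alpha"][i], data.slots["beta"][i], expr[i],
                    times, level=level, exact_ci=exact_ci,
                ))
        except Exception as err:  # per-gene failures are recorded, not fatal
            warnings.warn(f"gene {data.gene_ids[i]}: {err}", stacklevel=2)
            fits.append(KineticFit(method=method.upper(), converged=False,
                                   level=level, extra={"error": str(err)}))
    return fits
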