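"""Effective labeling time estimation ("temporal recalibration").

4sU must cross the cell membrane and pass the pyrimidine salvage pathway
before it is available for transcription, so the effective labeling time of a
sample -- a single global parameter shared by all genes -- can be shorter
than the nominal one, especially for short labeling.  Two recalibration
strategies are provided:

* ``recalibrate_joint`` (progressive designs): treat the per-sample labeling
  times as free parameters of a joint nonlinear least-squares fit over a
  stratified panel of well-expressed genes; identifiable only up to a time
  unit, fixed by anchoring the last time point at its nominal time.
* ``recalibrate_match_halflives`` (snapshot designs): choose the labeling
  time such that half-lives transformed from the sample's NTRs match a set
  of reference half-lives with median log fold change zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .datamodel import ExperimentData
from .kinetics import fit_nlls

__all__ = ["RecalibrationResult", "recalibrate_joint",
           "recalibrate_match_halflives"]

LN2 = math.log(2)

#: half-life strata (hours) used to select the recalibration gene panel
DEFAULT_CLASSES: tuple[tuple[float, float], ...] = (
    (0.0, 2.0), (2.0, 4.0), (6.0, 8.0), (8.0, float("inf")),
)


@dataclass
class RecalibrationResult:
    """Per-sample nominal and recalibrated labeling times."""

    sample_names: list[str]
    nominal: np.ndarray
    effective: np.ndarray
    fixed: np.ndarray  # True where the time was anchored, not estimated
    objective: float
    genes_used: list[str]
    converged: bool = True

    def apply(self, data: ExperimentData) -> ExperimentData:
        """Copy of the experiment with effective labeling times installed."""
        out = data.copy()
        for name, eff in zip(self.sample_names, self.effective):
            out.samples[out.sample_index(name)].labeling_time_effective = float(eff)
        return out


def _select_panel(
    data: ExperimentData,
    times: np.ndarray,
    classes,
    n_top: int,
    steady: bool,
) -> np.ndarray:
    """Indices of the top expressed genes stratified by rough half-life."""
    expr = data.expression()
    ntr = data.slots["ntr"]
    no4su = np.array([s.is_no4sU for s in data.samples])
    mean_expr = np.nanmean(expr, axis=1)
    halflives = np.full(data.n_genes, np.nan)
    for i in range(data.n_genes):
        ntr_i = np.where(no4su, 0.0, ntr[i])
        fit = fit_nlls(expr[i] * ntr_i, expr[i] * (1.0 - ntr_i), times,
                       steady=steady)
        if fit.converged:
            halflives[i] = fit.halflife
    selected: list[int] = []
    for lo, hi in classes:
        in_class = np.nonzero((halflives >= lo) & (halflives < hi))[0]
        if len(in_class) < 10:
            warnings.warn(
                f"half-life class [{lo}, {hi}) has only {len(in_class)} genes; "
                "skipped", stacklevel=3,
            )
            continue
        order = in_class[np.argsort(mean_expr[in_class])[::-1]]
        selected.extend(order[:n_top].tolist())
    if not selected:
        raise ValueError(
            "no half-life class provided at least 10 genes; cannot recalibrate"
        )
    return np.unique(selected)


def recalibrate_joint(
    data: ExperimentData,
    anchor: list[str] | None = None,
    steady: bool = True,
    n_top: int = 200,
    classes=DEFAULT_CLASSES,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> RecalibrationResult:
    """Jointly estimate effective labeling times from a progressive course.

    Alternates between (a) per-gene kinetic fits at the current labeling
    times and (b) per-sample scalar optimization of each free time against
    the pooled squared residuals, until the relative change of the pooled
    objective falls below ``tol``.  The anchor samples (default: all samples
    at the latest nominal time) keep their nominal times, which fixes the
    time unit of the model.
    """
    nominal = data.labeling_times(effective=False)
    labeled = np.array([not s.is_no4sU for s in data.samples])
    if len(np.unique(nominal[labeled])) < 3:
        raise ValueError("joint recalibration needs >= 3 distinct time points")
    if anchor is None:
        t_max = np.max(nominal[labeled])
        anchor = [s.name for s, t, lab in zip(data.samples, nominal, labeled)
                  if lab and t == t_max]
    fixed = np.array([(s.name in anchor) or s.is_no4sU for s in data.samples])

    panel = _select_panel(data, nominal, classes, n_top, steady)
    expr = data.expression()[panel]
    ntr = data.slots["ntr"][panel]
    no4su = np.array([s.is_no4sU for s in data.samples])
    ntr = np.where(no4su[None, :], 0.0, ntr)
    new = expr * ntr
    old = expr * (1.0 - ntr)

    times = nominal.astype(float).copy()
    free = np.nonzero(~fixed)[0]

    def gene_fits(tt):
        sig = np.empty(len(panel))
        dlt = np.empty(len(panel))
        a0 = np.empty(len(panel))
        for g in range(len(panel)):
            fit = fit_nlls(new[g], old[g], tt, steady=steady)
            if not fit.converged:
                sig[g] = dlt[g] = a0[g] = np.nan
            else:
                sig[g], dlt[g], a0[g] = fit.sigma, fit.delta, fit.a0
        return sig, dlt, a0

    def pooled_ssr(tt, sig, dlt, a0):
        e = np.exp(-np.outer(dlt, tt))
        m_new = (sig / dlt)[:, None] * (1.0 - e)
        m_old = a0[:, None] * e
        r = np.nan_to_num(new - m_new) ** 2 + np.nan_to_num(old - m_old) ** 2
        return float(np.nansum(r))

    obj_prev = np.inf
    converged = False
    for _ in range(max_iter):
        sig, dlt, a0 = gene_fits(times)
        ok = np.isfinite(dlt)
        sig, dlt, a0_ok = sig[ok], dlt[ok], a0[ok]
        new_ok, old_ok = new[ok], old[ok]

        for j in free:
            def ssr_j(tau):
                e = np.exp(-dlt * tau)
                m_new = sig / dlt * (1.0 - e)
                m_old = a0_ok * e
                return float(np.sum((new_ok[:, j] - m_new) ** 2
                                    + (old_ok[:, j] - m_old) ** 2))

            res = optimize.minimize_scalar(
                ssr_j, bounds=(1e-3, 3.0 * max(nominal[j], 1e-3)),
                method="bounded", options={"xatol": 1e-8},
            )
            times[j] = float(res.x)

        obj = pooled_ssr(times, sig, dlt, a0_ok)
        if obj_prev < np.inf and abs(obj_prev - obj) <= tol * max(obj_prev, 1e-300):
            converged = True
            obj_prev = obj
            break
        obj_prev = obj
    else:
        warnings.warn("joint recalibration did not converge; returning best "
                      "iterate", stacklevel=2)

    return RecalibrationResult(
        sample_names=data.sample_names,
        nominal=nominal,
        effective=times,
        fixed=fixed,
        objective=obj_prev,
        genes_used=[data.gene_ids[i] for i in panel],
        converged=converged,
    )


def recalibrate_match_halflives(
    alphas: np.ndarray,
    betas: np.ndarray,
    reference_halflives: np.ndarray,
    t_nominal: float,
    min_genes: int = 50,
) -> float:
    """Effective labeling time matching transformed half-lives to a reference.

    At an assumed labeling time t, the steady-state half-life of a gene is
    HL(t) = -t * ln2 / log((beta-1)/(alpha+beta-2)) (the transformed NTR MAP),
    which scales linearly with t.  The effective time solves

        median_g log(HL_g(t_eff) / HL_ref_g) = 0

    on (0, 2*t_nominal] by bracketed root finding.
    """
    alphas = np.asarray(alphas, dtype=float)
    betas = np.asarray(betas, dtype=float)
    ref = np.asarray(reference_halflives, dtype=float)
    ok = (np.isfinite(ref) & (ref > 0) & np.isfinite(alphas) & np.isfinite(betas)
          & (alphas > 1.0) & (betas > 1.0))
    if np.sum(ok) < min_genes:
        raise ValueError(
            f"only {np.sum(ok)} genes with valid NTR and reference half-life; "
            f"need >= {min_genes}"
        )
    a, b, r = alphas[ok], betas[ok], ref[ok]
    # per-gene half-life at unit labeling time
    hl_unit = -LN2 / np.log((b - 1.0) / (a + b - 2.0))

    def median_lfc(t_eff):
        return float(np.median(np.log(t_eff * hl_unit / r)))

    lo, hi = 1e-6 * t_nominal, 2.0 * t_nominal
    f_lo, f_hi = median_lfc(lo), median_lfc(hi)
    if f_lo * f_hi > 0:
        raise ValueError(
            "median log fold change does not change sign on the bracket "
            f"({f_lo:.3g} at {lo:.3g} h, {f_hi:.3g} at {hi:.3g} h)"
        )
    return float(optimize.brentq(median_lfc, lo, hi, xtol=1e-10))
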