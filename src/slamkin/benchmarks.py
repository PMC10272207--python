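"""End-to-end simulation benchmarks.

Two drivers assemble complete in-silico experiments and push them through the
estimation machinery:

* ``benchmark_progressive`` -- progressive labeling time courses fitted by
  the four kinetic methods, reporting per-gene half-life deviations from
  ground truth and credible/confidence-interval coverage;
* ``benchmark_snapshot`` -- two-condition snapshot experiments (control at
  steady state; synthesis or degradation rates perturbed, constant or
  smoothly time-varying) analyzed with the hierarchical Bayesian model,
  reporting per-gene MAP log2 fold changes, observed new/old RNA fold
  changes and ROPE probabilities.

Default problem sizes are desk-scale: ~200 reads per gene and a few thousand
genes, with half-lives following the reference class distribution.  The
rate-perturbation noise defaults to unit standard deviation in log2, which
reproduces the reference benchmark's stratum sizes (about 31% of genes
perturbed more than 2-fold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (ExperimentData, GeneKinetics, SampleDesign, normalize)
from .kinetics import fit_kinetics
from .ntrquant import MixtureParams
from .simulate import (SaturatingRate, SimProfile, rate_noise_sd,
                       sample_gene_kinetics, simulate_reads_for_sample,
                       simulate_time_course, simulate_time_course_nonconstant)
from .snapshot import (SnapshotInput, estimate_condition_samples,
                       estimate_dispersions, fit_abundance_prior,
                       fold_change_posterior)

__all__ = ["ProgressiveConfig", "SnapshotConfig", "simulate_experiment",
           "simulate_snapshot_experiment", "benchmark_progressive",
           "benchmark_snapshot"]

LN2 = math.log(2)

#: log2-sd of rate perturbations matching the reference stratum sizes
DEFAULT_PERTURB_SD = 1.0


def _sample_from_abundances(
    name: str,
    condition: str,
    replicate: str,
    time: float,
    abundance: np.ndarray,
    ntr: np.ndarray | None,
    dispersion: np.ndarray | float,
    reads_per_gene: float,
    mixture: MixtureParams,
    rng: np.random.Generator,
    read_len: int = 75,
) -> tuple[SampleDesign, dict]:
    """Simulate one sequencing sample from per-gene abundances."""
    n = len(abundance)
    rel = abundance / abundance.sum()
    profile = SimProfile(
        rel_abundance=rel, dispersion=dispersion,
        total_reads=int(round(reads_per_gene * n)), read_len=read_len,
        mixture=mixture,
    )
    is_no4su = ntr is None
    if is_no4su:
        counts, _, _ = simulate_reads_for_sample(
            profile, np.zeros(n), rng, estimate=False)
        cols = {
            "count": counts,
            "ntr": np.full(n, np.nan),
            "alpha": np.full(n, np.nan),
            "beta": np.full(n, np.nan),
            "conv": np.zeros(n),
        }
    else:
        counts, stats_list, posts = simulate_reads_for_sample(
            profile, ntr, rng, estimate=True)
        cols = {
            "count": counts,
            "ntr": np.array([p.map for p in posts]),
            "alpha": np.array([p.alpha for p in posts]),
            "beta": np.array([p.beta for p in posts]),
            "conv": np.array(
                [float(rs.mult[rs.tc > 0].sum()) for rs in stats_list]),
        }
    design = SampleDesign(
        name=name, condition=condition, replicate=replicate,
        labeling_time_nominal=time, is_no4sU=is_no4su,
    )
    return design, cols


def _assemble(designs: list[SampleDesign], columns: list[dict],
              gene_ids: list[str]) -> ExperimentData:
    slots = {key: np.column_stack([c[key] for c in columns])
             for key in columns[0]}
    data = ExperimentData(gene_ids, designs, slots)
    return normalize(data)


# ---------------------------------------------------------------------------
# progressive labeling
# ---------------------------------------------------------------------------

@dataclass
class ProgressiveConfig:
    """Settings of a progressive labeling simulation.

    ``effective_times`` (parallel to ``times``) inject a ground-truth
    effective labeling time differing from the nominal one; the design still
    carries the nominal times, as in a real mis-calibrated experiment.
    ``a0_fold`` != 1 starts all genes away from steady state at
    a0 = a0_fold * sigma/delta.
    """

    n_genes: int = 1000
    times: Sequence[float] = (1.0, 2.0, 4.0, 8.0)
    effective_times: Sequence[float] | None = None
    replicates: int = 1
    reads_per_gene: float = 200.0
    dispersion: float = 0.01
    v_sigma: float = 1.05
    v_delta: float = 1.05
    a0_fold: float = 1.0
    include_no4su: bool = False
    mixture: MixtureParams = field(default_factory=MixtureParams)
    seed: int = 0


def simulate_experiment(config: ProgressiveConfig) -> tuple[ExperimentData, dict]:
    """Simulate a progressive labeling experiment with ground truth.

    Returns the normalized experiment and a truth dict with the gene
    kinetics plus per-sample realized rates and true NTRs.
    """
    rng = np.random.default_rng(config.seed)
    kin = sample_gene_kinetics(config.n_genes, rng)
    if config.a0_fold != 1.0:
        kin = GeneKinetics(sigma=kin.sigma, delta=kin.delta,
                           a0=config.a0_fold * kin.steady_state)
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    eff = (list(config.effective_times) if config.effective_times is not None
           else list(config.times))
    designs, columns = [], []
    truth_samples = {}
    if config.include_no4su:
        for r in range(config.replicates):
            d, c = _sample_from_abundances(
                f"sim.no4sU.{r + 1}", "sim", str(r + 1), 0.0,
                np.asarray(kin.a0, dtype=float), None, config.dispersion,
                config.reads_per_gene, config.mixture, rng)
            designs.append(d)
            columns.append(c)
    for t_nom, t_eff in zip(config.times, eff):
        for r in range(config.replicates):
            truth = simulate_time_course(kin, t_eff, config.v_sigma,
                                         config.v_delta, rng)
            name = f"sim.{t_nom:g}h.{r + 1}"
            d, c = _sample_from_abundances(
                name, "sim", str(r + 1), t_nom, truth.abundance, truth.ntr,
                config.dispersion, config.reads_per_gene, config.mixture, rng)
            designs.append(d)
            columns.append(c)
            truth_samples[name] = truth
    data = _assemble(designs, columns, gene_ids)
    return data, {"kinetics": kin, "samples": truth_samples,
                  "effective_times": dict(zip(config.times, eff))}


def benchmark_progressive(
    config: ProgressiveConfig,
    methods: Sequence[str] = ("lm", "nlls", "ntr", "pulser"),
    steady: bool = True,
    exact_ci: bool = False,
) -> pd.DataFrame:
    """Fit a simulated progressive course with each method.

    Returns one row per gene and method with the true and estimated
    half-life, the log2 deviation, convergence and (where the method
    provides intervals) whether the truth is covered.
    """
    data, truth = simulate_experiment(config)
    kin: GeneKinetics = truth["kinetics"]
    hl_true = np.asarray(kin.halflife, dtype=float)
    rows = []
    for method in methods:
        fits = fit_kinetics(data, method=method, steady=steady,
                            exact_ci=exact_ci)
        for i, fit in enumerate(fits):
            row = {
                "gene": data.gene_ids[i],
                "method": method,
                "halflife_true": hl_true[i],
                "halflife_est": fit.halflife if fit.converged else np.nan,
                "sigma_est": fit.sigma,
                "converged": fit.converged,
            }
            row["log2_dev"] = (
                np.log2(row["halflife_est"] / hl_true[i])
                if fit.converged and fit.halflife > 0 else np.nan
            )
            if fit.converged and "delta" in fit.ci:
                lo, hi = fit.halflife_ci()
                row["ci_width"] = hi - lo
                row["covered"] = bool(lo <= hl_true[i] <= hi)
            if fit.converged and "delta_exact" in fit.ci:
                dlo, dhi = fit.ci["delta_exact"]
                row["ci_width_exact"] = LN2 / dlo - LN2 / dhi
                row["covered_exact"] = bool(dhi >= LN2 / hl_true[i] >= dlo)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# snapshot experiments
# ---------------------------------------------------------------------------

@dataclass
class SnapshotConfig:
    """Settings of a two-condition snapshot simulation.

    The control condition sits at steady state; the treated condition starts
    from the same initial abundances with synthesis or degradation rates
    perturbed by 2^eta, eta ~ Normal(0, ``perturb_sd``), either abruptly at
    the onset of labeling (``nonconstant=False``) or approaching the
    perturbed state smoothly with speed ``saturation_speed``.
    """

    n_genes: int = 2000
    t: float = 2.0
    replicates: int = 3
    reads_per_gene: float = 200.0
    dispersion: float = 0.01
    v_sigma: float = 1.05
    v_delta: float = 1.05
    perturb: str = "sigma"  # "sigma", "delta" or "none"
    perturb_sd: float = DEFAULT_PERTURB_SD
    nonconstant: bool = False
    saturation_speed: float = 1.39
    n_posterior_samples: int = 1000
    rope_halfwidth: float = 0.25
    mixture: MixtureParams = field(default_factory=MixtureParams)
    estimate_dispersion: bool = True
    seed: int = 0


def _treated_abundances(config: SnapshotConfig, kin: GeneKinetics,
                        eta: np.ndarray, rng: np.random.Generator):
    """Abundances (a_new, a_old) of one treated replicate."""
    n = config.n_genes
    sigma = np.asarray(kin.sigma, dtype=float)
    delta = np.asarray(kin.delta, dtype=float)
    a0 = np.asarray(kin.a0, dtype=float)
    eps_s = rng.normal(0.0, rate_noise_sd(config.v_sigma), size=n)
    eps_d = rng.normal(0.0, rate_noise_sd(config.v_delta), size=n)
    fold = np.exp2(eta)
    if not config.nonconstant:
        sig = sigma * (fold if config.perturb == "sigma" else 1.0) * np.exp2(eps_s)
        dlt = delta * (fold if config.perturb == "delta" else 1.0) * np.exp2(eps_d)
        a_new = sig / dlt * -np.expm1(-config.t * dlt)
        a_old = a0 * np.exp(-config.t * dlt)
        return a_new, a_old
    sig_base = sigma * np.exp2(eps_s)
    dlt_base = delta * np.exp2(eps_d)
    if config.perturb == "sigma":
        fns = [SaturatingRate(s, c, config.saturation_speed)
               for s, c in zip(sig_base, fold)]
        return simulate_time_course_nonconstant(
            fns, None, config.t, a0, delta=dlt_base)
    fns = [SaturatingRate(d, c, config.saturation_speed)
           for d, c in zip(dlt_base, fold)]
    return simulate_time_course_nonconstant(
        None, fns, config.t, a0, sigma=sig_base)


def simulate_snapshot_experiment(
    config: SnapshotConfig,
) -> tuple[ExperimentData, pd.DataFrame]:
    """Simulate a two-condition snapshot experiment with ground truth.

    Simulates shared 4sU-naive reference replicates at the start of labeling,
    control replicates at steady state and treated replicates with perturbed
    rates.  Returns the normalized experiment and a per-gene truth table
    with the base half-life and the true log2 fold changes (treated vs
    control) of the final-state synthesis rate and half-life.
    """
    if config.perturb not in ("sigma", "delta", "none"):
        raise ValueError("perturb must be 'sigma', 'delta' or 'none'")
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    kin = sample_gene_kinetics(n, rng)
    if config.perturb == "none":
        eta = np.zeros(n)
    else:
        eta = rng.normal(0.0, config.perturb_sd, size=n)
    # true log2 fold changes (treated vs control) of the final-state rates
    true_lfc_sigma = eta if config.perturb == "sigma" else np.zeros(n)
    true_lfc_halflife = -eta if config.perturb == "delta" else np.zeros(n)

    gene_ids = [f"G{i:05d}" for i in range(n)]
    designs, columns = [], []
    for r in range(config.replicates):
        d, c = _sample_from_abundances(
            f"ref.no4sU.{r + 1}", "ref", str(r + 1), 0.0,
            np.asarray(kin.a0, dtype=float), None, config.dispersion,
            config.reads_per_gene, config.mixture, rng)
        designs.append(d)
        columns.append(c)
    for r in range(config.replicates):
        truth = simulate_time_course(kin, config.t, config.v_sigma,
                                     config.v_delta, rng)
        d, c = _sample_from_abundances(
            f"ctrl.{config.t:g}h.{r + 1}", "ctrl", str(r + 1), config.t,
            truth.abundance, truth.ntr, config.dispersion,
            config.reads_per_gene, config.mixture, rng)
        designs.append(d)
        columns.append(c)
    for r in range(config.replicates):
        a_new, a_old = _treated_abundances(config, kin, eta, rng)
        total = a_new + a_old
        ntr = np.where(total > 0, a_new / np.maximum(total, 1e-300), 0.0)
        d, c = _sample_from_abundances(
            f"treat.{config.t:g}h.{r + 1}", "treat", str(r + 1), config.t,
            total, ntr, config.dispersion, config.reads_per_gene,
            config.mixture, rng)
        designs.append(d)
        columns.append(c)
    data = _assemble(designs, columns, gene_ids)
    truth = pd.DataFrame({
        "gene": gene_ids,
        "halflife_true": LN2 / np.asarray(kin.delta, dtype=float),
        "true_lfc_sigma": true_lfc_sigma,
        "true_lfc_halflife": true_lfc_halflife,
    })
    return data, truth


def benchmark_snapshot(config: SnapshotConfig) -> pd.DataFrame:
    """Simulate and analyze a two-condition snapshot experiment.

    Runs :func:`simulate_snapshot_experiment`, then the hierarchical Bayesian
    sampler per gene and condition, and returns one row per gene with true
    and estimated log2 fold changes of synthesis rate and half-life, observed
    new/old RNA fold changes and ROPE probabilities P_sigma and P_delta.
    """
    data, truth = simulate_snapshot_experiment(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = config.n_genes
    gene_ids = truth["gene"].tolist()

    m = config.replicates
    ref_idx = list(range(0, m))
    ctrl_idx = list(range(m, 2 * m))
    treat_idx = list(range(2 * m, 3 * m))
    expr = data.expression()
    if config.estimate_dispersion:
        disp = estimate_dispersions(expr, [ref_idx, ctrl_idx, treat_idx])
    else:
        disp = np.full(n, config.dispersion)
    prior = fit_abundance_prior(np.mean(expr, axis=1), disp)

    alphas = data.slots["alpha"]
    betas = data.slots["beta"]
    ntr_map = data.slots["ntr"]
    rows = []
    for i in range(n):
        try:
            inp_ctrl = SnapshotInput(
                counts=expr[i, ctrl_idx], ref_counts=expr[i, ref_idx],
                alphas=alphas[i, ctrl_idx], betas=betas[i, ctrl_idx],
                t=config.t, dispersion=float(disp[i]))
            inp_treat = SnapshotInput(
                counts=expr[i, treat_idx], ref_counts=expr[i, ref_idx],
                alphas=alphas[i, treat_idx], betas=betas[i, treat_idx],
                t=config.t, dispersion=float(disp[i]))
            draws_b = estimate_condition_samples(
                inp_ctrl, prior, config.n_posterior_samples, rng)
            draws_a = estimate_condition_samples(
                inp_treat, prior, config.n_posterior_samples, rng)
            summary = fold_change_posterior(
                draws_a[:2], draws_b[:2], config.rope_halfwidth,
                rejection_rate_a=draws_a[2], rejection_rate_b=draws_b[2])
        except (ValueError, RuntimeError):
            summary = None

        new_treat = float(np.mean(expr[i, treat_idx] * ntr_map[i, treat_idx]))
        new_ctrl = float(np.mean(expr[i, ctrl_idx] * ntr_map[i, ctrl_idx]))
        old_treat = float(np.mean(expr[i, treat_idx] * (1 - ntr_map[i, treat_idx])))
        old_ctrl = float(np.mean(expr[i, ctrl_idx] * (1 - ntr_map[i, ctrl_idx])))
        floor = 1e-3
        row = {
            "gene": gene_ids[i],
            "halflife_true": truth["halflife_true"].iat[i],
            "true_lfc_sigma": truth["true_lfc_sigma"].iat[i],
            "true_lfc_halflife": truth["true_lfc_halflife"].iat[i],
            "lfc_new_obs": math.log2(max(new_treat, floor) / max(new_ctrl, floor)),
            "lfc_old_obs": math.log2(max(old_treat, floor) / max(old_ctrl, floor)),
        }
        if summary is not None and summary.n_draws > 0:
            row.update({
                "map_lfc_sigma": summary.map_lfc_sigma,
                "map_lfc_halflife": summary.map_lfc_halflife,
                "p_sigma": summary.p_sigma,
                "p_delta": summary.p_delta,
                "n_draws": summary.n_draws,
                "rejection_rate": 0.5 * (summary.rejection_rate_a
                                         + summary.rejection_rate_b),
                "low_confidence": summary.low_confidence,
            })
        else:
            row.update({
                "map_lfc_sigma": np.nan, "map_lfc_halflife": np.nan,
                "p_sigma": np.nan, "p_delta": np.nan, "n_draws": 0,
                "rejection_rate": 1.0, "low_confidence": True,
            })
        rows.append(row)
    return pd.DataFrame(rows)
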