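# Methods

This note documents the statistical models implemented in slamkin, the
defaults and why they were chosen, what the simulator does and does not
emulate, and the numerical choices that matter for reproducibility.

## Conversion model and NTR inference

A read covering `u` uridines carries `k` T-to-C mismatches with probability

    P(k; u) = (1 − ntr)·B(k; u, p_e) + ntr·B(k; u, p_c),

where `p_e` is the sequencing-error mismatch rate, `p_c` the conversion rate
in labeled RNA and `ntr` the gene's new-to-total RNA ratio. The per-gene
log likelihood sums over the multiset of per-read `(u, tc)` pairs — the
sufficient statistics. `estimate_ntr` maximizes it on [ε, 1−ε] (ε = 1e−9,
compared against the boundary values) under a uniform prior, and fits a
Beta(α, β) to the mean and variance of the quadrature-normalized posterior
(512-point regular grid, log-space evaluation with max subtraction).
Moment matching was chosen because it is exactly reproducible and testable
against the quadrature moments; the flat case (no read covers a uridine)
returns Beta(1, 1) with the MAP marked undefined. `p_e` and `p_c` are
required inputs (defaults 1e−4 and 0.04): global estimation of the mixture
parameters from raw data belongs to the upstream read processor, not here.

## Kinetic model and the four progressive-labeling fitters

First-order kinetics `da/dt = σ − δa` give, after labeling for time t,
old RNA `a₀·e^(−δt)` and new RNA `(σ/δ)(1 − e^(−δt))`; observed old and new
RNA are `O = C(1 − Ξ)` and `N = C·Ξ` from normalized expression C and
estimated NTR Ξ. The fitters differ only in their error model:

- **LM**: OLS on `log O = log a₀ − δt` (homoscedastic log-normal). Samples
  with `O ≤ 0` are dropped. Intervals from standard regression theory.
- **NLLS**: unweighted least squares on `(N, O)` jointly
  (homoscedastic gaussian), Levenberg–Marquardt on log-scale parameters
  (positivity without constraints), starting values from LM with restarts at
  δ ∈ {0.05, ln 2, 2} h⁻¹; intervals from the linearized covariance.
- **NTR (Bayesian)**: steady state implies `δ = −log(1 − ntr)/t`; pooling
  the per-sample Beta posteriors of the NTR gives the log posterior
  `g(δ) = Σ_k (α_k−1)·log(1−e^(−t_k δ)) − t_k(β_k−1)·δ`, maximized by
  bounded scalar search on δ ∈ [ln2/168, ln2/0.01] h⁻¹ (half-lives 36 s to
  1 week). For one sample the maximizer has the closed form
  `−log((β−1)/(α+β−2))/t` (the transformed NTR MAP, the default point
  estimator); the mode of the density transformed to δ-space,
  `−log(β/(α+β−1))/t`, is also exposed — the MAP is not invariant under the
  change of variables. Approximate credible intervals use the likelihood
  drop `c = χ²₁(level)/2` with bracketed root search on both sides; exact
  intervals normalize `e^g` on a 4001-point geometric δ-grid and accumulate
  mass outward from the MAP, extending at each step the side with higher
  density (an equal-tailed option exists). `σ = mean(C_k)·δ̂`; the mean over
  samples is used because the steady-state relation `σ = C·δ` does not
  specify an aggregation.
- **pulseR-style**: negative-binomial likelihood on counts of reads with and
  without observed conversions, means `μ₁ + a₀e^(−δt)` and
  `μ₂ + (σ/δ)(1−e^(−δt))`; the nuisances μ₁ (conversion-free reads from new
  RNA) and μ₂ (error-conversion reads from old RNA) and a gene-wise
  dispersion are profiled jointly; everything is log-parameterized.

Under steady-state simulation, NLLS and NTR dominate LM and pulseR in
|log2(estimated/true half-life)|, NTR ~95% credible intervals cover ≈95% of
genes, and exact intervals are narrower than approximate ones in median —
all verified by the test suite.

## Temporal recalibration

Because 4sU must be taken up and activated, the effective labeling time of a
sample (one global parameter per sample) can be shorter than nominal.

*Joint fitting* (progressive designs): a stratified panel — the top 200
expressed genes in each rough half-life class 0–2, 2–4, 6–8, >8 h (classes
as used in the reference workflow; the 4–6 h gap is kept as printed, with an
override) — is fitted by alternating optimization: per-gene steady-state
NLLS at the current times, then per-sample bounded scalar minimization of
the pooled squared residuals over that sample's time, iterated until the
relative objective change is < 1e−6. Alternation replaces one monolithic
solver deliberately: given gene parameters the per-sample objectives
separate, which conditions the problem far better at the same optimum. The
latest time point is the anchor (identifiability: times are only determined
up to the model's time unit). Whether to use steady-state or a₀-free NLLS
inside the loop is switchable; steady state is the default.

*Half-life matching* (snapshot designs): at an assumed labeling time t the
transformed half-life of each gene scales linearly with t, so the effective
time solving `median_g log(HL_g(t_eff)/HL_ref_g) = 0` is found by bracketed
root search on (0, 2·t_nominal]; it needs ≥50 genes with a valid NTR
posterior (α, β > 1) and a finite reference half-life.

## Snapshot transformation and hierarchical Bayesian model

With a reference abundance from the start of labeling, `F = a_old/a_ref`
gives `δ = −log(F)/t` and `σ = −a_new·log(F)/(t(1−F))`; with an earlier
reference (t′ < 0) δ solves a one-dimensional root problem (rates assumed
constant on [t′, t]). An observed old-RNA fold change f maps half-lives as
`t½′ = t½/(1 − t½·log2(f)/t)` — not a constant fold change, which is why
old-RNA fold changes misrepresent stability changes.

The sampler draws, independently per condition:

1. **a₀ and a(t)** from the conjugate posterior of the reparameterized
   negative binomial: with size `s = 1/d` and `p = s/(s+μ)`, the NB pmf is
   ∝ `p^s(1−p)^c`, so `p | c₁..c_n ~ Beta(α + n·s, β + Σc_k)`; draws map
   back through `μ = (1−p)/(p·d)`. The Beta hyperprior is fitted across
   genes by method of moments on `p_i = s_i/(s_i+c_i)`. The per-gene
   dispersion is an input; a bundled fallback estimates it by pooled
   method of moments over replicate groups with 50/50 log-space shrinkage
   toward the across-gene median, clipped to [1e−4, 2] — a lightweight
   stand-in for trended empirical-Bayes estimators, adequate because the
   sampler is insensitive to modest dispersion error.
2. **ntr(t)** from a hierarchical Beta model: each replicate contributes a
   technical Beta(α_k, β_k); the biological prior Beta(α, β) is conjugate
   with them, leaving the marginal hyperparameter posterior
   `π(α,β)·Π_k B(α+α_k, β+β_k)/B(α,β)`. It is evaluated on a 61×61 grid in
   `(x, y) = (log(α/β), log(α+β))` — x is logit of the mean, the target of
   sampling — with Jacobian `e^(x+2y)/(e^x+1)²`, centered at the numerically
   located mode and extended per axis until the density falls below 1/1000
   of the maximum. Summing over y, sampling x with within-cell uniform
   jitter and applying the inverse logit yields draws of the biological mean
   NTR. The hyperprior on the concentration is the normalized sigmoid
   `f(x) = 1/(1+e^((x−o)/s))`, `C = s·log(1+e^(o/s))`; the offset o is set so
   a Beta at concentration o has variance equal to the replicate-mean
   scatter (floored by the mean technical variance when replicates agree or
   n = 1), and the scale is o/10 — a sharp but smooth cutoff; the exact
   shape matters little as long as the mean is unconstrained and the
   minimal variance is bounded. Grid resolution is configurable;
   convergence was checked by doubling.
3. Draws combine as `a_new = a(t)·ntr`, `a_old = a(t)·(1−ntr)` and pass
   through the snapshot transformation; draws with `F ≥ 1` (old RNA
   apparently grew — impossible under the model) are **rejected**, not
   clamped, and the rejection fraction is reported (a >50% fraction flags
   the gene).

Paired draws between condition A and control B give posteriors of
`log2(σ_A/σ_B)` and `log2(δ_B/δ_A)` — the half-life ratio is inverted so
increased stability in A is positive. The MAP summary is the mode of a
gaussian KDE (normal-reference bandwidth; the median is available), and the
ROPE probabilities P_σ, P_δ are the posterior mass outside ±0.25 log2 units;
P > 0.9 calls a significant change. A and B draws are paired by index,
equivalent to independent pairing for i.i.d. draws.

## Simulator

`simulate_reads_for_sample` draws counts `C_i ~ NB(a_i·N, d_i)`
(variance μ + dμ², Poisson at d = 0), per-read uridine counts
`u ~ Binom(read_len, p_u)` with `p_u ~ Beta` moment-matched to mean 0.25,
sd 0.05 (read length 75), and conversions from the mixture at the gene's
true NTR; the NTR posterior is then re-estimated from the simulated
statistics with the true mixture parameters, so simulated data pass through
the same quantification path as real data. Biological variability
multiplies each gene's rates per sample by `2^ε`,
`ε ~ N(0, log2(v)/1.6449)` (v = 1.05 by default: 90% of realized rates
within 1.05-fold). Time-varying rates follow the saturating form
`s·c^(1−e^(−t·d))` with d = 1.39 h⁻¹ (half the log-change after 30 min) and
are integrated (LSODA, rtol 1e−8) for new and old RNA separately.

The benchmark gene population emulates, rather than copies, a real
transcriptome: half-lives are log-uniform within five classes weighted
204/1417/2996/3122/3096 (0.25–1, 1–2, 2–4, 4–8, 8–48 h; the open upper
class is capped at 48 h), and steady-state abundances are log-normal
(log-sd 1), drawn **independently** of half-life. Real transcriptomes
couple the two (stable mRNAs tend to be highly expressed), so real data
quantify long-lived genes better than this emulation does; conclusions
about absolute error magnitudes transfer to real data only up to this
caveat, while orderings and calibration properties are robust to it.

Benchmark conditions: 2 h labeling, 3 vs 3 replicates plus 3 4sU-naive
reference replicates at the start of labeling, mean 2000 reads per gene and
true NB dispersion 0.005 — depth and dispersion chosen as typical of the
deep bulk cell-line datasets such experiments are performed on (tens of
millions of reads per sample; gene-wise dispersions of a few thousandths).
Rate perturbations are `2^η, η ~ N(0, 1)`, putting ~31% of genes beyond
2-fold; `perturb_rates` is alternatively parameterized by the expected
fraction beyond 2-fold. Dispersions used by the analysis are re-estimated
from the simulated counts, not taken from truth. Posterior sampling uses
1000 draws per gene and condition; the acceptance script runs 2000 genes
for the constant-rate comparisons and 1000 for the time-varying ones, sizes
chosen so a full run completes in minutes while percentage summaries carry
~1-point Monte-Carlo error.

The simulator does not emulate: positional error profiles, SNPs and
multi-mismatch chemistry, isoforms, UMI structure, library-preparation
biases, or expression–stability coupling (above). Passing benchmarks
therefore demonstrate correctness of the inference given the generative
model, not robustness to artifacts outside it.

## Numerical choices and degenerate inputs

- Likelihood and posterior evaluations subtract the maximum in log space
  before exponentiating; mixture pmfs are evaluated in linear space (their
  components cannot underflow for realistic u).
- Boundary NTRs: optimization on [1e−9, 1−1e−9] with explicit boundary
  comparison; `−inf` log likelihood is a value, not an exception.
- δ searches are bounded to half-lives between 36 s and 1 week; credible
  intervals clip at these bounds when the drop criterion finds no root.
- Root brackets (snapshot δ, half-life matching) report both bracket values
  when no sign change exists.
- Zero counts: size factors require at least one gene positive everywhere;
  genes with any zero are excluded from the reference set only.
- Seeds: every stochastic routine takes a `numpy.random.Generator`; the CLI
  and acceptance script derive independent child streams from one root seed
  via `SeedSequence`. Sampling is vectorized per sample, so results are
  reproducible for a fixed configuration and seed (changing `n_genes`
  reshuffles the stream).

## Known limitations

- The NTR method and the snapshot transformation assume constancy of rates
  during labeling; under time-varying rates estimates are time-averages
  weighted toward late labeling times, and the benchmark quantifies the
  resulting shrinkage of fold-change magnitudes (~30–35% at saturation
  speed 1.39 h⁻¹ over 2 h).
- The pulseR-style fitter needs ≥4 samples and integer-like counts; it is
  the slowest fitter and the least accurate under the simulated conditions.
- The hierarchical NTR model treats p_e/p_c as known and the Beta technical
  posterior as exact; both are approximations inherited from upstream
  quantification.
- With 3 replicates the fallback dispersion estimator is crude; when a
  trended estimate from a dedicated DE framework is available it should be
  passed in instead.
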