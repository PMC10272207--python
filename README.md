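# slamkin

Kinetic analysis of nucleotide-conversion metabolic RNA labeling RNA-seq
(SLAM-seq, TimeLapse-seq, TUC-seq) — for transcriptomics researchers who want
RNA synthesis and degradation rates, not just expression levels.

In these protocols, cells are fed 4-thiouridine (4sU) for a labeling period;
chemical conversion makes 4sU incorporated into nascent RNA read out as
T-to-C mismatches in sequencing reads. Per gene, the fraction of RNA made
during labeling — the new-to-total RNA ratio (NTR) — is identified by a
two-component binomial mixture over per-read conversion counts, and the
kinetics of RNA turnover follow the first-order model

    da/dt = σ − δ·a(t)    ⇒    a(t) = (a₀ − σ/δ)·e^(−δt) + σ/δ

with synthesis rate σ, degradation rate δ, and half-life t½ = ln 2 / δ.

## What the package does

- **Simulation with ground truth** (`simulate`, `benchmarks`): negative-binomial
  read counts, per-read (uridine, conversion) sufficient statistics from the
  mixture `P(k; u) = (1−ntr)·B(k; u, p_e) + ntr·B(k; u, p_c)`, biological rate
  variability, constant and smoothly time-varying rates, rate perturbations
  between conditions.
- **NTR quantification** (`ntrquant`): MAP estimate under a uniform prior and
  a moment-matched Beta(α, β) posterior approximation from the per-read
  sufficient statistics.
- **Progressive-labeling kinetics** (`kinetics`): per-gene (σ, δ) by four
  error models — log-linear regression on old RNA (LM), nonlinear least
  squares on old+new RNA (NLLS, the recommended default), a Bayesian estimate
  operating directly on the NTR posteriors (with approximate χ²-drop or exact
  numerically-integrated credible intervals), and a negative-binomial fit on
  conversion-read counts with leakage nuisances (pulseR-style).
- **Temporal recalibration** (`recalibrate`): effective labeling times differ
  from nominal ones because 4sU uptake and activation take time; estimated
  either by joint kinetic fitting over a stratified gene panel (progressive
  designs, anchored at the last time point) or by matching transformed
  half-lives to a reference (snapshot designs).
- **Snapshot Bayesian model** (`snapshot`): from a single labeling time point
  plus a reference sample, posterior samples of (σ, δ) per condition via
  conjugate count posteriors and a grid-sampled hierarchical Beta model of the
  NTR; log2 fold-change posteriors between conditions with
  region-of-practical-equivalence (ROPE) significance (P of |log2 FC| > 0.25).
- **Quality control** (`qc`): 4sU-toxicity statistic — Spearman correlation of
  NTR ranks vs expression fold change against 4sU-naive controls.

## Worked example

```python
import numpy as np
import slamkin as sk

config = sk.ProgressiveConfig(n_genes=100, times=(1, 2, 4, 8),
                              reads_per_gene=1000.0, seed=1)
data, truth = sk.simulate_experiment(config)
fits = sk.fit_kinetics(data, method="nlls", steady=True)

hl_true = np.asarray(truth["kinetics"].halflife)
hl_est = np.array([f.halflife for f in fits])
print(np.nanmedian(np.abs(np.log2(hl_est / hl_true))))
```

Running `examples/01_simulate_and_fit.py` (this example plus reporting)
prints:

```
genes fitted: 100 / 100
median |log2(estimated/true half-life)|: 0.080
correlation of log half-lives: 0.993
  G00000: true t1/2 = 6.29 h, estimated = 6.98 h
```

i.e. most half-lives are recovered within ~6% (2^0.08) of truth at 1000
reads per gene, and estimated and true half-lives correlate at r = 0.99.
The other scripts in `examples/` demonstrate NTR quantification, temporal
recalibration, snapshot fold-change inference with ROPE calls, and toxicity
QC, each printing the numbers it computes and what they mean.

A thin command line mirrors the library:

```bash
slamkin simulate --n-genes 500 --time-points 1,2,4,8 --seed 1 --out run/
slamkin fit --input run/data.tsv --design run/design.tsv --method nlls --out fits.tsv
slamkin snapshot --input data.tsv --design design.tsv \
    --condition-a treat --condition-b ctrl --reference-condition ref --out lfc.tsv
```

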