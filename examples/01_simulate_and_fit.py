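"""Simulate a progressive 4sU labeling course and fit per-gene kinetics.

Builds a 100-gene experiment with samples labeled for 1, 2, 4 and 8 hours,
fits the nonlinear-least-squares kinetic model per gene and compares the
recovered half-lives with the simulated ground truth.
"""

import numpy as np

import slamkin as sk

config = sk.ProgressiveConfig(n_genes=100, times=(1, 2, 4, 8),
                              reads_per_gene=1000.0, seed=1)
data, truth = sk.simulate_experiment(config)
fits = sk.fit_kinetics(data, method="nlls", steady=True)

hl_true = np.asarray(truth["kinetics"].halflife)
hl_est = np.array([f.halflife if f.converged else np.nan for f in fits])
dev = np.log2(hl_est / hl_true)

print(f"genes fitted: {int(np.sum(np.isfinite(hl_est)))} / {len(fits)}")
print(f"median |log2(estimated/true half-life)|: {np.nanmedian(np.abs(dev)):.3f}")
print(f"correlation of log half-lives: "
      f"{np.corrcoef(np.log(hl_est), np.log(hl_true))[0, 1]:.3f}")
for i in range(3):
    print(f"  {data.gene_ids[i]}: true t1/2 = {hl_true[i]:.2f} h, "
          f"estimated = {hl_est[i]:.2f} h")
# A median absolute log2 deviation well below 0.1 means most half-lives are
# recovered within ~7%; the per-gene lines show typical agreement.
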