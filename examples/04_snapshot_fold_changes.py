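"""Bayesian synthesis/half-life fold changes from a snapshot experiment.

Two conditions are labeled for 2 h (3 replicates each, plus 4sU-naive
reference samples from the start of labeling); the treated condition has
perturbed synthesis rates.  The hierarchical Bayesian model yields, per
gene, posterior samples of log2 fold changes of the synthesis rate and the
RNA half-life, summarized as a MAP estimate and ROPE probabilities
(P > 0.9 with |log2 FC| > 0.25 calls a significant change).
"""

import numpy as np

import slamkin as sk

config = sk.SnapshotConfig(n_genes=150, perturb="sigma", t=2.0,
                           replicates=3, reads_per_gene=1500.0,
                           n_posterior_samples=800, seed=4)
df = sk.benchmark_snapshot(config)

err = df["map_lfc_sigma"] - df["true_lfc_sigma"]
print(f"genes analyzed: {len(df)}")
print(f"RMSD of MAP synthesis log2 FC vs truth: "
      f"{np.sqrt(np.nanmean(err**2)):.3f}")
big = df["true_lfc_sigma"].abs() > 1
print(f"sensitivity (P_sigma > 0.9) among >2-fold perturbed genes: "
      f"{100 * (df.loc[big, 'p_sigma'] > 0.9).mean():.1f}% (n={big.sum()})")
print(f"false-positive rate for half-life calls (P_delta > 0.9): "
      f"{100 * (df['p_delta'] > 0.9).mean():.1f}%")
print(df[["gene", "true_lfc_sigma", "map_lfc_sigma", "p_sigma",
          "p_delta"]].head(5).to_string(index=False,
                                        float_format="%.3f".__mod__))
# Synthesis changes are detected with high sensitivity; half-life calls fire
# far less often (no half-life was changed), and their residual false
# positives shrink further with more genes and deeper sequencing.
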