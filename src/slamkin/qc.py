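"""Quality control for 4sU toxicity.

Incorporated 4sU can perturb transcription; because short-lived RNAs react
fastest to a global transcriptional slowdown, toxicity shows up as a negative
correlation between a gene's new-to-total RNA ratio (a proxy for turnover)
and its expression log2 fold change versus 4sU-naive control samples.  The
correlation is rank-based (Spearman) and therefore robust to the choice of
fold-change estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import ExperimentData

__all__ = ["ToxicityResult", "ntr_ranks", "toxicity_correlation"]


@dataclass
class ToxicityResult:
    """Spearman correlation of NTR rank vs log2 FC against no4sU controls."""

    sample: str
    rho: float
    p_value: float
    n_genes: int
    degenerate: bool = False


def ntr_ranks(ntr: np.ndarray) -> np.ndarray:
    """Min-max scaled average ranks of NTR values: 0 = smallest, 1 = largest.

    Ties share the average scaled rank; a constant vector yields all 0.5.
    NaN entries propagate as NaN.
    """
    ntr = np.asarray(ntr, dtype=float)
    finite = np.isfinite(ntr)
    n = int(np.sum(finite))
    if n < 2:
        raise ValueError("need at least 2 finite NTR values to rank")
    out = np.full(ntr.shape, np.nan)
    ranks = stats.rankdata(ntr[finite], method="average")
    if np.ptp(ntr[finite]) == 0:
        out[finite] = 0.5
    else:
        out[finite] = (ranks - 1.0) / (n - 1.0)
    return out


def toxicity_correlation(
    data: ExperimentData,
    treated: str,
    controls: list[str],
    pseudocount: float = 0.1,
    min_genes: int = 20,
) -> ToxicityResult:
    """4sU-toxicity statistic for one treated sample.

    Computes lfc = log2((treated + phi) / (mean(controls) + phi)) on
    normalized counts and correlates it (Spearman) with the scaled NTR ranks
    of the treated sample; the two-sided p-value uses the approximate t
    transformation of rho.  Controls must be 4sU-naive samples.
    """
    j = data.sample_index(treated)
    ctrl_idx = [data.sample_index(c) for c in controls]
    for k in ctrl_idx:
        if not data.samples[k].is_no4sU:
            raise ValueError(
                f"control sample {data.samples[k].name!r} is not 4sU-naive"
            )
    expr = data.expression()
    ntr = data.slots["ntr"][:, j]
    lfc = np.log2((expr[:, j] + pseudocount)
                  / (np.mean(expr[:, ctrl_idx], axis=1) + pseudocount))
    ok = np.isfinite(ntr) & np.isfinite(lfc)
    if np.sum(ok) < min_genes:
        raise ValueError(
            f"only {np.sum(ok)} genes usable for toxicity QC; need >= {min_genes}"
        )
    ranks = ntr_ranks(np.where(ok, ntr, np.nan))
    if np.ptp(ntr[ok]) == 0 or np.ptp(lfc[ok]) == 0:
        return ToxicityResult(treated, 0.0, 1.0, int(np.sum(ok)), degenerate=True)
    rho, p = stats.spearmanr(ranks[ok], lfc[ok])
    return ToxicityResult(treated, float(rho), float(p), int(np.sum(ok)))
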