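"""Core genes x samples data container for nucleotide-conversion RNA-seq.

Nucleotide-conversion protocols (SLAM-seq, TimeLapse-seq, TUC-seq) yield, per
gene and sample, a total expression level together with an estimate of the
new-to-total RNA ratio (NTR) -- the fraction of RNA synthesized during the
4sU labeling period -- and a Beta approximation of the NTR posterior.  This
module holds these data, parses sample metadata from systematic sample names,
and provides gene filtering and median-of-ratios size-factor normalization
shared by all downstream analyses.

Conventions
-----------
* Time is measured in hours everywhere; name parsers convert minutes.
* Counts are stored as floats: normalized values and simulated expectations
  are fractional.
* Samples without 4sU ("no4sU") carry no labeling information; their NTR,
  alpha and beta entries are NaN, never 0.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SampleDesign",
    "ExperimentData",
    "GeneKinetics",
    "parse_duration",
    "parse_systematic_names",
    "compute_size_factors",
    "normalize",
    "filter_genes",
]

_DURATION_RE = re.compile(r"^(\d+(?:\.\d+)?)(h|hr|hpi|min|m)$", re.IGNORECASE)

#: token in a duration field marking a 4sU-naive control sample
NO4SU_TOKEN = "no4sU"


@dataclass
class SampleDesign:
    """Metadata for one sequencing sample.

    ``labeling_time_effective`` defaults to the nominal labeling time; temporal
    recalibration replaces it by the estimated effective 4sU labeling time.
    """

    name: str
    condition: str = ""
    labeling_time_nominal: float = 0.0
    labeling_time_effective: float | None = None
    replicate: str = ""
    is_no4sU: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.labeling_time_effective is None:
            self.labeling_time_effective = self.labeling_time_nominal
        if self.labeling_time_nominal < 0:
            raise ValueError(f"negative labeling time for sample {self.name!r}")
        if not self.is_no4sU and self.labeling_time_effective <= 0:
            raise ValueError(
                f"sample {self.name!r}: labeled sample needs labeling time > 0 "
                "(use is_no4sU=True for 4sU-naive samples)"
            )


def parse_duration(token: str) -> tuple[float, bool]:
    """Parse a labeling-duration token like ``"2h"``, ``"30min"`` or ``"no4sU"``.

    Returns ``(hours, is_no4sU)``.
    """
    if token == NO4SU_TOKEN or token.lower() == NO4SU_TOKEN.lower():
        return 0.0, True
    m = _DURATION_RE.match(token)
    if not m:
        raise ValueError(f"unparseable labeling duration token {token!r}")
    value = float(m.group(1))
    unit = m.group(2).lower()
    if unit in ("min", "m"):
        value /= 60.0
    return value, False


def parse_systematic_names(
    names: Sequence[str],
    field_semantics: Sequence[str],
    separator: str = ".",
) -> list[SampleDesign]:
    """Parse systematic sample names (e.g. ``"mock.2h.A"``) into designs.

    ``field_semantics`` assigns a role to each separator-delimited field; one
    role must be ``"duration"`` (values like ``"2h"``, ``"30min"`` or
    ``"no4sU"``), the roles ``"condition"`` and ``"replicate"`` are copied to
    the corresponding fields and any other role is stored verbatim in
    ``extra``.
    """
    if "duration" not in field_semantics:
        raise ValueError("field_semantics must contain the role 'duration'")
    designs = []
    for idx, name in enumerate(names):
        fields = name.split(separator)
        if len(fields) != len(field_semantics):
            raise ValueError(
                f"sample name {name!r} (index {idx}) splits into {len(fields)} "
                f"fields on {separator!r}, expected {len(field_semantics)}"
            )
        kw: dict = {"name": name, "extra": {}}
        for role, value in zip(field_semantics, fields):
            if role == "duration":
                try:
                    hours, naive = parse_duration(value)
                except ValueError as err:
                    raise ValueError(f"sample name {name!r} (index {idx}): {err}") from None
                kw["labeling_time_nominal"] = hours
                kw["is_no4sU"] = naive
            elif role == "condition":
                kw["condition"] = value
            elif role == "replicate":
                kw["replicate"] = value
            else:
                kw["extra"][role] = value
        designs.append(SampleDesign(**kw))
    seen = set()
    for d in designs:
        if d.name in seen:
            raise ValueError(f"duplicate sample name {d.name!r}")
        seen.add(d.name)
    return designs


@dataclass
class GeneKinetics:
    """First-order RNA kinetics da/dt = sigma - delta * a(t).

    ``sigma`` is the synthesis rate (abundance units / h), ``delta`` the
    degradation rate constant (1/h) and ``a0`` the abundance at the start of
    labeling.  The half-life is ln(2)/delta.  Fields may be scalars or
    per-gene arrays.
    """

    sigma: np.ndarray | float
    delta: np.ndarray | float
    a0: np.ndarray | float | None = None

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.delta) <= 0):
            raise ValueError("degradation rate delta must be > 0")
        if np.any(np.asarray(self.sigma) < 0):
            raise ValueError("synthesis rate sigma must be >= 0")
        if self.a0 is None:
            # steady state: a0 = sigma / delta
            self.a0 = np.asarray(self.sigma) / np.asarray(self.delta)

    @property
    def halflife(self) -> np.ndarray | float:
        return math.log(2) / np.asarray(self.delta)

    @property
    def steady_state(self) -> np.ndarray | float:
        return np.asarray(self.sigma) / np.asarray(self.delta)


class ExperimentData:
    """Genes x samples container with named data slots.

    The required slot ``"count"`` holds raw (or simulated) expression values;
    optional slots ``"ntr"``, ``"alpha"``, ``"beta"`` hold the NTR MAP
    estimates and the shapes of the Beta posterior approximation, and
    ``"norm"`` holds size-factor normalized counts once :func:`normalize` has
    been applied.  All slot matrices share the same (n_genes, n_samples)
    shape.
    """

    def __init__(
        self,
        gene_ids: Sequence[str],
        samples: Sequence[SampleDesign],
        slots: Mapping[str, np.ndarray],
        symbols: Sequence[str] | None = None,
    ):
        self.gene_ids = list(gene_ids)
        self.samples = list(samples)
        self.symbols = list(symbols) if symbols is not None else list(gene_ids)
        names = [s.name for s in self.samples]
        if len(set(names)) != len(names):
            raise ValueError("sample names must be unique")
        self.slots: dict[str, np.ndarray] = {}
        if "count" not in slots:
            raise ValueError("required slot 'count' missing")
        shape = (len(self.gene_ids), len(self.samples))
        for key, mat in slots.items():
            arr = np.asarray(mat, dtype=float)
            if arr.shape != shape:
                raise ValueError(
                    f"slot {key!r} has shape {arr.shape}, expected {shape}"
                )
            self.slots[key] = arr.copy()
        self._validate()

    def _validate(self) -> None:
        if np.any(self.slots["count"] < 0):
            raise ValueError("counts must be non-negative")
        ntr = self.slots.get("ntr")
        if ntr is not None:
            finite = np.isfinite(ntr)
            if np.any((ntr[finite] < 0) | (ntr[finite] > 1)):
                raise ValueError("NTR values must lie in [0, 1]")
        for key in ("alpha", "beta"):
            mat = self.slots.get(key)
            if mat is not None and np.any(mat[np.isfinite(mat)] <= 0):
                raise ValueError(f"slot {key!r} must be positive where present")

    # -- basic introspection ------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_names(self) -> list[str]:
        return [s.name for s in self.samples]

    def sample_index(self, name: str) -> int:
        try:
            return self.sample_names.index(name)
        except ValueError:
            raise KeyError(f"no sample named {name!r}") from None

    def expression(self) -> np.ndarray:
        """Normalized counts if available, raw counts otherwise."""
        return self.slots.get("norm", self.slots["count"])

    # -- derived quantities -------------------------------------------------
    def labeling_times(self, effective: bool = True) -> np.ndarray:
        if effective:
            return np.array([s.labeling_time_effective for s in self.samples])
        return np.array([s.labeling_time_nominal for s in self.samples])

    def new_counts(self) -> np.ndarray:
        """Newly synthesized RNA N_k = C_k * NTR_k (NaN for no4sU samples)."""
        return self.expression() * self.slots["ntr"]

    def old_counts(self) -> np.ndarray:
        """Pre-existing RNA O_k = C_k * (1 - NTR_k); for no4sU samples the
        whole expression is old RNA."""
        ntr = self.slots["ntr"].copy()
        for j, s in enumerate(self.samples):
            if s.is_no4sU:
                ntr[:, j] = 0.0
        return self.expression() * (1.0 - ntr)

    # -- subsetting ---------------------------------------------------------
    def subset_genes(self, mask: np.ndarray) -> "ExperimentData":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.nonzero(mask)[0]
        else:
            idx = mask
        return ExperimentData(
            [self.gene_ids[i] for i in idx],
            [replace(s) for s in self.samples],
            {k: v[idx, :] for k, v in self.slots.items()},
            symbols=[self.symbols[i] for i in idx],
        )

    def subset_samples(self, names: Sequence[str]) -> "ExperimentData":
        idx = [self.sample_index(n) for n in names]
        return ExperimentData(
            self.gene_ids,
            [replace(self.samples[i]) for i in idx],
            {k: v[:, idx] for k, v in self.slots.items()},
            symbols=self.symbols,
        )

    def copy(self) -> "ExperimentData":
        return ExperimentData(
            self.gene_ids,
            [replace(s) for s in self.samples],
            dict(self.slots),
            symbols=self.symbols,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ExperimentData({self.n_genes} genes x {self.n_samples} samples, "
            f"slots={sorted(self.slots)})"
        )


def compute_size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (DESeq-style).

    The reference per gene is the geometric mean across samples; genes with a
    zero in any sample are excluded from the reference set.  The factor of a
    sample is the median over reference genes of count / geometric mean.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be a genes x samples matrix")
    positive = np.all(counts > 0, axis=1)
    if not np.any(positive):
        raise ValueError(
            "no gene has positive counts in every sample; "
            "filter genes before computing size factors"
        )
    ref = counts[positive, :]
    log_geo = np.mean(np.log(ref), axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(ref) - log_geo, axis=0))
    return factors


def normalize(data: ExperimentData, factors: np.ndarray | None = None) -> ExperimentData:
    """Divide counts by per-sample size factors, filling the ``"norm"`` slot.

    NTR, alpha and beta slots are untouched: the NTR is a ratio and therefore
    scale-free.  When ``factors`` is omitted, median-of-ratios factors are
    computed from the count slot.
    """
    if factors is None:
        factors = compute_size_factors(data.slots["count"])
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (data.n_samples,):
        raise ValueError("one size factor per sample required")
    if np.any(factors <= 0):
        raise ValueError("size factors must be strictly positive")
    out = data.copy()
    out.slots["norm"] = data.slots["count"] / factors[None, :]
    return out


def filter_genes(
    data: ExperimentData, min_count: float = 0.0, min_samples: int = 1
) -> ExperimentData:
    """Keep genes with count >= min_count in at least min_samples samples."""
    if min_count < 0 or min_samples < 0:
        raise ValueError("thresholds must be >= 0")
    keep = np.sum(data.slots["count"] >= min_count, axis=1) >= min_samples
    if not np.any(keep):
        warnings.warn("gene filter removed all genes", stacklevel=2)
    return data.subset_genes(keep)
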