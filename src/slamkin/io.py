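"""Tab-separated readers and writers.

Two dialects are supported:

* the gene-level table written by nucleotide-conversion read processors:
  columns ``Gene``, ``Symbol``, then per sample ``<name> Readcount``,
  ``<name> alpha``, ``<name> beta``, ``<name> MAP`` (header-driven and
  order-insensitive);
* paired plain count matrices (total + labeled) with a separate design table
  (columns ``name``, ``condition``, ``time_h``, ``replicate``, ``no4sU``).

All writers prepend ``#key=value`` provenance comment lines (version, seed,
config hash); readers skip comment lines.  Dialect: tab delimiter, '.'
decimal separator, UTF-8.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .version import __version__
from .datamodel import ExperimentData, SampleDesign, parse_systematic_names
from .ntrquant import ReadStats

__all__ = [
    "read_grandslam_table",
    "write_grandslam_table",
    "read_count_matrices",
    "write_read_stats",
    "read_read_stats",
    "write_design_table",
    "read_design_table",
    "provenance_header",
    "read_provenance",
]

_SUFFIXES = {" Readcount": "count", " alpha": "alpha", " beta": "beta",
             " MAP": "ntr"}
_FLOAT_FMT = "%.10g"


def provenance_header(seed: int | None = None, config: dict | None = None) -> str:
    lines = [f"#version={__version__}"]
    if seed is not None:
        lines.append(f"#seed={seed}")
    if config is not None:
        blob = json.dumps(config, sort_keys=True, default=str)
        lines.append(f"#config_hash={hashlib.sha256(blob.encode()).hexdigest()[:16]}")
    return "\n".join(lines) + "\n"


def read_provenance(path: str | Path) -> dict:
    """Parse leading #key=value comment lines of a written table."""
    out: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, _, val = line[1:].strip().partition("=")
                out[key] = val
    return out


def write_grandslam_table(
    data: ExperimentData,
    path: str | Path,
    seed: int | None = None,
    config: dict | None = None,
) -> None:
    """Write the per-sample Readcount/alpha/beta/MAP gene table."""
    cols: dict[str, object] = {"Gene": data.gene_ids, "Symbol": data.symbols}
    for j, s in enumerate(data.samples):
        cols[f"{s.name} Readcount"] = data.slots["count"][:, j]
        for slot, suffix in (("alpha", "alpha"), ("beta", "beta"), ("ntr", "MAP")):
            if slot in data.slots:
                cols[f"{s.name} {suffix}"] = data.slots[slot][:, j]
    df = pd.DataFrame(cols)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(provenance_header(seed, config))
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_grandslam_table(
    path: str | Path,
    field_semantics: list[str] | None = None,
    separator: str = ".",
    designs: list[SampleDesign] | None = None,
) -> ExperimentData:
    """Read the gene table back into an ExperimentData.

    Sample names are parsed with ``parse_systematic_names`` when
    ``field_semantics`` is given; otherwise explicit ``designs`` may be
    supplied, or bare designs (no metadata) are created.  Missing alpha/beta
    columns disable the Bayesian slots with a warning from the caller's side;
    NTR values outside [0, 1] are rejected with the offending row.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if "Gene" not in df.columns:
        raise ValueError("missing required column 'Gene'")
    sample_names: list[str] = []
    slot_cols: dict[str, dict[str, str]] = {v: {} for v in _SUFFIXES.values()}
    for col in df.columns:
        for suffix, slot in _SUFFIXES.items():
            if col.endswith(suffix):
                name = col[: -len(suffix)]
                if name not in sample_names:
                    sample_names.append(name)
                slot_cols[slot][name] = col
    if not sample_names:
        raise ValueError("no per-sample 'Readcount' columns found")
    missing = [n for n in sample_names if n not in slot_cols["count"]]
    if missing:
        raise ValueError(f"missing 'Readcount' columns for samples {missing}")

    if designs is None:
        if field_semantics is not None:
            designs = parse_systematic_names(sample_names, field_semantics,
                                             separator)
        else:
            designs = [SampleDesign(name=n, is_no4sU=True) for n in sample_names]
    slots: dict[str, np.ndarray] = {}
    for slot, mapping in slot_cols.items():
        if len(mapping) == len(sample_names):
            mat = np.column_stack(
                [pd.to_numeric(df[mapping[n]], errors="coerce").to_numpy()
                 for n in sample_names]
            )
            slots[slot] = mat
        elif mapping and slot != "count":
            raise ValueError(
                f"columns for slot {slot!r} present for only a subset of "
                f"samples: {sorted(mapping)}"
            )
    if "alpha" not in slots or "beta" not in slots:
        warnings.warn(
            "table lacks alpha/beta columns; Bayesian features are disabled",
            stacklevel=2,
        )
    ntr = slots.get("ntr")
    if ntr is not None:
        bad = np.nonzero(np.nan_to_num(ntr, nan=0.5) > 1.0)
        bad2 = np.nonzero(np.nan_to_num(ntr, nan=0.5) < 0.0)
        if bad[0].size or bad2[0].size:
            row = int((bad[0] if bad[0].size else bad2[0])[0])
            raise ValueError(f"NTR outside [0, 1] at table row {row}")
    symbols = df["Symbol"].astype(str).tolist() if "Symbol" in df.columns else None
    return ExperimentData(df["Gene"].astype(str).tolist(), designs, slots,
                          symbols=symbols)


def write_read_stats(stats: dict[str, "ReadStats"], path: str | Path) -> None:
    """Serialize per-gene (u, tc) sufficient statistics as TSV.

    Columns: gene, u, tc, n_reads (one row per distinct (u, tc) cell).
    """
    rows = []
    for gene, rs in stats.items():
        for u, tc, m in zip(rs.u, rs.tc, rs.mult):
            rows.append({"gene": gene, "u": int(u), "tc": int(tc),
                         "n_reads": int(m)})
    pd.DataFrame(rows, columns=["gene", "u", "tc", "n_reads"]).to_csv(
        path, sep="\t", index=False)


def read_read_stats(path: str | Path) -> dict[str, "ReadStats"]:
    """Read per-gene (u, tc) sufficient statistics written by
    :func:`write_read_stats`."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"gene", "u", "tc", "n_reads"} - set(df.columns)
    if missing:
        raise ValueError(f"read-stats table lacks columns {sorted(missing)}")
    out: dict[str, ReadStats] = {}
    for gene, sub in df.groupby("gene", sort=False):
        out[str(gene)] = ReadStats(
            {(int(r.u), int(r.tc)): int(r.n_reads) for r in sub.itertuples()})
    return out


def write_design_table(data: ExperimentData, path: str | Path) -> None:
    rows = [
        {
            "name": s.name,
            "condition": s.condition,
            "time_h": s.labeling_time_nominal,
            "replicate": s.replicate,
            "no4sU": s.is_no4sU,
        }
        for s in data.samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_design_table(path: str | Path) -> list[SampleDesign]:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"name", "condition", "time_h", "replicate", "no4sU"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design table lacks columns {sorted(missing)}")
    return [
        SampleDesign(
            name=str(r["name"]),
            condition=str(r["condition"]),
            labeling_time_nominal=float(r["time_h"]),
            replicate=str(r["replicate"]),
            is_no4sU=bool(r["no4sU"]),
        )
        for _, r in df.iterrows()
    ]


def read_count_matrices(
    total_path: str | Path,
    labeled_path: str | Path,
    design_path: str | Path,
) -> ExperimentData:
    """Build an experiment from total + labeled count matrices and a design.

    The matrices are gene x sample TSVs with a leading gene-id column; the
    NTR slot is derived as labeled/total (NaN where total is 0 or the sample
    is 4sU-naive).
    """
    designs = read_design_table(design_path)
    total = pd.read_csv(total_path, sep="\t", comment="#", index_col=0)
    labeled = pd.read_csv(labeled_path, sep="\t", comment="#", index_col=0)
    names = [d.name for d in designs]
    if list(total.columns) != names or list(labeled.columns) != names:
        total = total[names]
        labeled = labeled[names]
    counts = total.to_numpy(dtype=float)
    lab = labeled.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ntr = np.where(counts > 0, lab / counts, np.nan)
    for j, d in enumerate(designs):
        if d.is_no4sU:
            ntr[:, j] = np.nan
    return ExperimentData(total.index.astype(str).tolist(), designs,
                          {"count": counts, "ntr": ntr})
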