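"""From raw digest reads to per-sequence accessibility proportions.

Sequencing reads from the DpnI and DpnII digests are matched back to the
designed library (reads are reverse complements of the construct, so the
first N nucleotides of the reverse complement of a read are the variable
sequence; only perfect matches count). Counts are normalized to reads per
million within each digest, sequences with too few total reads are dropped
(proportion estimates are noisy at low coverage), and accessibility is the
Dpn proportion DpnII / (DpnI + DpnII) per (sequence, condition, replicate).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .design import DesignedSequence

__all__ = [
    "match_and_count",
    "normalize_rpm",
    "filter_low_coverage",
    "dpn_proportion",
    "accessibility_table",
    "coverage_diagnostic",
]

RPM_SCALE = 1_000_000.0


def match_and_count(
    reads: list[str],
    library: list[DesignedSequence],
    variable_length: int,
) -> tuple[dict[str, int], int]:
    """Assign reads to library sequences by exact match.

    Each read's reverse complement is truncated to ``variable_length`` nt
    and looked up against the library's variable sequences; only perfect
    matches are counted. Returns (counts per design id, unassigned reads).
    """
    ids = [d.id for d in library]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate design ids in library")
    lookup: dict[str, str] = {}
    collisions = []
    for d in library:
        v = d.variable_seq.upper()
        if v in lookup:
            collisions.append((lookup[v], d.id))
        lookup[v] = d.id
    if collisions:
        raise ValueError(f"duplicate variable sequences (ambiguous): {collisions}")

    counts = {d.id: 0 for d in library}
    unassigned = 0
    for read in reads:
        if len(read) < variable_length:
            unassigned += 1
            continue
        key = str(Seq(read).reverse_complement())[:variable_length].upper()
        hit = lookup.get(key)
        if hit is None:
            unassigned += 1
        else:
            counts[hit] += 1
    return counts, unassigned


def normalize_rpm(raw: pd.DataFrame) -> pd.DataFrame:
    """Add reads-per-million within each (condition, replicate, digest).

    A digest with zero total reads keeps rpm 0 for all its sequences.
    """
    required = {"sequence_id", "condition", "replicate", "digest", "raw_count"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    out = raw.copy()
    totals = out.groupby(["condition", "replicate", "digest"])["raw_count"].transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        out["rpm"] = np.where(
            totals > 0, out["raw_count"] * RPM_SCALE / totals, 0.0
        )
    return out


def dpn_proportion(dpnii_rpm: float, dpni_rpm: float) -> float:
    """Accessibility estimate DpnII / (DpnI + DpnII); NaN when both are 0."""
    if dpnii_rpm < 0 or dpni_rpm < 0:
        raise ValueError("rpm values must be >= 0")
    total = dpnii_rpm + dpni_rpm
    if total == 0:
        return float("nan")
    return dpnii_rpm / total


def filter_low_coverage(table: pd.DataFrame, min_total_rpm: float) -> pd.Series:
    """Per-sequence filter flag: total rpm over all replicates and digests.

    The threshold trades noise for retention (proportion estimates have
    high standard deviation at low totals); see ``coverage_diagnostic`` for
    choosing it. Returns a boolean Series indexed by sequence_id.
    """
    if min_total_rpm < 0:
        raise ValueError("min_total_rpm must be >= 0")
    if "rpm" not in table.columns:
        raise ValueError("run normalize_rpm first")
    totals = table.groupby("sequence_id")["rpm"].sum()
    return totals >= min_total_rpm


def accessibility_table(
    table: pd.DataFrame,
    min_total_rpm: float = 0.0,
) -> pd.DataFrame:
    """Dpn proportion per (sequence, condition, replicate), post filter.

    Output columns: sequence_id, condition, replicate, dpn_proportion,
    passed_filter. Proportions are computed from rpm; rows where both
    digests are zero get NaN; sequences failing the coverage filter keep
    their flag but carry NaN proportions so they cannot leak downstream.
    """
    passed = filter_low_coverage(table, min_total_rpm)
    wide = (
        table.pivot_table(
            index=["sequence_id", "condition", "replicate"],
            columns="digest",
            values="rpm",
            aggfunc="sum",
            fill_value=0.0,
        )
        .reindex(columns=["DpnI", "DpnII"], fill_value=0.0)
        .reset_index()
    )
    total = wide["DpnI"] + wide["DpnII"]
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(total > 0, wide["DpnII"] / total, np.nan)
    out = wide[["sequence_id", "condition", "replicate"]].copy()
    out["dpn_proportion"] = prop
    out["passed_filter"] = out["sequence_id"].map(passed).fillna(False).astype(bool)
    out.loc[~out["passed_filter"], "dpn_proportion"] = np.nan
    return out


def coverage_diagnostic(table: pd.DataFrame, n_bins: int = 20) -> pd.DataFrame:
    """SD of Dpn proportion vs. total rpm, binned — to pick the filter.

    Bins sequences by total rpm (quantile bins) and reports the standard
    deviation of per-replicate proportions within each bin; the filter
    threshold is typically set where the SD stops inflating.
    """
    acc = accessibility_table(table, min_total_rpm=0.0)
    totals = table.groupby("sequence_id")["rpm"].sum().rename("total_rpm")
    merged = acc.merge(totals, on="sequence_id")
    merged = merged.dropna(subset=["dpn_proportion"])
    merged["bin"] = pd.qcut(merged["total_rpm"], q=n_bins, duplicates="drop")
    diag = (
        merged.groupby("bin", observed=True)
        .agg(
            mean_total_rpm=("total_rpm", "mean"),
            proportion_sd=("dpn_proportion", "std"),
            n=("dpn_proportion", "size"),
        )
        .reset_index(drop=True)
    )
    return diag
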