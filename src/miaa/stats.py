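"""Two-stage paired differential-accessibility statistics.

A motif (or arrangement) is called differentially accessible when it passes
two paired tests across its panel of neutral backgrounds, each under
Benjamini-Hochberg FDR control within its own family:

stage 1
    paired test of openness between the two cell conditions (one paired
    observation per background, replicate proportions averaged first);
stage 2
    paired test of designed sequences against their nucleotide-shuffled
    controls within a condition, which separates motif content from
    composition.

Group-level rank-sum, hypergeometric enrichment and orientation chi-square
tests used for region-set analyses live here as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MotifTestResult",
    "paired_condition_test",
    "control_paired_test",
    "bh_adjust",
    "classify_differential",
    "group_ranksum_test",
    "categorical_enrichment_test",
    "orientation_chisq",
]

_METHODS = ("paired_t", "wilcoxon_signed_rank")


@dataclass
class MotifTestResult:
    """Two-stage test outcome for one motif or arrangement."""

    motif_or_arrangement_id: str
    n_backgrounds: int
    effect_condition_diff: float
    effect_vs_shuffle: dict[str, float] = field(default_factory=dict)
    p_condition: float = np.nan
    p_shuffle: dict[str, float] = field(default_factory=dict)
    q_condition: float = np.nan
    q_shuffle: dict[str, float] = field(default_factory=dict)
    is_differential: bool = False
    direction: str = ""


def _paired(values_a, values_b, method: str) -> tuple[float, float]:
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-d and of equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 paired observations")
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}")
    diff = b - a
    effect = float(diff.mean())
    if np.allclose(diff, 0.0):
        return effect, 1.0
    if method == "paired_t":
        res = sps.ttest_rel(b, a)
    else:
        res = sps.wilcoxon(b, a, zero_method="wilcox")
    p = float(res.pvalue)
    if np.isnan(p):  # zero-variance nonzero diffs under t: treat as extreme
        p = 0.0
    return effect, p


def paired_condition_test(
    openness_a,
    openness_b,
    method: str = "paired_t",
) -> tuple[float, float]:
    """Stage-1 test: condition B vs condition A openness across backgrounds.

    Inputs are paired per background (replicates pre-averaged); the effect
    is mean(B - A) and the p-value two-sided. Identical vectors return
    p = 1 by the degenerate-case policy.
    """
    return _paired(openness_a, openness_b, method)


def control_paired_test(
    design_openness,
    shuffle_openness,
    method: str = "paired_t",
) -> tuple[float, float]:
    """Stage-2 test: designed sequences vs their shuffled controls.

    Pairing unit is the background; the effect is mean(design - shuffle)
    within one condition.
    """
    return _paired(shuffle_openness, design_openness, method)


def bh_adjust(p_values, fdr: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: q-values and rejection flags (q < fdr)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q, q < fdr


def classify_differential(
    stage1: pd.DataFrame,
    stage2: pd.DataFrame,
    fdr: float = 0.05,
) -> list[MotifTestResult]:
    """Combine the two stages into differential calls under per-stage BH.

    ``stage1`` needs columns (motif_id, n_backgrounds, effect, p); ``stage2``
    (motif_id, condition, effect, p). BH runs within each stage's family
    (stage 2: one family across all motif x condition tests). A motif is
    differential iff its stage-1 test and at least one of its stage-2 tests
    are both rejected; direction is the sign of the stage-1 effect.
    """
    s1 = stage1.reset_index(drop=True)
    s2 = stage2.reset_index(drop=True)
    q1, rej1 = bh_adjust(s1["p"].to_numpy(), fdr)
    if len(s2):
        q2, rej2 = bh_adjust(s2["p"].to_numpy(), fdr)
    else:
        q2, rej2 = np.array([]), np.array([], dtype=bool)
    s1 = s1.assign(q=q1, rejected=rej1)
    s2 = s2.assign(q=q2, rejected=rej2)

    results = []
    for row in s1.itertuples():
        sub = s2[s2["motif_id"] == row.motif_id]
        any_shuffle = bool(sub["rejected"].any()) if len(sub) else False
        results.append(
            MotifTestResult(
                motif_or_arrangement_id=row.motif_id,
                n_backgrounds=int(row.n_backgrounds),
                effect_condition_diff=float(row.effect),
                effect_vs_shuffle=dict(zip(sub["condition"], sub["effect"])),
                p_condition=float(row.p),
                p_shuffle=dict(zip(sub["condition"], sub["p"])),
                q_condition=float(row.q),
                q_shuffle=dict(zip(sub["condition"], sub["q"])),
                is_differential=bool(row.rejected) and any_shuffle,
                direction="up" if row.effect > 0 else ("down" if row.effect < 0 else ""),
            )
        )
    return results


def group_ranksum_test(group1, group2) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value."""
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if len(g1) < 1 or len(g2) < 1:
        raise ValueError("both groups need at least one value")
    return float(sps.mannwhitneyu(g1, g2, alternative="two-sided").pvalue)


def categorical_enrichment_test(
    hits_in_set: int,
    set_size: int,
    hits_in_universe: int,
    universe_size: int,
) -> float:
    """Upper-tail hypergeometric enrichment p-value.

    Probability of observing at least ``hits_in_set`` marked elements in a
    sample of ``set_size`` drawn without replacement from a universe of
    ``universe_size`` containing ``hits_in_universe`` marked elements.
    """
    if not (
        0 <= hits_in_set <= set_size <= universe_size
        and hits_in_set <= hits_in_universe <= universe_size
    ):
        raise ValueError("inconsistent counts for hypergeometric test")
    return float(sps.hypergeom.sf(hits_in_set - 1, universe_size, hits_in_universe, set_size))


def orientation_chisq(orientation_counts) -> float:
    """Chi-square goodness of fit of dimer-orientation counts vs uniform.

    ``orientation_counts`` are the four counts for the -/+, +/-, +/+ and
    -/- motif dimer orientations.
    """
    counts = np.asarray(orientation_counts, dtype=float)
    if counts.shape != (4,):
        raise ValueError("expected exactly 4 orientation counts")
    if np.any(counts < 0):
        raise ValueError("counts must be >= 0")
    if counts.sum() == 0:
        raise ValueError("total count must be > 0")
    return float(sps.chisquare(counts).pvalue)
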