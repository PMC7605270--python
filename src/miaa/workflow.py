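"""End-to-end helpers wiring the pipeline stages together."""

from __future__ import annotations

import pandas as pd

from .design import DesignedSequence
from .regression import motif_unit
from .stats import (
    MotifTestResult,
    classify_differential,
    control_paired_test,
    paired_condition_test,
)

__all__ = ["average_replicates", "two_stage_tests"]


def average_replicates(accessibility: pd.DataFrame) -> pd.DataFrame:
    """Mean Dpn proportion per (sequence, condition) across replicates."""
    return (
        accessibility.dropna(subset=["dpn_proportion"])
        .groupby(["sequence_id", "condition"], as_index=False)["dpn_proportion"]
        .mean()
    )


def two_stage_tests(
    accessibility: pd.DataFrame,
    designs: list[DesignedSequence],
    condition_a: str = "ESC",
    condition_b: str = "DE",
    fdr: float = 0.05,
    method: str = "paired_t",
    min_backgrounds: int = 3,
) -> list[MotifTestResult]:
    """Two-stage differential calls for every motif unit in a library.

    Stage 1 pairs condition B against condition A per background (replicate
    proportions averaged first); stage 2 pairs each design against its
    shuffled control within each condition. BH correction runs within each
    stage's family and a motif is differential only if both stages reject.
    """
    by_id = {d.id: d for d in designs}
    avg = average_replicates(accessibility)
    openness = {(r.sequence_id, r.condition): r.dpn_proportion for r in avg.itertuples()}

    groups: dict[str, list[DesignedSequence]] = {}
    for d in designs:
        unit = motif_unit(d)
        if unit is not None and d.design_class != "shuffle_control":
            groups.setdefault(unit, []).append(d)

    stage1_rows, stage2_rows = [], []
    for unit, members in sorted(groups.items()):
        a_vals, b_vals = [], []
        shuffle_vals: dict[str, tuple[list[float], list[float]]] = {
            condition_a: ([], []),
            condition_b: ([], []),
        }
        for d in members:
            ka, kb = (d.id, condition_a), (d.id, condition_b)
            if ka in openness and kb in openness:
                a_vals.append(openness[ka])
                b_vals.append(openness[kb])
            partner = d.shuffle_partner_id
            if partner and partner in by_id:
                for cond in (condition_a, condition_b):
                    kd, ks = (d.id, cond), (partner, cond)
                    if kd in openness and ks in openness:
                        shuffle_vals[cond][0].append(openness[kd])
                        shuffle_vals[cond][1].append(openness[ks])
        if len(a_vals) < min_backgrounds:
            continue
        effect, p = paired_condition_test(a_vals, b_vals, method=method)
        stage1_rows.append(
            {"motif_id": unit, "n_backgrounds": len(a_vals), "effect": effect, "p": p}
        )
        for cond, (dvals, svals) in shuffle_vals.items():
            if len(dvals) >= min_backgrounds:
                eff2, p2 = control_paired_test(dvals, svals, method=method)
                stage2_rows.append(
                    {"motif_id": unit, "condition": cond, "effect": eff2, "p": p2}
                )

    stage1 = pd.DataFrame(stage1_rows, columns=["motif_id", "n_backgrounds", "effect", "p"])
    stage2 = pd.DataFrame(stage2_rows, columns=["motif_id", "condition", "effect", "p"])
    return classify_differential(stage1, stage2, fdr=fdr)
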