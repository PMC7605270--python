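"""Synthetic MIAA data with known ground truth.

Emulates the accessibility reporter readout end to end: neutral background
sequences, per-sequence DpnI/DpnII restriction-digest count tables with a
known generative model, and labeled 100-nt sequence sets for training the
accessibility CNN. Every downstream stage of the pipeline can therefore be
tested against recorded truth without any external data.

Generative model
----------------
True openness of sequence *s* in condition *c* (and replicate *r*) is

    p(s, c, r) = floor + (ceiling - floor) *
                 logistic( gc_slope_c * (GC(s) - 0.5)
                           + sum_m effect(m, c) * copies(m, s)
                           + b(c, r) )

where ``floor`` is the residual methylation of closed chromatin (negative
controls in the assay sit near 20-50% methylation; default 0.2), ``ceiling``
the methylation of fully open chromatin (around 95% at strong activator
binding sites; default 0.95), and ``b(c, r) ~ N(0, replicate_sd)`` is a
batch effect drawn once per (condition, replicate) and shared across
sequences. Library abundance per sequence is Gamma with mean 1 and the
configured dispersion; DpnII counts are Poisson with mean
``abundance * depth * p`` and DpnI counts Poisson with mean
``abundance * depth * (1 - p)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignedSequence, gc_content, scan_motif

__all__ = [
    "GroundTruthModel",
    "LabeledSequenceSet",
    "SimulatedCounts",
    "generate_backgrounds",
    "simulate_miaa_readcounts",
    "generate_labeled_training_set",
    "logistic",
]


def logistic(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass
class GroundTruthModel:
    """Generative parameters for simulated MIAA count tables.

    ``motif_effects`` maps (motif_id, condition) to an additive effect on
    the logit openness scale, applied once per placed copy of the motif.
    """

    floor: float = 0.2
    ceiling: float = 0.95
    gc_slope_per_condition: dict[str, float] = field(default_factory=dict)
    motif_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    replicate_sd: float = 0.0
    abundance_dispersion: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.floor < self.ceiling <= 1.0:
            raise ValueError("require 0 <= floor < ceiling <= 1")
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be >= 0")
        if self.abundance_dispersion <= 0:
            raise ValueError("abundance_dispersion must be > 0")

    def known_motifs(self) -> set[str]:
        return {m for m, _ in self.motif_effects}


@dataclass
class LabeledSequenceSet:
    """Fixed-length sequences with (open-in-ESC, open-in-DE) bit labels."""

    sequences: list[str]
    labels: np.ndarray  # shape (n, 2), dtype int
    class_counts: dict[int, int]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("sequences must have identical length")
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.sequences), 2):
            raise ValueError("labels must be (n, 2)")


@dataclass
class SimulatedCounts:
    """A simulated count table plus its ground-truth openness sidecar.

    ``counts`` has one row per (sequence_id, condition, replicate, digest)
    with the raw count; ``truth`` one row per (sequence_id, condition) with
    the replicate-noise-free true openness ``true_p``.
    """

    counts: pd.DataFrame
    truth: pd.DataFrame


def generate_backgrounds(
    n_native: int,
    length: int,
    gc_targets: list[float],
    seed: int,
) -> list[str]:
    """Random neutral background sequences at target GC fractions.

    Stands in for native genomic sequences screened to be accessibility
    neutral: each output is a uniformly random sequence whose GC count is
    the target fraction rounded to the nearest achievable integer (always
    within 0.005 of target at length 100; targets further than 0.05 from
    any achievable fraction are rejected).
    """
    if n_native < 1:
        raise ValueError("n_native must be >= 1")
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    for i in range(n_native):
        target = gc_targets[i % len(gc_targets)]
        if not 0.0 < target < 1.0:
            raise ValueError(f"gc_target {target} outside (0, 1)")
        n_gc = round(target * length)
        if abs(n_gc / length - target) > 0.05:
            raise ValueError(
                f"gc_target {target} unreachable within 0.05 at length {length}"
            )
        bases = np.concatenate([
            rng.choice(["G", "C"], size=n_gc),
            rng.choice(["A", "T"], size=length - n_gc),
        ])
        rng.shuffle(bases)
        out.append("".join(bases))
    return out


def true_openness(
    design: DesignedSequence,
    truth: GroundTruthModel,
    condition: str,
    replicate_effect: float = 0.0,
) -> float:
    """Ground-truth openness of a design under the generative model."""
    known = truth.known_motifs()
    z = truth.gc_slope_per_condition.get(condition, 0.0) * (design.gc - 0.5)
    for motif_id, copies in design.motif_copy_counts().items():
        if motif_id not in known:
            raise ValueError(f"design {design.id} uses unknown motif {motif_id!r}")
        z += truth.motif_effects.get((motif_id, condition), 0.0) * copies
    z += replicate_effect
    return truth.floor + (truth.ceiling - truth.floor) * float(logistic(z))


def simulate_miaa_readcounts(
    designs: list[DesignedSequence],
    truth: GroundTruthModel,
    conditions: list[str],
    replicates_per_condition: int | dict[str, int],
    mean_depth: float,
    seed: int,
) -> SimulatedCounts:
    """Simulate a DpnI/DpnII read-count table for a designed library.

    ``replicates_per_condition`` may be a single integer or a mapping per
    condition (the assay's standard design uses 8 ESC and 4 DE biological
    replicates). Per-sequence abundance is Gamma-distributed with mean 1
    and shape ``1 / abundance_dispersion``; digest counts are Poisson, so
    expected total reads per (sequence, replicate, digest pair) equal
    ``abundance * mean_depth`` irrespective of openness.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    if isinstance(replicates_per_condition, int):
        reps = {c: replicates_per_condition for c in conditions}
    else:
        reps = dict(replicates_per_condition)
    if any(reps.get(c, 0) < 1 for c in conditions):
        raise ValueError("need >= 1 replicate per condition")

    rng = np.random.default_rng(seed)
    shape = 1.0 / truth.abundance_dispersion
    abundance = rng.gamma(shape, scale=1.0 / shape, size=len(designs))

    rep_effect = {
        (c, r): (rng.normal(0.0, truth.replicate_sd) if truth.replicate_sd > 0 else 0.0)
        for c in conditions
        for r in range(1, reps[c] + 1)
    }

    count_rows: list[tuple] = []
    truth_rows: list[tuple] = []
    for i, design in enumerate(designs):
        for c in conditions:
            truth_rows.append((design.id, c, true_openness(design, truth, c)))
            for r in range(1, reps[c] + 1):
                p = true_openness(design, truth, c, rep_effect[(c, r)])
                lam = abundance[i] * mean_depth
                dpnii = rng.poisson(lam * p)
                dpni = rng.poisson(lam * (1.0 - p))
                count_rows.append((design.id, c, r, "DpnII", int(dpnii)))
                count_rows.append((design.id, c, r, "DpnI", int(dpni)))

    counts = pd.DataFrame(
        count_rows,
        columns=["sequence_id", "condition", "replicate", "digest", "raw_count"],
    )
    truth_df = pd.DataFrame(truth_rows, columns=["sequence_id", "condition", "true_p"])
    return SimulatedCounts(counts=counts, truth=truth_df)


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def generate_labeled_training_set(
    motif_esc: str,
    motif_de: str,
    motif_shared: str,
    n_per_class: int,
    length: int = 100,
    seed: int = 0,
) -> LabeledSequenceSet:
    """Balanced four-class sequence set for accessibility CNN training.

    Classes mirror the four openness scenarios of a sequence across the two
    cell types: (1) open in DE only — carries ``motif_de``; (2) open in ESC
    only — carries ``motif_esc``; (3) open in both — carries
    ``motif_shared``; (4) closed in both — carries no planted motif. The
    planted motif is written at a uniformly random position over a random
    background that is rejection-sampled to contain no exact match to any
    of the three motifs; labels are (open_in_ESC, open_in_DE) bits.
    """
    for m in (motif_esc, motif_de, motif_shared):
        if len(m) >= length:
            raise ValueError("motif length must be < sequence length")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    motifs = [motif_esc.upper(), motif_de.upper(), motif_shared.upper()]

    def clean_background() -> str:
        while True:
            s = _random_sequence(length, rng)
            if not any(m in s for m in motifs):
                return s

    # (planted motif or None, (open_esc, open_de))
    classes = [
        (motifs[1], (0, 1)),  # open in DE only
        (motifs[0], (1, 0)),  # open in ESC only
        (motifs[2], (1, 1)),  # open in both
        (None, (0, 0)),       # closed in both
    ]
    sequences: list[str] = []
    labels: list[tuple[int, int]] = []
    for motif, label in classes:
        for _ in range(n_per_class):
            s = clean_background()
            if motif is not None:
                pos = int(rng.integers(0, length - len(motif) + 1))
                s = s[:pos] + motif + s[pos + len(motif):]
            sequences.append(s)
            labels.append(label)
    class_counts = {k: n_per_class for k in range(1, 5)}
    return LabeledSequenceSet(
        sequences=sequences,
        labels=np.array(labels, dtype=int),
        class_counts=class_counts,
    )
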