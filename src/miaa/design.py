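"""Design of MIAA reporter libraries.

A MIAA library is a set of short variable DNA sequences (70 or 100 nt)
assembled from neutral genomic backgrounds into which transcription-factor
binding motifs are written at fixed positions. Each design carries a
nucleotide-shuffled control so that motif effects can be separated from
composition (GC) effects. Variable sequences are finally flanked by fixed
25-nt primer arms, the 3' arm carrying the GATC site read out by Dam
methylation.

Conventions
-----------
* Positions are 1-based inclusive throughout, matching how insertion sites
  are reported in library annotation files.
* Motif insertion overwrites background characters, preserving length.
* Only the forward strand / a single motif orientation is designed.
* "Spacing" between consecutive motifs is the gap in nucleotides between
  the last base of one motif and the first base of the next.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IUPAC",
    "MotifHypothesis",
    "DesignedSequence",
    "Arrangement",
    "gc_content",
    "perturb_native",
    "pack_single_motif",
    "pack_motif_pair",
    "chain_pack_motifs",
    "enumerate_arrangements",
    "pack_arrangement",
    "shuffle_control",
    "assemble_oligo",
    "concretize_motif",
    "iupac_matches",
    "scan_motif",
    "SINGLE_MOTIF_STARTS",
    "PAIR_MOTIF_A_STARTS",
    "PAIR_MOTIF_B_STARTS",
]

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: 1-based insertion starts for a single motif packed seven times in 100 nt.
SINGLE_MOTIF_STARTS = (2, 16, 30, 44, 58, 72, 86)
#: 1-based starts for the first motif of a pair (four copies).
PAIR_MOTIF_A_STARTS = (2, 30, 58, 86)
#: 1-based starts for the second motif of a pair (three copies).
PAIR_MOTIF_B_STARTS = (16, 44, 72)

_MOTIF_SOURCES = frozenset({"KMAC", "DeepAccess", "consensus-TF"})
_DIRECTIONS = frozenset({"ESC", "DE", "shared", "unknown"})
_DESIGN_CLASSES = frozenset({
    "native", "neutral_background", "motif", "motif_pair",
    "chained", "arrangement", "shuffle_control", "hashimoto_control",
})


@dataclass(frozen=True)
class MotifHypothesis:
    """A candidate accessibility-modifying motif.

    Motifs derived from de novo discovery on differential DNase-seq regions
    (KMAC or CNN saliency windows) are 8-12 nt; consensus motifs of known
    transcription factors may fall outside that range.
    """

    id: str
    consensus: str
    source: str = "consensus-TF"
    hypothesized_direction: str = "unknown"

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError("motif consensus must be non-empty")
        bad = set(self.consensus.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"non-IUPAC characters in consensus: {sorted(bad)}")
        if self.source not in _MOTIF_SOURCES:
            raise ValueError(f"unknown motif source {self.source!r}")
        if self.hypothesized_direction not in _DIRECTIONS:
            raise ValueError(f"unknown direction {self.hypothesized_direction!r}")
        if self.source in ("KMAC", "DeepAccess") and not 8 <= len(self.consensus) <= 12:
            raise ValueError("discovery-derived motifs must be 8-12 nt")

    def __len__(self) -> int:
        return len(self.consensus)


@dataclass
class DesignedSequence:
    """A variable library sequence plus its design metadata.

    ``placements`` records (motif_id, 1-based start, copy index) for every
    motif written into the background.
    """

    id: str
    variable_seq: str
    background_id: str
    placements: list[tuple[str, int, int]] = field(default_factory=list)
    design_class: str = "neutral_background"
    shuffle_partner_id: str | None = None

    def __post_init__(self) -> None:
        if self.design_class not in _DESIGN_CLASSES:
            raise ValueError(f"unknown design class {self.design_class!r}")

    @property
    def gc(self) -> float:
        return gc_content(self.variable_seq)

    def motif_copy_counts(self) -> dict[str, int]:
        """Number of placed copies per motif id."""
        counts: dict[str, int] = {}
        for motif_id, _, _ in self.placements:
            counts[motif_id] = counts.get(motif_id, 0) + 1
        return counts


@dataclass(frozen=True)
class Arrangement:
    """An ordered motif layout: 1-3 motif instances with fixed spacing."""

    id: str
    motif_ids_in_order: tuple[str, ...]
    spacing_nt: int = 6

    def __post_init__(self) -> None:
        if not 1 <= len(self.motif_ids_in_order) <= 3:
            raise ValueError("arrangements hold 1-3 motif instances")
        if self.spacing_nt < 0:
            raise ValueError("spacing must be non-negative")

    @property
    def is_homotypic(self) -> bool:
        return len(set(self.motif_ids_in_order)) == 1

    @property
    def n_instances(self) -> int:
        return len(self.motif_ids_in_order)


def gc_content(seq: str) -> float:
    """Fraction of G+C bases in ``seq`` (ACGT alphabet only)."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters: {sorted(bad)}")
    return (seq.count("G") + seq.count("C")) / len(seq)


def concretize_motif(consensus: str, rng: np.random.Generator) -> str:
    """Resolve IUPAC ambiguity codes to concrete bases, uniformly at random."""
    return "".join(
        c if len(IUPAC[c]) == 1 else IUPAC[c][rng.integers(len(IUPAC[c]))]
        for c in consensus.upper()
    )


def iupac_matches(pattern: str, seq: str) -> bool:
    """True if concrete sequence ``seq`` matches IUPAC ``pattern`` base-wise."""
    if len(pattern) != len(seq):
        return False
    return all(s in IUPAC[p] for p, s in zip(pattern.upper(), seq.upper()))


def scan_motif(pattern: str, seq: str) -> list[int]:
    """1-based start positions of IUPAC ``pattern`` matches in ``seq``."""
    w = len(pattern)
    return [
        i + 1
        for i in range(len(seq) - w + 1)
        if iupac_matches(pattern, seq[i : i + w])
    ]


def perturb_native(
    native: str,
    n_variants: int,
    substitution_rate: float,
    forbidden_motifs: list[MotifHypothesis],
    seed: int,
    max_retries: int = 100,
) -> list[str]:
    """Derive perturbed variants of a native background.

    Each variant differs from the native at exactly ``ceil(rate * length)``
    positions and contains no match to any forbidden motif. The caller
    combines natives and variants into the background panel (six natives
    perturbed three times each give the standard panel of 24).
    """
    if not 0.0 < substitution_rate < 1.0:
        raise ValueError("substitution_rate must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_sub = int(np.ceil(substitution_rate * len(native)))
    variants: list[str] = []
    for _ in range(n_variants):
        for _attempt in range(max_retries):
            pos = rng.choice(len(native), size=n_sub, replace=False)
            chars = list(native)
            for p in pos:
                alternatives = [b for b in "ACGT" if b != chars[p]]
                chars[p] = alternatives[rng.integers(3)]
            cand = "".join(chars)
            if not any(scan_motif(m.consensus, cand) for m in forbidden_motifs):
                variants.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not satisfy forbidden-motif constraint in {max_retries} tries"
            )
    return variants


def _write_motif(
    chars: list[str],
    motif: str,
    start_1based: int,
) -> None:
    if start_1based < 1 or start_1based + len(motif) - 1 > len(chars):
        raise ValueError(
            f"placement at {start_1based} of {len(motif)}-nt motif exceeds "
            f"{len(chars)}-nt sequence"
        )
    chars[start_1based - 1 : start_1based - 1 + len(motif)] = list(motif)


def pack_single_motif(
    background: str,
    motif: MotifHypothesis,
    background_id: str = "bg",
    rng: np.random.Generator | None = None,
) -> DesignedSequence:
    """Pack seven copies of one motif into a 100-nt background.

    Copies are written at 1-based starts 2, 16, 30, 44, 58, 72, 86; the
    14-nt site pitch means motifs up to 14 nt cannot self-overlap.
    """
    if len(background) != 100:
        raise ValueError("single-motif packing requires a 100-nt background")
    if len(motif) > 14:
        raise ValueError("motif longer than 14 nt would overlap the next site")
    rng = rng or np.random.default_rng(0)
    chars = list(background.upper())
    placements = []
    for copy_idx, start in enumerate(SINGLE_MOTIF_STARTS):
        _write_motif(chars, concretize_motif(motif.consensus, rng), start)
        placements.append((motif.id, start, copy_idx))
    return DesignedSequence(
        id=f"{background_id}|motif={motif.id}",
        variable_seq="".join(chars),
        background_id=background_id,
        placements=placements,
        design_class="motif",
    )


def pack_motif_pair(
    background: str,
    motif_a: MotifHypothesis,
    motif_b: MotifHypothesis,
    background_id: str = "bg",
    rng: np.random.Generator | None = None,
) -> DesignedSequence:
    """Pack two distinct motifs, alternating: A at 2/30/58/86, B at 16/44/72."""
    if len(background) != 100:
        raise ValueError("motif-pair packing requires a 100-nt background")
    if motif_a.id == motif_b.id or motif_a.consensus == motif_b.consensus:
        raise ValueError("motif pair must be two distinct motifs")
    if max(len(motif_a), len(motif_b)) > 14:
        raise ValueError("motif longer than 14 nt would overlap the next site")
    rng = rng or np.random.default_rng(0)
    chars = list(background.upper())
    placements = []
    for copy_idx, start in enumerate(PAIR_MOTIF_A_STARTS):
        _write_motif(chars, concretize_motif(motif_a.consensus, rng), start)
        placements.append((motif_a.id, start, copy_idx))
    for copy_idx, start in enumerate(PAIR_MOTIF_B_STARTS):
        _write_motif(chars, concretize_motif(motif_b.consensus, rng), start)
        placements.append((motif_b.id, start, copy_idx))
    placements.sort(key=lambda p: p[1])
    return DesignedSequence(
        id=f"{background_id}|pair={motif_a.id}+{motif_b.id}",
        variable_seq="".join(chars),
        background_id=background_id,
        placements=placements,
        design_class="motif_pair",
    )


def chain_pack_motifs(
    seed_motif: MotifHypothesis,
    scored_motifs: list[tuple[MotifHypothesis, float]],
    overlap: int = 4,
    target_length: int = 100,
    pad_rng: np.random.Generator | None = None,
) -> str:
    """Greedily chain overlapping motifs into a maximally packed sequence.

    Starting from the seed, the highest-scoring candidate whose first
    ``overlap`` bases are IUPAC-compatible with the current suffix is
    appended (sharing the overlap), until the target length is reached or
    no candidate fits. Ties in score break lexicographically by motif id.
    The result is trimmed or padded with random neutral bases to
    ``target_length``.
    """
    if overlap < 1:
        raise ValueError("overlap must be >= 1")
    if any(len(m) <= overlap for m, _ in scored_motifs) or len(seed_motif) <= overlap:
        raise ValueError("all motifs must be longer than the overlap")
    pad_rng = pad_rng or np.random.default_rng(0)
    chain = concretize_motif(seed_motif.consensus, pad_rng)
    ranked = sorted(scored_motifs, key=lambda t: (-t[1], t[0].id))
    while len(chain) < target_length:
        suffix = chain[-overlap:]
        ext = next(
            (m for m, _ in ranked if iupac_matches(m.consensus[:overlap], suffix)),
            None,
        )
        if ext is None:
            break
        # overlap region takes the concrete suffix; the rest is concretized
        tail = concretize_motif(ext.consensus[overlap:], pad_rng)
        chain += tail
    if len(chain) > target_length:
        chain = chain[:target_length]
    while len(chain) < target_length:
        chain += "ACGT"[pad_rng.integers(4)]
    return chain


def enumerate_arrangements(
    tf_sets: tuple[list[MotifHypothesis], list[MotifHypothesis]],
    copy_numbers: frozenset[int] | set[int] = frozenset({1, 2, 3}),
    spacing_nt: int = 6,
) -> list[Arrangement]:
    """Enumerate homotypic and heterotypic motif arrangements.

    Homotypic: one arrangement per (motif, copy number). Heterotypic: every
    ordered pair of distinct motifs within a set, and every permutation of
    the full triple within a set. Sets are never mixed. Two sets of three
    motifs with copies {1,2,3} yield 42 arrangements (18 + 12 + 12).
    """
    arrangements: list[Arrangement] = []
    for set_idx, motifs in enumerate(tf_sets):
        ids = [m.id for m in motifs]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate motif ids in set {set_idx}: {ids}")
        for m in ids:
            for k in sorted(copy_numbers):
                arrangements.append(
                    Arrangement(
                        id=f"set{set_idx}|homo|{m}x{k}",
                        motif_ids_in_order=(m,) * k,
                        spacing_nt=spacing_nt,
                    )
                )
        if 2 in copy_numbers:
            for a, b in itertools.permutations(ids, 2):
                arrangements.append(
                    Arrangement(
                        id=f"set{set_idx}|hetero|{a}-{b}",
                        motif_ids_in_order=(a, b),
                        spacing_nt=spacing_nt,
                    )
                )
        if 3 in copy_numbers and len(ids) >= 3:
            for perm in itertools.permutations(ids, 3):
                arrangements.append(
                    Arrangement(
                        id=f"set{set_idx}|hetero|{'-'.join(perm)}",
                        motif_ids_in_order=perm,
                        spacing_nt=spacing_nt,
                    )
                )
    return arrangements


def pack_arrangement(
    background: str,
    arrangement: Arrangement,
    motifs: dict[str, MotifHypothesis],
    background_id: str = "bg",
    rng: np.random.Generator | None = None,
) -> DesignedSequence:
    """Write an arrangement's motifs into a background, centered.

    Motifs are placed left-to-right in arrangement order with exactly
    ``spacing_nt`` background nucleotides between the end of one motif and
    the start of the next; the whole block is centered (1-based start
    offset ``floor((L - span) / 2) + 1``).
    """
    rng = rng or np.random.default_rng(0)
    lengths = [len(motifs[m]) for m in arrangement.motif_ids_in_order]
    span = sum(lengths) + arrangement.spacing_nt * (len(lengths) - 1)
    if span > len(background):
        raise ValueError(
            f"arrangement span {span} nt exceeds {len(background)}-nt background"
        )
    chars = list(background.upper())
    start = (len(background) - span) // 2 + 1
    placements = []
    copy_seen: dict[str, int] = {}
    for motif_id, mlen in zip(arrangement.motif_ids_in_order, lengths):
        concrete = concretize_motif(motifs[motif_id].consensus, rng)
        _write_motif(chars, concrete, start)
        idx = copy_seen.get(motif_id, 0)
        placements.append((motif_id, start, idx))
        copy_seen[motif_id] = idx + 1
        start += mlen + arrangement.spacing_nt
    return DesignedSequence(
        id=f"{background_id}|arr={arrangement.id}",
        variable_seq="".join(chars),
        background_id=background_id,
        placements=placements,
        design_class="arrangement",
    )


def shuffle_control(design: DesignedSequence, seed: int) -> DesignedSequence:
    """Nucleotide-shuffled control: same composition, motifs destroyed.

    Links the pair in both directions (the input design is modified in
    place to point at its control).
    """
    if not design.variable_seq:
        raise ValueError("cannot shuffle an empty sequence")
    rng = np.random.default_rng(seed)
    chars = np.array(list(design.variable_seq))
    rng.shuffle(chars)
    control = DesignedSequence(
        id=f"{design.id}|shuffle",
        variable_seq="".join(chars),
        background_id=design.background_id,
        placements=[],
        design_class="shuffle_control",
        shuffle_partner_id=design.id,
    )
    design.shuffle_partner_id = control.id
    return control


def assemble_oligo(design: DesignedSequence, flank5: str, flank3: str) -> str:
    """Assemble the full synthesis oligo: 5' arm + variable + 3' arm.

    Both arms are 25 nt; the 3' arm must carry GATC starting at its second
    base, i.e. one neutral nucleotide downstream of the variable sequence,
    so that Dam methylation of the readout site reflects local
    accessibility of the variable region.
    """
    if len(flank5) != 25 or len(flank3) != 25:
        raise ValueError("flanks must be exactly 25 nt")
    if flank3[1:5].upper() != "GATC":
        raise ValueError("3' flank must contain GATC starting at its 2nd base")
    return flank5 + design.variable_seq + flank3
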