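"""Readers and writers for library, count and result files.

All positions in annotation files are 1-based inclusive.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import DesignedSequence

__all__ = [
    "write_library_fasta",
    "read_fasta",
    "write_design_annotation",
    "read_design_annotation",
    "write_counts_tsv",
    "read_counts_tsv",
    "read_reads",
]


def write_library_fasta(designs: list[DesignedSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(d.variable_seq), id=d.id, description=d.design_class)
        for d in designs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _placements_str(d: DesignedSequence) -> str:
    return ";".join(f"{m}:{start}" for m, start, _ in d.placements)


def write_design_annotation(designs: list[DesignedSequence], path: str | Path) -> None:
    """Design annotation TSV; motif positions are 1-based starts."""
    rows = [
        {
            "id": d.id,
            "design_class": d.design_class,
            "background_id": d.background_id,
            "placements": _placements_str(d),
            "shuffle_partner": d.shuffle_partner_id or "",
            "gc": round(d.gc, 6),
        }
        for d in designs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_design_annotation(path: str | Path, sequences: dict[str, str]) -> list[DesignedSequence]:
    """Rebuild designs from an annotation TSV plus the library FASTA."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    designs = []
    for row in df.itertuples():
        placements = []
        if row.placements:
            copy_seen: dict[str, int] = {}
            for item in row.placements.split(";"):
                m, start = item.rsplit(":", 1)
                k = copy_seen.get(m, 0)
                placements.append((m, int(start), k))
                copy_seen[m] = k + 1
        designs.append(
            DesignedSequence(
                id=row.id,
                variable_seq=sequences[row.id],
                background_id=row.background_id,
                placements=placements,
                design_class=row.design_class,
                shuffle_partner_id=row.shuffle_partner or None,
            )
        )
    return designs


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_reads(path: str | Path) -> list[str]:
    """Read sequencing reads from FASTQ/FASTA (by extension) or plain text."""
    p = Path(path)
    if p.suffix in (".fastq", ".fq"):
        return [str(rec.seq) for rec in SeqIO.parse(str(p), "fastq")]
    if p.suffix in (".fasta", ".fa"):
        return [str(rec.seq) for rec in SeqIO.parse(str(p), "fasta")]
    return [line.strip() for line in p.read_text().splitlines() if line.strip()]
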