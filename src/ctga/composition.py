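"""Composition of the placed vs. unplaced partitions of an assembly.

Once contigs have been assigned to chromosomes (or not), the two contig
sets are profiled: how much of each partition is repeat-masked, how many
genes each carries, and what fraction of those genes are lncRNAs.  In
repeat-rich plant assemblies the unplaced partition is typically almost
entirely repetitive and enriched for lncRNA annotations, while nearly
all protein-coding genes land on chromosomes.

Genes belong to the partition of their host contig; repeat and gene
accounting are independent (a gene overlapping a repeat still counts).
Overlapping repeat annotations are merged per contig before coverage is
summed so no base is counted twice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from ctga.homology_placement import Placement
from ctga.io_formats import FeatureInterval, SequenceRecord

__all__ = [
    "PartitionComposition",
    "merge_intervals",
    "merged_coverage",
    "compute_composition",
    "protein_coding_placement_rate",
]


@dataclass(frozen=True)
class PartitionComposition:
    partition: str  # 'placed' or 'unplaced'
    total_bp: int
    repeat_bp: int
    n_genes: int
    n_protein_coding: int
    n_lncRNA: int

    @property
    def repeat_fraction(self) -> float:
        return self.repeat_bp / self.total_bp if self.total_bp else 0.0

    @property
    def lncRNA_fraction(self) -> float:
        return self.n_lncRNA / self.n_genes if self.n_genes else 0.0


def merge_intervals(
    intervals: Iterable[FeatureInterval],
    contig_lengths: Mapping[str, int] | None = None,
) -> dict[str, list[tuple[int, int]]]:
    """Merge overlapping/adjacent intervals per contig.

    Returns, per contig, the minimal set of disjoint 0-based half-open
    intervals covering the same bases, sorted by start.  If
    ``contig_lengths`` is given, intervals extending beyond their contig
    raise ``ValueError``.
    """
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        if contig_lengths is not None:
            if iv.seq_id not in contig_lengths:
                raise ValueError(f"interval on unknown contig {iv.seq_id!r}")
            if iv.end > contig_lengths[iv.seq_id]:
                raise ValueError(
                    f"interval [{iv.start}, {iv.end}) beyond end of "
                    f"{iv.seq_id} (length {contig_lengths[iv.seq_id]})"
                )
        trees.setdefault(iv.seq_id, IntervalTree()).addi(iv.start, iv.end)
    merged: dict[str, list[tuple[int, int]]] = {}
    for seq_id, tree in trees.items():
        tree.merge_overlaps(strict=False)  # adjacent intervals coalesce too
        merged[seq_id] = sorted((i.begin, i.end) for i in tree)
    return merged


def merged_coverage(
    intervals: Iterable[FeatureInterval],
    contig_lengths: Mapping[str, int] | None = None,
) -> int:
    """Total bases covered by the merged intervals."""
    merged = merge_intervals(intervals, contig_lengths)
    return sum(end - start for spans in merged.values() for start, end in spans)


def compute_composition(
    placements: Sequence[Placement],
    contigs: Sequence[SequenceRecord],
    repeats: Sequence[FeatureInterval],
    genes: Sequence[FeatureInterval],
) -> tuple[PartitionComposition, PartitionComposition]:
    """Profile the placed and unplaced contig partitions.

    Contigs not listed in ``placements`` and contigs with ambiguous
    status are counted as unplaced.  Returns ``(placed, unplaced)``.
    """
    lengths = {c.id: len(c) for c in contigs}
    for feat in list(repeats) + list(genes):
        if feat.seq_id not in lengths:
            raise ValueError(f"feature on unknown contig {feat.seq_id!r}")
    placed_ids = {
        p.contig_id for p in placements if p.status == "placed"
    }
    out = []
    for name in ("placed", "unplaced"):
        in_partition = (
            (lambda cid: cid in placed_ids)
            if name == "placed"
            else (lambda cid: cid not in placed_ids)
        )
        total_bp = sum(length for cid, length in lengths.items() if in_partition(cid))
        repeat_bp = merged_coverage(
            [r for r in repeats if in_partition(r.seq_id)], lengths
        )
        part_genes = [g for g in genes if in_partition(g.seq_id)]
        out.append(
            PartitionComposition(
                partition=name,
                total_bp=total_bp,
                repeat_bp=repeat_bp,
                n_genes=len(part_genes),
                n_protein_coding=sum(
                    1 for g in part_genes if g.subclass == "protein_coding"
                ),
                n_lncRNA=sum(1 for g in part_genes if g.subclass == "lncRNA"),
            )
        )
    return out[0], out[1]


def protein_coding_placement_rate(
    placed: PartitionComposition, unplaced: PartitionComposition
) -> float:
    """Fraction of all protein-coding genes hosted on placed contigs."""
    total = placed.n_protein_coding + unplaced.n_protein_coding
    if total == 0:
        raise ValueError("no protein-coding genes in either partition")
    return placed.n_protein_coding / total
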