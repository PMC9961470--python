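"""In-silico assignment of assembly contigs to reference chromosomes.

The placer indexes every k-mer that occurs exactly once in the reference
(counting both strands through the canonical form) and lets each such
anchor found on a contig cast one vote for the chromosome it came from.
Repeat-derived contigs have no unique anchors and stay unplaced — the
same behaviour reference-guided scaffolders show on repeat-dominated
plant assemblies.  Each reference genome is processed independently;
merging several divergent references into one placement run is
deliberately not supported.

Defaults: k=21 (canonical), min_anchors=10, min_confidence=0.8 — chosen
so exact substrings of the reference always place with confidence 1.0
and half-and-half chimeric contigs come out ambiguous rather than
assigned by coin flip.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ctga.io_formats import AgpRecord, SequenceRecord

__all__ = [
    "AnchorIndex",
    "Placement",
    "build_anchor_index",
    "place_contig",
    "place_all",
    "order_and_export",
    "agp_to_evidence",
    "canonical",
    "revcomp",
]

DEFAULT_K = 21
DEFAULT_MIN_ANCHORS = 10
DEFAULT_MIN_CONFIDENCE = 0.8
DEFAULT_GAP_LEN = 100

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> tuple[str, bool]:
    """Strand-folded form of a k-mer and whether the forward form was kept."""
    rc = revcomp(kmer)
    return (kmer, True) if kmer <= rc else (rc, False)


@dataclass
class AnchorIndex:
    """Unique k-mer anchors of one reference genome.

    ``anchors`` maps each canonical k-mer occurring exactly once in the
    reference (both strands folded together) to
    ``(chromosome_id, position, forward)`` where ``position`` is the
    0-based start of the occurrence and ``forward`` records whether the
    canonical form equals the reference forward-strand k-mer there.
    """

    k: int
    anchors: dict[str, tuple[str, int, bool]]
    chromosome_ids: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.anchors)


def _iter_kmers(seq: str, k: int) -> Iterable[tuple[int, str]]:
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        yield i, kmer


def build_anchor_index(
    reference: Sequence[SequenceRecord], k: int = DEFAULT_K
) -> AnchorIndex:
    """Index the k-mers occurring exactly once across the whole reference.

    The reference should contain chromosome-scale sequences only
    (unplaced scaffolds must be filtered out by the caller).  k-mers
    containing N are excluded; counting is canonical, so a k-mer and its
    reverse complement are the same anchor.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd so no k-mer is its own reverse complement")
    if all(len(chrom) < k for chrom in reference):
        raise ValueError(f"k={k} exceeds every reference sequence length")
    first: dict[str, tuple[str, int, bool]] = {}
    repeated: set[str] = set()
    for chrom in reference:
        for pos, kmer in _iter_kmers(chrom.seq, k):
            canon, forward = canonical(kmer)
            if canon in repeated:
                continue
            if canon in first:
                del first[canon]
                repeated.add(canon)
            else:
                first[canon] = (chrom.id, pos, forward)
    return AnchorIndex(
        k=k, anchors=first, chromosome_ids=tuple(c.id for c in reference)
    )


@dataclass(frozen=True)
class Placement:
    """Outcome of placing one contig against one reference."""

    contig_id: str
    status: str  # 'placed' | 'unplaced' | 'ambiguous'
    chromosome_id: str | None = None
    anchor_votes: Mapping[str, int] = field(default_factory=dict)
    position: float | None = None  # median supporting-anchor coordinate
    orientation: str | None = None
    confidence: float | None = None  # top-chromosome vote fraction

    @property
    def total_votes(self) -> int:
        return sum(self.anchor_votes.values())


def place_contig(
    contig: SequenceRecord,
    index: AnchorIndex,
    min_anchors: int = DEFAULT_MIN_ANCHORS,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
) -> Placement:
    """Vote a contig onto a chromosome using unique-k-mer anchors.

    Every contig k-mer present in the index casts one vote for its
    chromosome.  The contig is placed iff total votes >= ``min_anchors``,
    the top chromosome is a strict maximum and its vote fraction reaches
    ``min_confidence``; too few votes leave it unplaced, conflicting
    votes make it ambiguous.  Orientation is the majority strand
    agreement of the supporting anchors; position the median of their
    reference coordinates.
    """
    votes: dict[str, int] = {}
    support: dict[str, list[tuple[int, bool]]] = {}
    for _, kmer in _iter_kmers(contig.seq, index.k):
        canon, contig_forward = canonical(kmer)
        hit = index.anchors.get(canon)
        if hit is None:
            continue
        chrom, pos, ref_forward = hit
        votes[chrom] = votes.get(chrom, 0) + 1
        # anchor supports '+' when contig and reference agree on which
        # strand carries the canonical form
        support.setdefault(chrom, []).append((pos, contig_forward == ref_forward))
    total = sum(votes.values())
    if total == 0 or total < min_anchors:
        return Placement(contig.id, "unplaced", anchor_votes=votes)
    best = max(votes.values())
    leaders = [chrom for chrom, v in votes.items() if v == best]
    confidence = best / total
    if len(leaders) > 1 or confidence < min_confidence:
        return Placement(
            contig.id, "ambiguous", anchor_votes=votes, confidence=confidence
        )
    chrom = leaders[0]
    positions = sorted(pos for pos, _ in support[chrom])
    fwd = sum(1 for _, agree in support[chrom] if agree)
    rev = len(support[chrom]) - fwd
    if fwd == rev:
        warnings.warn(
            f"orientation tie for {contig.id} on {chrom}; defaulting to '+'",
            stacklevel=2,
        )
    orientation = "+" if fwd >= rev else "-"
    return Placement(
        contig_id=contig.id,
        status="placed",
        chromosome_id=chrom,
        anchor_votes=votes,
        position=statistics.median(positions),
        orientation=orientation,
        confidence=confidence,
    )


def place_all(
    contigs: Sequence[SequenceRecord],
    index: AnchorIndex,
    min_anchors: int = DEFAULT_MIN_ANCHORS,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
) -> list[Placement]:
    return [
        place_contig(c, index, min_anchors=min_anchors, min_confidence=min_confidence)
        for c in contigs
    ]


def order_and_export(
    placements: Sequence[Placement],
    contig_lengths: Mapping[str, int],
    reference_tag: str,
    gap_len: int = DEFAULT_GAP_LEN,
) -> list[AgpRecord]:
    """Turn placements into AGP records.

    Placed contigs are sorted by median anchor position per chromosome and
    joined by gaps of unknown size (component_type U); unplaced and
    ambiguous contigs become singleton objects named after themselves.
    Chromosome objects are named ``<chromosome>_<reference_tag>``.
    """
    seen: set[str] = set()
    for p in placements:
        if p.contig_id in seen:
            raise ValueError(f"duplicate contig in placements: {p.contig_id}")
        seen.add(p.contig_id)
    records: list[AgpRecord] = []
    by_chrom: dict[str, list[Placement]] = {}
    singletons: list[Placement] = []
    for p in placements:
        if p.status == "placed":
            by_chrom.setdefault(p.chromosome_id, []).append(p)
        else:
            singletons.append(p)
    for chrom in sorted(by_chrom):
        object_id = f"{chrom}_{reference_tag}"
        ordered = sorted(by_chrom[chrom], key=lambda p: (p.position, p.contig_id))
        cursor = 1
        part = 1
        for i, p in enumerate(ordered):
            length = contig_lengths[p.contig_id]
            if i > 0:
                records.append(
                    AgpRecord(
                        object_id=object_id,
                        object_beg=cursor,
                        object_end=cursor + gap_len - 1,
                        part_number=part,
                        component_type="U",
                        gap_length=gap_len,
                        gap_type="scaffold",
                        linkage="yes",
                        evidence="align_genus",
                    )
                )
                cursor += gap_len
                part += 1
            records.append(
                AgpRecord(
                    object_id=object_id,
                    object_beg=cursor,
                    object_end=cursor + length - 1,
                    part_number=part,
                    component_type="W",
                    component_id=p.contig_id,
                    component_beg=1,
                    component_end=length,
                    orientation=p.orientation,
                )
            )
            cursor += length
            part += 1
    for p in sorted(singletons, key=lambda p: p.contig_id):
        length = contig_lengths[p.contig_id]
        records.append(
            AgpRecord(
                object_id=p.contig_id,
                object_beg=1,
                object_end=length,
                part_number=1,
                component_type="W",
                component_id=p.contig_id,
                component_beg=1,
                component_end=length,
                orientation="+",
            )
        )
    return records


def agp_to_evidence(
    agp: Sequence[AgpRecord], reference_tag: str
) -> list["EvidenceRecord"]:
    """Extract per-contig chromosome claims from scaffolder AGP output.

    Only W components placed on chromosome objects (objects whose name
    differs from the component, i.e. not singleton unplaced contigs)
    yield evidence; the claim's source is ``scaffold:<reference_tag>``
    and the chromosome label is normalized by stripping reference
    suffixes.
    """
    from ctga.evidence_consensus import EvidenceRecord, normalize_chromosome

    out: list[EvidenceRecord] = []
    for rec in agp:
        if rec.component_type != "W":
            continue
        if rec.object_id == rec.component_id:
            continue  # singleton unplaced contig
        out.append(
            EvidenceRecord(
                contig_id=rec.component_id,
                chromosome=normalize_chromosome(rec.object_id),
                source=f"scaffold:{reference_tag}",
            )
        )
    return out
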