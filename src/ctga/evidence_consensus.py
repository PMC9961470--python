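"""Majority-vote integration of heterogeneous chromosome-assignment evidence.

Each evidence track (genetic markers, reference-guided scaffolding
against one or more references, protein homology, DArT-seq loci,
BAC/FISH probes) claims a chromosome for some contigs.  The consensus
for a contig is the chromosome with the highest weighted number of
matches across tracks; ties are surfaced as ambiguous, never resolved
arbitrarily, and every dissenting track is listed as a conflict.

Two consensi are computed in integrated reports: a bioinformatics-only
consensus that excludes cytogenetic (BAC/FISH) evidence, and an
all-evidence consensus — mirroring how wet-lab probe localizations are
used to *validate* the in-silico assignment rather than vote in it.

Within one source, claims are pre-aggregated first: if a source's loci
disagree about a contig, the source's internal majority is taken, and an
internal tie makes the source abstain for that contig.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ctga.io_formats import LocusHit

__all__ = [
    "EvidenceRecord",
    "ConsensusAssignment",
    "normalize_chromosome",
    "loci_to_evidence",
    "consensus_assign",
    "consensus_for_all",
    "build_integrated_table",
    "BACFISH_SOURCE",
]

#: source name carrying cytogenetic evidence, excluded from the
#: bioinformatics-only consensus
BACFISH_SOURCE = "bac_fish"

#: default pattern extracting a bare chromosome label from possibly
#: reference-suffixed forms such as 'Chr2_9930'
CHROM_PATTERN = re.compile(r"(Chr\d+)", re.IGNORECASE)


def normalize_chromosome(label: str, pattern: re.Pattern = CHROM_PATTERN) -> str:
    """Strip reference suffixes: 'Chr2_9930' -> 'Chr2'."""
    m = pattern.search(label)
    if not m:
        raise ValueError(f"cannot extract a chromosome label from {label!r}")
    token = m.group(1)
    return "Chr" + token[3:]  # canonical capitalization


@dataclass(frozen=True)
class EvidenceRecord:
    """One source's chromosome claim for a contig."""

    contig_id: str
    chromosome: str
    source: str
    locus_id: str | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("evidence weight must be positive")


@dataclass(frozen=True)
class ConsensusAssignment:
    """Per-contig result of the weighted majority vote."""

    contig_id: str
    votes: Mapping[str, float]
    consensus: str | None  # chromosome, or None when ambiguous/no_evidence
    status: str  # 'assigned' | 'ambiguous' | 'no_evidence'
    support: float | None  # winning weight / total weight
    conflicts: tuple[tuple[str, str], ...]  # (source, dissenting chromosome)


def loci_to_evidence(
    hits: Iterable[LocusHit],
    locus_chrom_map: Mapping[str, str],
    source: str,
    min_identity: float = 90.0,
) -> list[EvidenceRecord]:
    """Turn locus-to-assembly BLASTN hits into chromosome claims.

    Hits below ``min_identity`` percent identity are discarded; each
    locus contributes at most one claim, through its best remaining hit
    (minimal e-value, ties to maximal identity then smallest contig id);
    loci absent from the genetic map contribute nothing.
    """
    best: dict[str, LocusHit] = {}
    for hit in hits:
        if hit.pct_identity < min_identity:
            continue
        if hit.locus_id not in locus_chrom_map:
            continue
        key = (hit.evalue, -hit.pct_identity, hit.contig_id)
        cur = best.get(hit.locus_id)
        if cur is None or key < (cur.evalue, -cur.pct_identity, cur.contig_id):
            best[hit.locus_id] = hit
    return [
        EvidenceRecord(
            contig_id=hit.contig_id,
            chromosome=normalize_chromosome(locus_chrom_map[locus]),
            source=source,
            locus_id=locus,
        )
        for locus, hit in sorted(best.items())
    ]


def _aggregate_by_source(
    records: Iterable[EvidenceRecord],
) -> dict[str, tuple[str, float]]:
    """Deduplicate, then reduce each source to one claim (or abstention).

    Returns ``{source: (chromosome, weight)}``; sources whose internal
    majority is tied are dropped (abstain).
    """
    unique = {
        (r.contig_id, r.source, r.chromosome, r.locus_id): r for r in records
    }
    per_source: dict[str, Counter] = {}
    weights: dict[str, float] = {}
    for r in unique.values():
        per_source.setdefault(r.source, Counter())[r.chromosome] += 1
        weights[r.source] = max(weights.get(r.source, 0.0), r.weight)
    claims: dict[str, tuple[str, float]] = {}
    for source, tally in per_source.items():
        top = tally.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            continue  # internal tie -> abstain
        claims[source] = (top[0][0], weights[source])
    return claims


def consensus_assign(
    contig_id: str,
    records: Iterable[EvidenceRecord],
    exclude_sources: Iterable[str] = (),
) -> ConsensusAssignment:
    """Weighted majority vote over one contig's evidence.

    A unique maximum yields an assignment with support = winning weight /
    total weight and a conflict entry for every dissenting source; a tied
    maximum is reported as ambiguous, empty evidence as no_evidence.
    """
    excluded = set(exclude_sources)
    relevant = [r for r in records if r.contig_id == contig_id and r.source not in excluded]
    claims = _aggregate_by_source(relevant)
    if not claims:
        return ConsensusAssignment(
            contig_id=contig_id,
            votes={},
            consensus=None,
            status="no_evidence",
            support=None,
            conflicts=(),
        )
    votes: dict[str, float] = {}
    for chrom, weight in claims.values():
        votes[chrom] = votes.get(chrom, 0.0) + weight
    total = sum(votes.values())
    best = max(votes.values())
    leaders = [c for c, v in votes.items() if v == best]
    if len(leaders) > 1:
        return ConsensusAssignment(
            contig_id=contig_id,
            votes=votes,
            consensus=None,
            status="ambiguous",
            support=None,
            conflicts=(),
        )
    winner = leaders[0]
    conflicts = tuple(
        sorted(
            (source, chrom)
            for source, (chrom, _) in claims.items()
            if chrom != winner
        )
    )
    return ConsensusAssignment(
        contig_id=contig_id,
        votes=votes,
        consensus=winner,
        status="assigned",
        support=best / total,
        conflicts=conflicts,
    )


def consensus_for_all(
    records: Sequence[EvidenceRecord],
    contig_universe: Iterable[str] | None = None,
    exclude_sources: Iterable[str] = (),
) -> dict[str, ConsensusAssignment]:
    """Consensus per contig over a full evidence table."""
    by_contig: dict[str, list[EvidenceRecord]] = {}
    for r in records:
        by_contig.setdefault(r.contig_id, []).append(r)
    universe = list(contig_universe) if contig_universe is not None else sorted(by_contig)
    return {
        cid: consensus_assign(cid, by_contig.get(cid, ()), exclude_sources)
        for cid in universe
    }


DEFAULT_SOURCE_ORDER = (
    "markers",
    "scaffold:9930",
    "scaffold:Gy14",
    "blastp:9930",
    "blastp:gy14",
    "dart",
    BACFISH_SOURCE,
)


def build_integrated_table(
    contig_universe: Sequence[str],
    records: Sequence[EvidenceRecord],
    source_order: Sequence[str] = DEFAULT_SOURCE_ORDER,
) -> pd.DataFrame:
    """One row per contig, one column per evidence source, plus both
    consensi (bioinformatics-only and all-evidence), support and
    conflict columns.  Sources missing for a contig leave blank cells.
    """
    universe = list(contig_universe)
    known = set(universe)
    stray = sorted({r.contig_id for r in records} - known)
    if stray:
        warnings.warn(
            f"evidence for contigs outside the universe: {', '.join(stray)}",
            stacklevel=2,
        )
        universe = universe + stray
    by_contig: dict[str, list[EvidenceRecord]] = {}
    for r in records:
        by_contig.setdefault(r.contig_id, []).append(r)
    extra_sources = sorted(
        {r.source for r in records} - set(source_order)
    )
    columns = list(source_order) + extra_sources
    rows = []
    for cid in universe:
        recs = by_contig.get(cid, [])
        claims = _aggregate_by_source(recs)
        bio = consensus_assign(cid, recs, exclude_sources=(BACFISH_SOURCE,))
        full = consensus_assign(cid, recs)
        row: dict[str, object] = {"contig": cid}
        for source in columns:
            row[source] = claims[source][0] if source in claims else ""
        row["consensus_bioinformatics"] = (
            bio.consensus if bio.consensus else bio.status
        )
        row["consensus_all"] = full.consensus if full.consensus else full.status
        row["support_all"] = "" if full.support is None else round(full.support, 4)
        row["conflicts"] = "; ".join(
            f"{source}={chrom}" for source, chrom in full.conflicts
        )
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["contig"]
        + columns
        + ["consensus_bioinformatics", "consensus_all", "support_all", "conflicts"],
    )
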