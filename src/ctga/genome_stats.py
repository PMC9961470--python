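"""Whole-assembly summary statistics.

The N50 here is the classical contig N50: the length of the shortest
contig such that contigs of that length or longer cover at least half of
the assembly.  Base percentages use the total assembly length as the
denominator, so ambiguous bases (N) depress the four base percentages
rather than being excluded — the convention that chromosome-scale plant
assemblies with embedded gap runs make visible (A+C+G+T < 100%).
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

from ctga.io_formats import SequenceRecord

__all__ = ["AssemblyStats", "compute_assembly_stats", "n50"]


@dataclass(frozen=True)
class AssemblyStats:
    genome_size: int
    n_contigs: int
    pct_a: float
    pct_t: float
    pct_g: float
    pct_c: float
    pct_gc: float
    n50: int
    max_len: int
    min_len: int
    median_len: float

    def to_row(self) -> dict:
        """One-row summary with percentages at two-decimal display precision."""
        row = asdict(self)
        for key in ("pct_a", "pct_t", "pct_g", "pct_c", "pct_gc"):
            row[key] = round(row[key], 2)
        return row

    def to_json(self) -> str:
        return json.dumps(self.to_row(), indent=2)


def n50(lengths: Iterable[int]) -> int:
    """N50 of a multiset of contig lengths.

    Sort descending, accumulate, and return the first length at which the
    running total reaches half the assembly size.
    """
    ordered = sorted(lengths, reverse=True)
    if not ordered:
        raise ValueError("N50 of an empty length set is undefined")
    half = sum(ordered) / 2
    acc = 0
    for length in ordered:
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")  # pragma: no cover


def compute_assembly_stats(contigs: Sequence[SequenceRecord]) -> AssemblyStats:
    """Compute size, base composition, N50 and length quantiles.

    Raises ``ValueError`` on an empty collection.  Results are invariant
    under any reordering of the contigs.
    """
    if not contigs:
        raise ValueError("cannot compute statistics of an empty assembly")
    lengths = [len(c) for c in contigs]
    total = sum(lengths)
    counts = {"A": 0, "C": 0, "G": 0, "T": 0}
    for contig in contigs:
        for base in counts:
            counts[base] += contig.seq.count(base)
    pct = {base: 100.0 * counts[base] / total for base in counts}
    return AssemblyStats(
        genome_size=total,
        n_contigs=len(contigs),
        pct_a=pct["A"],
        pct_t=pct["T"],
        pct_g=pct["G"],
        pct_c=pct["C"],
        pct_gc=pct["G"] + pct["C"],
        n50=n50(lengths),
        max_len=max(lengths),
        min_len=min(lengths),
        median_len=statistics.median(lengths),
    )
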