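"""Best-hit selection and identity-binned summaries of proteome searches.

A proteome-vs-proteome BLASTP run yields many hits per query; downstream
comparison keeps the single best e-value hit per query and summarizes
the best hits into sequence-identity bins: exactly 100%, [95, 100),
[90, 95), [80, 90) and below 80.  Cross-referencing two searches (the
same queries against two reference proteomes) counts queries satisfying
an identity predicate in both.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

from ctga.io_formats import ProteinMatch

__all__ = [
    "IdentityBinSummary",
    "BIN_LABELS",
    "best_hit_per_query",
    "bin_by_identity",
    "intersect_identity_sets",
]

BIN_LABELS = (
    "=100",
    "<100 AND >=95",
    "<95 AND >=90",
    "<90 AND >=80",
    "<80",
)


def _bin_of(pct: float) -> str:
    if not 0.0 <= pct <= 100.0:
        raise ValueError(f"identity {pct} outside [0, 100]")
    if pct == 100.0:
        return "=100"
    if pct >= 95.0:
        return "<100 AND >=95"
    if pct >= 90.0:
        return "<95 AND >=90"
    if pct >= 80.0:
        return "<90 AND >=80"
    return "<80"


@dataclass(frozen=True)
class IdentityBinSummary:
    """Counts of best hits per identity bin; bins are disjoint and
    exhaustive over [0, 100], so the counts sum to the number of queries
    with any hit."""

    counts: Mapping[str, int]
    total_found: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total_found:
            raise ValueError("bin counts do not sum to total_found")


def _hit_sort_key(match: ProteinMatch) -> tuple:
    # minimal e-value, then maximal bitscore, maximal identity,
    # lexicographically smallest subject — fully deterministic
    return (match.evalue, -match.bitscore, -match.pct_identity, match.subject_id)


def best_hit_per_query(
    matches: Iterable[ProteinMatch],
) -> dict[str, ProteinMatch]:
    """Keep one hit per query: the best e-value, deterministic tie-breaks."""
    best: dict[str, ProteinMatch] = {}
    for match in matches:
        cur = best.get(match.query_id)
        if cur is None or _hit_sort_key(match) < _hit_sort_key(cur):
            best[match.query_id] = match
    return best


def bin_by_identity(best_hits: Mapping[str, ProteinMatch]) -> IdentityBinSummary:
    """Summarize best hits into the standard identity bins.

    'Exactly 100' means the tabular pident field parsed to 100.00; no
    alignment-coverage condition is applied.
    """
    counts = {label: 0 for label in BIN_LABELS}
    for match in best_hits.values():
        counts[_bin_of(match.pct_identity)] += 1
    return IdentityBinSummary(counts=counts, total_found=len(best_hits))


def intersect_identity_sets(
    best_a: Mapping[str, ProteinMatch],
    best_b: Mapping[str, ProteinMatch],
    pred_a: Callable[[float], bool],
    pred_b: Callable[[float], bool],
) -> int:
    """Count queries whose best-hit identity satisfies ``pred_a`` in A and
    ``pred_b`` in B.  Queries missing from either map never match."""
    return sum(
        1
        for query, match in best_a.items()
        if pred_a(match.pct_identity)
        and query in best_b
        and pred_b(best_b[query].pct_identity)
    )
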