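"""End-to-end orchestration: generate or load a study, place contigs,
collect every evidence track, vote, and report.

This is the programmatic equivalent of running the CLI subcommands in
sequence, used by the test-suite and the reproduction script.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from ctga import composition, genome_stats, protein_match
from ctga.evidence_consensus import (
    BACFISH_SOURCE,
    ConsensusAssignment,
    EvidenceRecord,
    consensus_for_all,
    build_integrated_table,
    loci_to_evidence,
    normalize_chromosome,
)
from ctga.homology_placement import (
    AnchorIndex,
    Placement,
    agp_to_evidence,
    build_anchor_index,
    order_and_export,
    place_all,
)
from ctga.io_formats import (
    read_blast_tab,
    read_fasta,
    read_gff_genes,
    read_locus_hits,
    read_repeatmasker_out,
)
from ctga.synthetic_data import SyntheticStudy

__all__ = [
    "PipelineResult",
    "read_two_column_map",
    "read_marker_track",
    "blast_to_evidence",
    "run_synthetic_pipeline",
    "verify_reference_statistics",
]


def read_two_column_map(path: str | Path) -> dict[str, str]:
    """Read a headered two-column TSV into a dict (id -> chromosome)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)  # header
        for row in reader:
            out[row[0]] = row[1]
    return out


def read_marker_track(path: str | Path, source: str = "markers") -> list[EvidenceRecord]:
    """Read a marker TSV (locus_id, contig_id, pct_identity, chromosome)."""
    records = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            records.append(
                EvidenceRecord(
                    contig_id=row["contig_id"],
                    chromosome=normalize_chromosome(row["chromosome"]),
                    source=source,
                    locus_id=row["locus_id"],
                )
            )
    return records


def blast_to_evidence(
    matches_path: str | Path,
    query_contig_map: Mapping[str, str],
    subject_chrom_map: Mapping[str, str],
    source: str,
) -> list[EvidenceRecord]:
    """Protein-homology evidence: each query's best subject claims the
    subject's chromosome for the query's host contig."""
    best = protein_match.best_hit_per_query(read_blast_tab(matches_path))
    records = []
    for query, match in sorted(best.items()):
        contig = query_contig_map.get(query)
        chrom = subject_chrom_map.get(match.subject_id)
        if contig is None or chrom is None:
            continue
        records.append(
            EvidenceRecord(
                contig_id=contig,
                chromosome=normalize_chromosome(chrom),
                source=source,
                locus_id=query,
            )
        )
    return records


@dataclass
class PipelineResult:
    placements: list[Placement]
    agp: list
    evidence: list[EvidenceRecord]
    consensus_all: dict[str, ConsensusAssignment]
    consensus_bioinformatics: dict[str, ConsensusAssignment]
    integrated: pd.DataFrame
    composition_placed: composition.PartitionComposition
    composition_unplaced: composition.PartitionComposition


def run_synthetic_pipeline(
    study: SyntheticStudy,
    k: int = 21,
    min_anchors: int = 10,
    min_confidence: float = 0.8,
) -> PipelineResult:
    """Run the whole pipeline on a generated study's files."""
    reference = read_fasta(study.files["reference.fa"])
    contigs = read_fasta(study.files["contigs.fa"])
    contig_lengths = {c.id: len(c) for c in contigs}

    index = build_anchor_index(reference, k=k)
    placements = place_all(
        contigs, index, min_anchors=min_anchors, min_confidence=min_confidence
    )
    agp = order_and_export(placements, contig_lengths, reference_tag="ref")

    evidence: list[EvidenceRecord] = []
    evidence += agp_to_evidence(agp, reference_tag="ref")
    evidence += read_marker_track(study.files["markers.tsv"])
    evidence += loci_to_evidence(
        read_locus_hits(study.files["dart_hits.tsv"]),
        read_two_column_map(study.files["dart_map.tsv"]),
        source="dart",
        min_identity=90.0,
    )
    evidence += loci_to_evidence(
        read_locus_hits(study.files["stc_hits.tsv"]),
        read_two_column_map(study.files["stc_map.tsv"]),
        source=BACFISH_SOURCE,
        min_identity=90.0,
    )
    gene_contig = dict(study.truth.gene_contig)
    for tag in ("refA", "refB"):
        evidence += blast_to_evidence(
            study.files[f"blastp_{tag}.tsv"],
            gene_contig,
            read_two_column_map(study.files[f"subject_map_{tag}.tsv"]),
            source=f"blastp:{tag}",
        )

    universe = sorted(contig_lengths, key=lambda c: int(c[3:]))
    consensus_all = consensus_for_all(evidence, universe)
    consensus_bio = consensus_for_all(
        evidence, universe, exclude_sources=(BACFISH_SOURCE,)
    )
    integrated = build_integrated_table(
        universe,
        evidence,
        source_order=(
            "markers",
            "scaffold:ref",
            "blastp:refA",
            "blastp:refB",
            "dart",
            BACFISH_SOURCE,
        ),
    )

    repeats = read_repeatmasker_out(study.files["repeats.out"])
    genes = read_gff_genes(study.files["genes.gff3"])
    placed, unplaced = composition.compute_composition(
        placements, contigs, repeats, genes
    )

    return PipelineResult(
        placements=placements,
        agp=agp,
        evidence=evidence,
        consensus_all=consensus_all,
        consensus_bioinformatics=consensus_bio,
        integrated=integrated,
        composition_placed=placed,
        composition_unplaced=unplaced,
    )


#: published whole-assembly statistics for the three cucumber genomes,
#: used to validate locally provided copies of the public FASTA files
REFERENCE_ASSEMBLY_STATS: dict[str, dict[str, int]] = {
    "B10v3": {
        "genome_size": 342_288_160,
        "n_contigs": 8035,
        "n50": 857_970,
        "max_len": 12_672_375,
        "min_len": 3684,
        "median_len": 15_301,
    },
    "Gy14": {"n_contigs": 8, "n50": 33_288_019, "max_len": 41_698_299},
    "9930": {"n_contigs": 85, "n50": 31_125_843, "max_len": 40_877_379},
}


def verify_reference_statistics(
    fasta_path: str | Path, expected: Mapping[str, int]
) -> dict[str, tuple[int, int, bool]]:
    """Compare computed assembly statistics with expected published values.

    Returns ``{metric: (computed, expected, matches)}`` for every metric
    in ``expected``.  Intended for validating locally downloaded copies
    of the public genomes against :data:`REFERENCE_ASSEMBLY_STATS`.
    """
    stats = genome_stats.compute_assembly_stats(read_fasta(fasta_path))
    report: dict[str, tuple[int, int, bool]] = {}
    for metric, want in expected.items():
        got = getattr(stats, metric)
        report[metric] = (got, want, got == want)
    return report
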