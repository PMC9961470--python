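"""Bundled worked example: published integration evidence for the
cucumber B10v3 assembly.

The B10v3 cucumber genome (342 Mb, 8035 contigs) was organized into
chromosomes by combining seven evidence tracks: assembly markers,
reference-guided scaffolding against the 9930 and Gy14 genomes, protein
homology (BLASTP) against both reference proteomes, DArT-seq loci on the
genetic map, and BAC/FISH probe localization.  This module carries the
published per-source chromosome claims for the six FISH-verified contigs
together with the twelve STC (sequence-tagged connector) probe rows that
tie BAC clones to contigs — a complete, desk-sized input for the
consensus machinery.

For ctg775 and ctg1000 (hit by STC probes but outside the six-contig
integrated snippet) the per-source breakdown was not published; their
entry carries the published aggregate bioinformatics localization as a
single claim under source ``stc_blastn``.
"""

from __future__ import annotations

from ctga.evidence_consensus import EvidenceRecord

__all__ = [
    "fish_contig_evidence",
    "stc_probe_rows",
    "stc_contig_evidence",
]

# per-source chromosome claims for the six FISH-verified contigs
# (source -> claimed chromosome); blank cells omitted
_FISH_EVIDENCE: dict[str, dict[str, str]] = {
    "ctg2607": {
        "markers": "Chr3",
        "scaffold:9930": "Chr3_9930",
        "scaffold:Gy14": "Chr3_Gy14",
        "blastp:9930": "Chr3",
        "blastp:gy14": "Chr3",
        "dart": "Chr3",
        "bac_fish": "Chr1",
    },
    "ctg105": {
        "markers": "Chr2",
        "scaffold:9930": "Chr2_9930",
        "scaffold:Gy14": "Chr2_Gy14",
        "blastp:9930": "Chr2",
        "blastp:gy14": "Chr2",
        "dart": "Chr2",
        "bac_fish": "Chr2",
    },
    "ctg184": {
        "markers": "Chr4",
        "scaffold:9930": "Chr4_9930",
        "scaffold:Gy14": "Chr4_Gy14",
        "blastp:9930": "Chr4",
        "blastp:gy14": "Chr4",
        "dart": "Chr4",
        "bac_fish": "Chr4",
    },
    "ctg197": {
        "markers": "Chr5",
        "scaffold:9930": "Chr5_9930",
        "scaffold:Gy14": "Chr5_Gy14",
        "blastp:9930": "Chr5",
        "blastp:gy14": "Chr5",
        "dart": "Chr5",
        "bac_fish": "Chr5",
    },
    "ctg1673": {
        "markers": "Chr5",
        "scaffold:9930": "Chr5_9930",
        "scaffold:Gy14": "Chr5_Gy14",
        "blastp:9930": "Chr5",
        "blastp:gy14": "Chr5",
        "dart": "Chr5",
        "bac_fish": "Chr5",
    },
    "ctg1047": {
        "markers": "Chr7",
        "scaffold:9930": "Chr7_9930",
        "scaffold:Gy14": "Chr7_Gy14",
        "blastp:9930": "Chr7",
        "blastp:gy14": "Chr7",
        # no DArT-seq claim for ctg1047
        "bac_fish": "Chr7",
    },
}

# STC probe -> (contig hit by BLASTN, published bioinformatics consensus,
#               chromosome according to BAC analysis)
_STC_ROWS: list[tuple[str, str, str, str]] = [
    ("STC1_Bam_024_D19_M13", "ctg105", "Chr2", "Chr2"),
    ("STC1_Bam_007_M21_M13", "ctg184", "Chr4", "Chr4"),
    ("STC1_Bam_022_G02_M13", "ctg184", "Chr4", "Chr4"),
    ("STC1_Bam_001_J07_M13", "ctg184", "Chr4", "Chr3"),
    ("STC1_Bam_065_A04_M13", "ctg1673", "Chr5", "Chr5"),
    ("STC1_Bam_002_E06_M13", "ctg2607", "Chr3", "Chr1"),
    ("STC1_Bam_041_H23_M13", "ctg1047", "Chr7", "Chr7"),
    ("STC1_Bam_002_L09_M13", "ctg197", "Chr5", "Chr5"),
    ("STC1_Bam_062_O16_M13", "ctg775", "Chr5", "Chr5"),
    ("STC1_Bam_072_K05_M13", "ctg105", "Chr2", "Chr2"),
    ("STC1_Bam_038_P19_M13", "ctg1000", "Chr6", "Chr6"),
    ("STC1_Bam_065_L02_M13", "ctg775", "Chr5", "Chr5"),
]

# aggregate bioinformatics localization for the STC-only contigs
_STC_ONLY_EVIDENCE: dict[str, dict[str, str]] = {
    "ctg775": {"stc_blastn": "Chr5"},
    "ctg1000": {"stc_blastn": "Chr6"},
}


def _to_records(table: dict[str, dict[str, str]]) -> list[EvidenceRecord]:
    return [
        EvidenceRecord(contig_id=cid, chromosome=_bare(chrom), source=source)
        for cid, claims in table.items()
        for source, chrom in claims.items()
    ]


def _bare(label: str) -> str:
    from ctga.evidence_consensus import normalize_chromosome

    return normalize_chromosome(label)


def fish_contig_evidence() -> list[EvidenceRecord]:
    """Evidence records for the six FISH-verified contigs."""
    return _to_records(_FISH_EVIDENCE)


def stc_probe_rows() -> list[tuple[str, str, str, str]]:
    """The twelve STC probe rows:
    (probe_id, contig, published bioinformatics consensus, BAC chromosome)."""
    return list(_STC_ROWS)


def stc_contig_evidence() -> list[EvidenceRecord]:
    """Non-BAC evidence for every contig hit by an STC probe: the full
    per-source claims where published, the aggregate localization for
    ctg775/ctg1000."""
    records = [
        r for r in fish_contig_evidence() if r.source != "bac_fish"
    ]
    records += _to_records(_STC_ONLY_EVIDENCE)
    return records
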