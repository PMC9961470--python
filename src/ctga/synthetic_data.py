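"""Miniature multi-chromosome study with known ground truth.

The generator emulates the shape of a fragmented plant genome project:
a chromosome-level reference (default seven chromosomes, ~1 Mb total,
matching the cucumber karyotype at toy scale), an assembly produced by
cutting a mutated copy of that reference into contigs, annotations
(genes with protein-coding/lncRNA biotypes, repeat intervals in
RepeatMasker ``.out`` layout), and the five evidence tracks the
integration stage consumes — markers, locus BLASTN hit tables for
DArT-seq and STC probes with their genetic-map assignments, and protein
best-hit tables against two reference proteomes.

Repeat arrays are tandem copies of a few short motifs (Type-III/Type-IV
tandem-unit-like and an rDNA-like unit) placed pericentromerically and
shared across chromosomes, so contigs drawn entirely from an array
carry no unique k-mer anchors and are genuinely unplaceable by
homology.  Evidence corruption swaps a claim to a uniformly random
other chromosome and is always recorded in the truth object, one
corruption per (source, contig) claim.

Everything is driven by one integer seed; two runs with the same
parameters are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import kendalltau

from ctga.evidence_consensus import ConsensusAssignment
from ctga.homology_placement import Placement, revcomp
from ctga.io_formats import SequenceRecord, write_fasta

__all__ = [
    "SyntheticParams",
    "SyntheticTruth",
    "SyntheticStudy",
    "generate",
    "truth_compare",
    "inject_corruptions",
]

_REPEAT_FAMILIES = ("TypeIII", "TypeIV", "rDNA45S")
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticParams:
    """Knobs of the generated study; defaults describe the standard
    conditions all recovery tests run under."""

    n_chromosomes: int = 7
    chrom_len_range: tuple[int, int] = (120_000, 160_000)
    substitution_rate: float = 0.01
    indel_rate: float = 0.0005
    contig_len_range: tuple[int, int] = (2_000, 50_000)
    repeat_unit_len: int = 180
    repeat_mass_fraction: float = 0.10
    interspersed_repeat_fraction: float = 0.25  # on gene-bearing contigs
    n_genes: int = 140
    lncRNA_proportion_unique: float = 0.23
    lncRNA_proportion_repeat: float = 0.74
    n_markers: int = 25
    n_dart: int = 30
    n_stc: int = 12
    evidence_error_rate: float = 0.05
    seed: int = 42

    def validate(self) -> None:
        for rate in (
            self.substitution_rate,
            self.indel_rate,
            self.evidence_error_rate,
        ):
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"rate {rate} outside [0, 1)")
        if self.contig_len_range[0] > self.chrom_len_range[1]:
            raise ValueError(
                "minimum contig length exceeds maximum chromosome length"
            )
        if min(self.chrom_len_range + self.contig_len_range) <= 0:
            raise ValueError("lengths must be positive")
        if self.repeat_mass_fraction and (
            self.repeat_mass_fraction * self.chrom_len_range[0]
            < 3 * self.repeat_unit_len
        ):
            raise ValueError(
                "repeat arrays need room for at least three tandem unit copies"
            )


@dataclass
class SyntheticTruth:
    """Ground truth of one generated study."""

    contig_chrom: dict[str, str]  # every contig's true chromosome
    contig_order: dict[str, int]  # order index along its chromosome
    contig_orientation: dict[str, str]  # '+' kept, '-' reverse-complemented
    contig_is_repeat: dict[str, bool]  # drawn entirely from a repeat array
    repeat_bp: dict[str, int]  # planted (merged) repeat bases per contig
    gene_contig: dict[str, str]
    gene_biotype: dict[str, str]
    locus_chrom: dict[str, str]  # true chromosome per evidence locus
    corruptions: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SyntheticStudy:
    """In-memory handles to everything :func:`generate` wrote."""

    params: SyntheticParams
    outdir: Path
    reference: list[SequenceRecord]
    contigs: list[SequenceRecord]
    truth: SyntheticTruth
    files: dict[str, Path]


# --------------------------------------------------------------------------
# sequence helpers


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mutate(
    seq: str, sub_rate: float, indel_rate: float, rng: np.random.Generator
) -> str:
    """Substitutions and single-base indels at the given per-base rates."""
    arr = np.array(list(seq))
    if sub_rate > 0:
        hits = np.flatnonzero(rng.random(arr.size) < sub_rate)
        if hits.size:
            # shift by 1-3 in base order: always a different base
            shift = rng.integers(1, 4, size=hits.size)
            index = {b: i for i, b in enumerate("ACGT")}
            old = np.array([index[b] for b in arr[hits]])
            arr[hits] = _BASES[(old + shift) % 4]
    out = arr.tolist()
    if indel_rate > 0:
        hits = np.flatnonzero(rng.random(len(out)) < indel_rate)
        for pos in hits[::-1]:  # right to left so positions stay valid
            if rng.random() < 0.5 and len(out) > 1:
                del out[pos]
            else:
                out.insert(int(pos), str(_BASES[rng.integers(0, 4)]))
    return "".join(out)


def _partition_lengths(
    total: int, lo: int, hi: int, rng: np.random.Generator
) -> list[int]:
    """Cut ``total`` into pieces of length ~U(lo, hi); a too-short tail is
    folded into the previous piece."""
    pieces: list[int] = []
    left = total
    while left > 0:
        size = int(rng.integers(lo, hi + 1))
        if size >= left:
            size = left
        pieces.append(size)
        left -= size
    if len(pieces) > 1 and pieces[-1] < max(500, lo // 4):
        tail = pieces.pop()
        pieces[-1] += tail
    return pieces


# --------------------------------------------------------------------------
# corruption


def inject_corruptions(
    claims: Sequence[tuple[str, str, str, str]],
    chromosomes: Sequence[str],
    error_rate: float,
    rng: np.random.Generator,
) -> tuple[list[tuple[str, str, str, str]], list[dict]]:
    """Corrupt claims ``(source, locus_id, contig_id, chromosome)`` at the
    given per-claim rate, swapping to a uniformly random *other*
    chromosome.  Returns (claims after corruption, corruption log)."""
    out: list[tuple[str, str, str, str]] = []
    log: list[dict] = []
    for source, locus, contig, chrom in claims:
        if error_rate > 0 and rng.random() < error_rate:
            others = [c for c in chromosomes if c != chrom]
            wrong = others[int(rng.integers(0, len(others)))]
            log.append(
                {
                    "source": source,
                    "locus_id": locus,
                    "contig_id": contig,
                    "true_chromosome": chrom,
                    "corrupted_chromosome": wrong,
                }
            )
            chrom = wrong
        out.append((source, locus, contig, chrom))
    return out, log


# --------------------------------------------------------------------------
# generation


def generate(params: SyntheticParams, outdir: str | Path) -> SyntheticStudy:
    """Generate the full study into ``outdir`` and return handles.

    Files written: ``reference.fa``, ``contigs.fa``, ``genes.gff3``,
    ``repeats.out``, ``markers.tsv``, ``{dart,stc}_hits.tsv`` +
    ``{dart,stc}_map.tsv``, ``blastp_ref{A,B}.tsv`` +
    ``subject_map_ref{A,B}.tsv`` and ``truth.json``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    motifs = [_random_seq(rng, params.repeat_unit_len) for _ in _REPEAT_FAMILIES]

    # ---- reference chromosomes with pericentromeric repeat arrays
    chroms: list[SequenceRecord] = []
    # (chrom, order, start, length, is_repeat, family)
    segments: list[tuple[str, int, int, int, bool, str | None]] = []
    for ci in range(params.n_chromosomes):
        chrom_id = f"Chr{ci + 1}"
        length = int(rng.integers(*params.chrom_len_range))
        family_i = ci % len(_REPEAT_FAMILIES)
        array_len = int(params.repeat_mass_fraction * length)
        if array_len and array_len < 3 * params.repeat_unit_len:
            array_len = 3 * params.repeat_unit_len
        if array_len:
            left_len = int((length - array_len) * rng.uniform(0.4, 0.6))
        else:
            left_len = length  # no pericentromeric array: one unique region
        right_len = length - array_len - left_len
        left = _random_seq(rng, left_len)
        right = _random_seq(rng, right_len)
        if array_len:
            unit = motifs[family_i]
            array = (unit * (array_len // len(unit) + 1))[:array_len]
        else:
            array = ""
        chroms.append(SequenceRecord(chrom_id, left + array + right))
        order = 0
        cursor = 0
        for region_len, is_rep in ((left_len, False), (array_len, True), (right_len, False)):
            if region_len == 0:
                continue
            for piece in _partition_lengths(
                region_len, *params.contig_len_range, rng
            ):
                segments.append(
                    (
                        chrom_id,
                        order,
                        cursor,
                        piece,
                        is_rep,
                        _REPEAT_FAMILIES[family_i] if is_rep else None,
                    )
                )
                order += 1
                cursor += piece

    # ---- fragment into named, shuffled, mutated contigs
    perm = rng.permutation(len(segments))
    chrom_seq = {c.id: c.seq for c in chroms}
    contigs: list[SequenceRecord] = []
    truth = SyntheticTruth(
        contig_chrom={},
        contig_order={},
        contig_orientation={},
        contig_is_repeat={},
        repeat_bp={},
        gene_contig={},
        gene_biotype={},
        locus_chrom={},
    )
    contig_family: dict[str, str | None] = {}
    for new_i, seg_i in enumerate(perm):
        chrom_id, order, start, length, is_rep, family = segments[seg_i]
        cid = f"ctg{new_i + 1}"
        seq = _mutate(
            chrom_seq[chrom_id][start : start + length],
            params.substitution_rate,
            params.indel_rate,
            rng,
        )
        orientation = "+" if rng.random() < 0.5 else "-"
        if orientation == "-":
            seq = revcomp(seq)
        contigs.append(SequenceRecord(cid, seq))
        truth.contig_chrom[cid] = chrom_id
        truth.contig_order[cid] = order
        truth.contig_orientation[cid] = orientation
        truth.contig_is_repeat[cid] = is_rep
        contig_family[cid] = family

    contig_len = {c.id: len(c) for c in contigs}
    unique_contigs = sorted(
        (cid for cid, rep in truth.contig_is_repeat.items() if not rep),
        key=lambda cid: int(cid[3:]),
    )
    repeat_contigs = sorted(
        (cid for cid, rep in truth.contig_is_repeat.items() if rep),
        key=lambda cid: int(cid[3:]),
    )
    chromosomes = [c.id for c in chroms]

    # ---- repeat annotation (.out): repeat contigs fully covered, unique
    # contigs carry disjoint interspersed intervals; some intervals are
    # written as two overlapping rows to exercise downstream merging
    repeat_rows: list[tuple[str, int, int, str, str]] = []  # contig, start0, end0, strand, family
    for cid in repeat_contigs:
        truth.repeat_bp[cid] = contig_len[cid]
        repeat_rows.append((cid, 0, contig_len[cid], "+", contig_family[cid]))
    for cid in unique_contigs:
        target = int(params.interspersed_repeat_fraction * contig_len[cid])
        planted = 0
        cursor = 0
        spans: list[tuple[int, int]] = []
        while planted < target and cursor < contig_len[cid] - 300:
            span = int(rng.integers(150, 1200))
            start = cursor + int(rng.integers(50, 400))
            end = min(start + span, contig_len[cid])
            if end <= start:
                break
            spans.append((start, end))
            planted += end - start
            cursor = end
        truth.repeat_bp[cid] = sum(e - s for s, e in spans)
        for start, end in spans:
            family = _REPEAT_FAMILIES[int(rng.integers(0, len(_REPEAT_FAMILIES)))]
            strand = "+" if rng.random() < 0.5 else "-"
            if end - start > 400 and rng.random() < 0.3:
                mid = (start + end) // 2
                repeat_rows.append((cid, start, mid + 50, strand, family))
                repeat_rows.append((cid, mid - 50, end, strand, family))
            else:
                repeat_rows.append((cid, start, end, strand, family))

    # ---- genes: mostly on unique contigs, lncRNA-enriched on repeat contigs
    n_repeat_genes = max(1, int(round(0.06 * params.n_genes)))
    gene_rows: list[tuple[str, int, int, str, str, str]] = []
    unique_weights = np.array([contig_len[c] for c in unique_contigs], dtype=float)
    unique_weights /= unique_weights.sum()
    for gi in range(params.n_genes):
        gene_id = f"gene{gi + 1}"
        on_repeat = gi < n_repeat_genes and repeat_contigs
        if on_repeat:
            cid = repeat_contigs[int(rng.integers(0, len(repeat_contigs)))]
            lnc_p = params.lncRNA_proportion_repeat
        else:
            cid = unique_contigs[int(rng.choice(len(unique_contigs), p=unique_weights))]
            lnc_p = params.lncRNA_proportion_unique
        biotype = "lncRNA" if rng.random() < lnc_p else "protein_coding"
        glen = int(rng.integers(300, 1500))
        start = int(rng.integers(0, max(1, contig_len[cid] - glen)))
        end = min(start + glen, contig_len[cid])
        strand = "+" if rng.random() < 0.5 else "-"
        gene_rows.append((cid, start, end, strand, gene_id, biotype))
        truth.gene_contig[gene_id] = cid
        truth.gene_biotype[gene_id] = biotype

    # ---- evidence tracks: distinct unique contigs per track, one locus
    # per (source, contig); claims corrupted at evidence_error_rate
    def sample_contigs(n: int) -> list[str]:
        n = min(n, len(unique_contigs))
        idx = rng.choice(len(unique_contigs), size=n, replace=False)
        return [unique_contigs[i] for i in sorted(idx)]

    claims: list[tuple[str, str, str, str]] = []
    for source, prefix, count in (
        ("markers", "MRK", params.n_markers),
        ("dart", "DART", params.n_dart),
        ("bac_fish", "STC", params.n_stc),
    ):
        for i, cid in enumerate(sample_contigs(count)):
            locus = f"{prefix}{i + 1:03d}"
            truth.locus_chrom[locus] = truth.contig_chrom[cid]
            claims.append((source, locus, cid, truth.contig_chrom[cid]))
    claims, truth.corruptions = inject_corruptions(
        claims, chromosomes, params.evidence_error_rate, rng
    )

    # ---- protein best-hit tables vs two reference proteomes
    pc_genes = [g for g, b in truth.gene_biotype.items() if b == "protein_coding"]
    blast_tables: dict[str, list[str]] = {"refA": [], "refB": []}
    subject_maps: dict[str, list[tuple[str, str]]] = {"refA": [], "refB": []}
    for tag in ("refA", "refB"):
        for gi, gene in enumerate(pc_genes):
            chrom = truth.contig_chrom[truth.gene_contig[gene]]
            subject = f"{tag}_g{gi + 1}"
            subject_maps[tag].append((subject, chrom))
            draw = rng.random()
            if draw < 0.55:
                pident = "100.00"
            elif draw < 0.9:
                pident = f"{rng.uniform(95.0, 99.99):.2f}"
            elif draw < 0.97:
                pident = f"{rng.uniform(85.0, 94.99):.2f}"
            else:
                pident = f"{rng.uniform(40.0, 79.99):.2f}"
            aln = int(rng.integers(80, 600))
            evalue = f"{rng.uniform(1e-180, 1e-20):.3e}"
            bits = f"{rng.uniform(100, 900):.1f}"
            blast_tables[tag].append(
                f"{gene}\t{subject}\t{pident}\t{aln}\t0\t0\t1\t{aln}\t1\t{aln}\t{evalue}\t{bits}"
            )

    # ---- write everything
    files: dict[str, Path] = {}

    def _write(name: str, text: str) -> None:
        path = outdir / name
        path.write_text(text)
        files[name] = path

    write_fasta(chroms, outdir / "reference.fa")
    files["reference.fa"] = outdir / "reference.fa"
    write_fasta(contigs, outdir / "contigs.fa")
    files["contigs.fa"] = outdir / "contigs.fa"

    gff_lines = ["##gff-version 3"]
    for cid, start, end, strand, gene_id, biotype in sorted(gene_rows):
        gff_lines.append(
            f"{cid}\tctga_synth\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\t"
            f"ID={gene_id};biotype={biotype}"
        )
    _write("genes.gff3", "\n".join(gff_lines) + "\n")

    rm_lines = [
        "   SW  perc perc perc  query     position in query    matching PLACEHOLDER",
        "score  div. del. ins.  sequence  begin end (left)     repeat class/family",
        "",
    ]
    for cid, start, end, strand, family in sorted(repeat_rows):
        sw = int(rng.integers(200, 5000))
        div = f"{rng.uniform(0.0, 25.0):.1f}"
        strand_col = "+" if strand == "+" else "C"
        rm_lines.append(
            f"{sw} {div} 0.0 0.0 {cid} {start + 1} {end} "
            f"({contig_len[cid] - end}) {strand_col} {family}-unit {family}"
        )
    _write("repeats.out", "\n".join(rm_lines) + "\n")

    marker_lines = ["locus_id\tcontig_id\tpct_identity\tchromosome"]
    dart_hits: list[str] = []
    dart_map = ["locus_id\tchromosome"]
    stc_hits: list[str] = []
    stc_map = ["locus_id\tchromosome"]
    for source, locus, cid, chrom in claims:
        if source == "markers":
            marker_lines.append(f"{locus}\t{cid}\t100.00\t{chrom}")
            continue
        hits, lmap = (dart_hits, dart_map) if source == "dart" else (stc_hits, stc_map)
        lmap.append(f"{locus}\t{chrom}")
        hit_len = int(rng.integers(60, 200))
        start = int(rng.integers(1, max(2, contig_len[cid] - hit_len)))
        pident = f"{rng.uniform(94.0, 100.0):.2f}"
        hits.append(
            f"{locus}\t{cid}\t{pident}\t{hit_len}\t0\t0\t1\t{hit_len}\t"
            f"{start}\t{start + hit_len - 1}\t1e-50\t{hit_len * 1.8:.1f}"
        )
        # sub-threshold decoy hit on some other contig: must be filtered out
        if rng.random() < 0.3:
            other = unique_contigs[int(rng.integers(0, len(unique_contigs)))]
            hits.append(
                f"{locus}\t{other}\t{rng.uniform(70.0, 89.9):.2f}\t{hit_len}\t"
                f"9\t1\t1\t{hit_len}\t1\t{hit_len}\t1e-10\t{hit_len * 0.9:.1f}"
            )
    _write("markers.tsv", "\n".join(marker_lines) + "\n")
    _write("dart_hits.tsv", "\n".join(dart_hits) + "\n" if dart_hits else "")
    _write("dart_map.tsv", "\n".join(dart_map) + "\n")
    _write("stc_hits.tsv", "\n".join(stc_hits) + "\n" if stc_hits else "")
    _write("stc_map.tsv", "\n".join(stc_map) + "\n")
    for tag in ("refA", "refB"):
        _write(f"blastp_{tag}.tsv", "\n".join(blast_tables[tag]) + "\n")
        _write(
            f"subject_map_{tag}.tsv",
            "subject_id\tchromosome\n"
            + "\n".join(f"{s}\t{c}" for s, c in subject_maps[tag])
            + "\n",
        )
    truth.to_json(outdir / "truth.json")
    files["truth.json"] = outdir / "truth.json"

    return SyntheticStudy(
        params=params,
        outdir=outdir,
        reference=chroms,
        contigs=contigs,
        truth=truth,
        files=files,
    )


# --------------------------------------------------------------------------
# accuracy against truth


def truth_compare(
    result: Sequence[Placement] | Mapping[str, ConsensusAssignment],
    truth: SyntheticTruth,
) -> dict[str, float]:
    """Score a placement list or a consensus map against ground truth.

    Placements yield ``chromosome_accuracy`` (fraction of
    chromosome-carrying contigs on their true chromosome), ``placed_rate``
    and ``mean_kendall_tau`` (contig order along each chromosome).
    Consensus maps additionally yield ``conflict_precision`` and
    ``conflict_recall`` of the injected evidence corruptions.
    """
    if isinstance(result, Mapping):
        unknown = set(result) - set(truth.contig_chrom)
        if unknown:
            raise ValueError(f"contigs absent from truth: {sorted(unknown)[:5]}")
        assigned = {
            cid: c for cid, c in result.items() if c.status == "assigned"
        }
        correct = sum(
            1 for cid, c in assigned.items() if c.consensus == truth.contig_chrom[cid]
        )
        detected = {
            (cid, source)
            for cid, c in result.items()
            for source, _ in c.conflicts
        }
        injected = {
            (corr["contig_id"], corr["source"]) for corr in truth.corruptions
        }
        hits = detected & injected
        return {
            "chromosome_accuracy": correct / len(assigned) if assigned else 0.0,
            "assigned_rate": len(assigned) / len(result) if result else 0.0,
            "conflict_precision": len(hits) / len(detected) if detected else 1.0,
            "conflict_recall": len(hits) / len(injected) if injected else 1.0,
        }

    unknown = {p.contig_id for p in result} - set(truth.contig_chrom)
    if unknown:
        raise ValueError(f"contigs absent from truth: {sorted(unknown)[:5]}")
    placed = [p for p in result if p.status == "placed"]
    correct = sum(
        1 for p in placed if p.chromosome_id == truth.contig_chrom[p.contig_id]
    )
    taus: list[float] = []
    by_chrom: dict[str, list[Placement]] = {}
    for p in placed:
        if p.chromosome_id == truth.contig_chrom[p.contig_id]:
            by_chrom.setdefault(p.chromosome_id, []).append(p)
    for chrom, group in by_chrom.items():
        if len(group) < 2:
            continue
        positions = [p.position for p in group]
        true_order = [truth.contig_order[p.contig_id] for p in group]
        tau = kendalltau(positions, true_order).statistic
        if not np.isnan(tau):
            taus.append(tau)
    return {
        "chromosome_accuracy": correct / len(placed) if placed else 0.0,
        "placed_rate": len(placed) / len(result) if result else 0.0,
        "mean_kendall_tau": float(np.mean(taus)) if taus else float("nan"),
    }
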