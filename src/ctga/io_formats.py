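"""Readers and writers for the external formats the pipeline touches.

Every on-disk format here uses 1-based inclusive coordinates (FASTA has
none; AGP, GFF3, RepeatMasker ``.out`` and BLAST tabular all do).  The
package keeps interval coordinates 0-based half-open internally —
:class:`FeatureInterval` converts at the boundary — while
:class:`AgpRecord` mirrors the AGP column layout verbatim because AGP
rows are exchanged with external scaffolders and must round-trip
byte-for-byte.

All readers are strict: a malformed line aborts the parse with a
:class:`FormatError` naming the offending line; no partial results are
returned silently.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from gffutils.feature import feature_from_line

__all__ = [
    "FormatError",
    "SequenceRecord",
    "AgpRecord",
    "FeatureInterval",
    "ProteinMatch",
    "LocusHit",
    "read_fasta",
    "write_fasta",
    "read_agp",
    "write_agp",
    "read_gff_genes",
    "read_repeatmasker_out",
    "read_blast_tab",
    "read_locus_hits",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


# --------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or amino-acid sequence (one FASTA record)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.seq:
            raise FormatError(f"sequence record {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AgpRecord:
    """One AGP v2.x line: a contig (W) or gap (U) part of a larger object.

    Coordinates follow the AGP convention: 1-based inclusive, both on the
    object being built and on the component placed into it.
    """

    object_id: str
    object_beg: int
    object_end: int
    part_number: int
    component_type: str  # 'W' (contig) or 'U' (gap of unknown size)
    # W fields
    component_id: str | None = None
    component_beg: int | None = None
    component_end: int | None = None
    orientation: str | None = None
    # U fields
    gap_length: int | None = None
    gap_type: str | None = None
    linkage: str | None = None
    evidence: str | None = None

    def validate(self) -> None:
        if self.component_type not in ("W", "U"):
            raise FormatError(
                f"unknown component_type {self.component_type!r} "
                f"(object {self.object_id}, part {self.part_number})"
            )
        if self.object_end < self.object_beg:
            raise FormatError(
                f"object_end < object_beg on {self.object_id} part {self.part_number}"
            )
        if self.part_number < 1:
            raise FormatError(
                f"part_number must be positive on {self.object_id}"
            )
        if self.component_type == "W":
            if None in (self.component_id, self.component_beg, self.component_end):
                raise FormatError(
                    f"W record missing component fields on {self.object_id} "
                    f"part {self.part_number}"
                )
            if self.orientation not in ("+", "-"):
                raise FormatError(
                    f"W record orientation must be '+' or '-' on "
                    f"{self.object_id} part {self.part_number}"
                )
            if (self.object_end - self.object_beg) != (
                self.component_end - self.component_beg
            ):
                raise FormatError(
                    f"object span != component span on {self.object_id} "
                    f"part {self.part_number}"
                )
        else:
            if self.gap_length is None or self.gap_length < 1:
                raise FormatError(
                    f"U record needs positive gap_length on {self.object_id} "
                    f"part {self.part_number}"
                )
            if self.object_end - self.object_beg + 1 != self.gap_length:
                raise FormatError(
                    f"gap span != gap_length on {self.object_id} "
                    f"part {self.part_number}"
                )

    def to_line(self) -> str:
        if self.component_type == "W":
            tail = (
                f"{self.component_id}\t{self.component_beg}\t"
                f"{self.component_end}\t{self.orientation}"
            )
        else:
            tail = (
                f"{self.gap_length}\t{self.gap_type}\t{self.linkage}\t{self.evidence}"
            )
        return (
            f"{self.object_id}\t{self.object_beg}\t{self.object_end}\t"
            f"{self.part_number}\t{self.component_type}\t{tail}"
        )


@dataclass(frozen=True)
class FeatureInterval:
    """A classified interval on a contig or chromosome.

    ``start``/``end`` are 0-based half-open; ``start1``/``end1`` give the
    1-based inclusive view used by GFF3 and RepeatMasker on disk.
    """

    seq_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str  # '+', '-' or '.'
    kind: str  # 'gene' or 'repeat'
    subclass: str  # biotype (protein_coding|lncRNA|other) or repeat family

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError(
                f"empty or inverted interval on {self.seq_id}: "
                f"[{self.start}, {self.end})"
            )

    @property
    def start1(self) -> int:
        return self.start + 1

    @property
    def end1(self) -> int:
        return self.end

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ProteinMatch:
    """One BLAST tabular hit (query vs subject)."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise FormatError(
                f"pct_identity {self.pct_identity} outside [0, 100] "
                f"for {self.query_id} vs {self.subject_id}"
            )
        if self.evalue < 0:
            raise FormatError(f"negative e-value for {self.query_id}")


@dataclass(frozen=True)
class LocusHit:
    """A marker / DArT-seq / STC locus located on an assembly contig."""

    locus_id: str
    contig_id: str
    pct_identity: float
    contig_start: int  # 1-based inclusive, as printed by BLASTN
    contig_end: int
    evalue: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise FormatError(
                f"pct_identity {self.pct_identity} outside [0, 100] "
                f"for locus {self.locus_id}"
            )


# --------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Sequences are uppercased and concatenated across wrapped lines; record
    order is preserved.  Duplicate ids, empty sequences and non-FASTA
    leading bytes abort the parse.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
        if first != ">":
            raise FormatError(f"{path}: not a FASTA file (first byte {first!r})")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: empty sequence under header {rec.id!r}")
        records.append(SequenceRecord(rec.id, seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA (fixed line width, deterministic)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# --------------------------------------------------------------------------
# AGP


def _parse_int(token: str, path: Path, lineno: int, what: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: non-integer {what} {token!r}") from None


def read_agp(path: str | Path) -> list[AgpRecord]:
    """Read an AGP v2.x file, validating part numbering and tiling."""
    path = Path(path)
    records: list[AgpRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            obj, beg, end, part, ctype = cols[:5]
            beg_i = _parse_int(beg, path, lineno, "object_beg")
            end_i = _parse_int(end, path, lineno, "object_end")
            part_i = _parse_int(part, path, lineno, "part_number")
            if ctype == "W":
                rec = AgpRecord(
                    object_id=obj,
                    object_beg=beg_i,
                    object_end=end_i,
                    part_number=part_i,
                    component_type="W",
                    component_id=cols[5],
                    component_beg=_parse_int(cols[6], path, lineno, "component_beg"),
                    component_end=_parse_int(cols[7], path, lineno, "component_end"),
                    orientation=cols[8],
                )
            elif ctype in ("U", "N"):
                rec = AgpRecord(
                    object_id=obj,
                    object_beg=beg_i,
                    object_end=end_i,
                    part_number=part_i,
                    component_type="U",
                    gap_length=_parse_int(cols[5], path, lineno, "gap_length"),
                    gap_type=cols[6],
                    linkage=cols[7],
                    evidence=cols[8],
                )
            else:
                raise FormatError(
                    f"{path}:{lineno}: unknown component_type {ctype!r}"
                )
            try:
                rec.validate()
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            records.append(rec)
    _validate_agp_tiling(records, str(path))
    return records


def _validate_agp_tiling(records: Sequence[AgpRecord], origin: str = "<records>") -> None:
    """Check per-object part consecutiveness and gap-free tiling."""
    by_object: dict[str, list[AgpRecord]] = {}
    for rec in records:
        by_object.setdefault(rec.object_id, []).append(rec)
    for obj, parts in by_object.items():
        parts = sorted(parts, key=lambda r: r.part_number)
        expected_part = 1
        expected_beg = 1
        for rec in parts:
            if rec.part_number != expected_part:
                raise FormatError(
                    f"{origin}: object {obj}: non-consecutive part_number "
                    f"{rec.part_number} (expected {expected_part})"
                )
            if rec.object_beg != expected_beg:
                raise FormatError(
                    f"{origin}: object {obj} part {rec.part_number}: parts do "
                    f"not tile (object_beg {rec.object_beg}, expected {expected_beg})"
                )
            expected_part += 1
            expected_beg = rec.object_end + 1


def write_agp(records: Sequence[AgpRecord], path: str | Path) -> None:
    """Write AGP v2.1, ordered by (object_id, part_number).

    All invariants are validated before the first byte is written.
    """
    from ctga import __version__

    for rec in records:
        rec.validate()
    _validate_agp_tiling(records)
    ordered = sorted(records, key=lambda r: (r.object_id, r.part_number))
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        fh.write(f"# generated by ctga {__version__}\n")
        for rec in ordered:
            fh.write(rec.to_line() + "\n")


# --------------------------------------------------------------------------
# GFF3 genes

#: attribute keys probed, in order, for the gene biotype
DEFAULT_BIOTYPE_KEYS = ("biotype", "gene_biotype", "locus_type")

_KNOWN_BIOTYPES = {"protein_coding", "lncRNA"}


def read_gff_genes(
    path: str | Path,
    biotype_keys: Sequence[str] = DEFAULT_BIOTYPE_KEYS,
) -> list[FeatureInterval]:
    """Read gene-level features from a GFF3 file.

    Only features of type ``gene`` are returned.  The biotype is looked up
    under ``biotype_keys`` (first present key wins) and mapped onto
    {protein_coding, lncRNA, other}.
    """
    path = Path(path)
    genes: list[FeatureInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 GFF3 columns, got {len(cols)}"
                )
            if cols[2] != "gene":
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise FormatError(f"{path}:{lineno}: unparseable GFF3 line: {exc}") from None
            try:
                start1, end1 = int(cols[3]), int(cols[4])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: malformed coordinates {cols[3]!r}..{cols[4]!r}"
                ) from None
            if end1 < start1:
                raise FormatError(f"{path}:{lineno}: end < start")
            biotype = "other"
            for key in biotype_keys:
                if key in feat.attributes:
                    value = feat.attributes[key][0]
                    biotype = value if value in _KNOWN_BIOTYPES else "other"
                    break
            genes.append(
                FeatureInterval(
                    seq_id=feat.seqid,
                    start=start1 - 1,
                    end=end1,
                    strand=feat.strand if feat.strand in ("+", "-") else ".",
                    kind="gene",
                    subclass=biotype,
                )
            )
    return genes


# --------------------------------------------------------------------------
# RepeatMasker .out

# data rows: score div del ins query qbegin qend qleft strand repeat class ...
_RM_MIN_COLS = 11


def read_repeatmasker_out(
    path: str | Path,
    keep_overlapping: bool = True,
) -> list[FeatureInterval]:
    """Read a RepeatMasker ``.out`` annotation file.

    The standard layout is three header lines followed by whitespace-aligned
    columns.  Rows flagged ``*`` (lower-scoring overlap with a better hit)
    are kept unless ``keep_overlapping`` is false.  RepeatMasker marks
    minus-strand hits with ``C`` (complement); these become strand ``-``.
    """
    path = Path(path)
    repeats: list[FeatureInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            # header lines start with the column banners
            if line.startswith(("SW", "score", "bit")):
                continue
            cols = line.split()
            if len(cols) < _RM_MIN_COLS:
                raise FormatError(
                    f"{path}:{lineno}: expected at least {_RM_MIN_COLS} columns, "
                    f"got {len(cols)}"
                )
            starred = cols[-1] == "*"
            if starred and not keep_overlapping:
                continue
            query = cols[4]
            try:
                qbegin, qend = int(cols[5]), int(cols[6])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: malformed query coordinates "
                    f"{cols[5]!r}..{cols[6]!r}"
                ) from None
            if qend < qbegin:
                raise FormatError(f"{path}:{lineno}: qend < qbegin")
            strand = "-" if cols[8] == "C" else "+"
            repeats.append(
                FeatureInterval(
                    seq_id=query,
                    start=qbegin - 1,
                    end=qend,
                    strand=strand,
                    kind="repeat",
                    subclass=cols[10],
                )
            )
    return repeats


# --------------------------------------------------------------------------
# BLAST tabular (outfmt 6, 12 columns)


def _parse_blast_rows(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(cols)}"
                )
            yield lineno, cols


def read_blast_tab(path: str | Path) -> list[ProteinMatch]:
    """Read 12-column BLAST tabular output into :class:`ProteinMatch` rows.

    ``pident`` is parsed exactly as printed (no re-rounding), so an exact
    equality test against 100.00 is meaningful downstream.
    """
    matches: list[ProteinMatch] = []
    for lineno, cols in _parse_blast_rows(path):
        try:
            matches.append(
                ProteinMatch(
                    query_id=cols[0],
                    subject_id=cols[1],
                    pct_identity=float(cols[2]),
                    aln_length=int(cols[3]),
                    evalue=float(cols[10]),
                    bitscore=float(cols[11]),
                )
            )
        except ValueError:
            raise FormatError(
                f"{path}:{lineno}: non-numeric pident/length/evalue/bitscore"
            ) from None
    return matches


def read_locus_hits(path: str | Path) -> list[LocusHit]:
    """Read BLASTN hits of locus sequences against the assembly.

    Same 12-column tabular layout as :func:`read_blast_tab`; the subject is
    the assembly contig and subject coordinates locate the locus on it.
    """
    hits: list[LocusHit] = []
    for lineno, cols in _parse_blast_rows(path):
        try:
            hits.append(
                LocusHit(
                    locus_id=cols[0],
                    contig_id=cols[1],
                    pct_identity=float(cols[2]),
                    contig_start=int(cols[8]),
                    contig_end=int(cols[9]),
                    evalue=float(cols[10]),
                )
            )
        except ValueError:
            raise FormatError(
                f"{path}:{lineno}: non-numeric pident/coordinates/evalue"
            ) from None
    return hits
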