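"""Anchor indexing, contig placement, AGP export and evidence extraction."""

import random

import pytest

from ctga.evidence_consensus import EvidenceRecord
from ctga.homology_placement import (
    agp_to_evidence,
    build_anchor_index,
    canonical,
    order_and_export,
    place_contig,
    revcomp,
    Placement,
)
from ctga.io_formats import SequenceRecord


def random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def unique_kmers_bruteforce(seqs, k):
    """Oracle: canonical k-mer counting with a plain dictionary."""
    counts = {}
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            canon, _ = canonical(kmer)
            counts[canon] = counts.get(canon, 0) + 1
    return {k_ for k_, c in counts.items() if c == 1}


class TestAnchorIndex:
    def test_small_enumeration(self):
        # "ACGTACGT": 3-mers ACG,CGT,GTA,TAC,ACG,CGT -> canonical forms of
        # ACG and CGT repeat; only GTA/TAC's canonical form is ambiguous by
        # hand, so compare against the brute-force oracle directly
        ref = [SequenceRecord("chr1", "ACGTACGT")]
        index = build_anchor_index(ref, k=3)
        assert set(index.anchors) == unique_kmers_bruteforce(["ACGTACGT"], 3)

    def test_two_identical_chromosomes_share_nothing_unique(self):
        seq = random_seq(random.Random(0), 500)
        ref = [SequenceRecord("chr1", seq), SequenceRecord("chr2", seq)]
        assert len(build_anchor_index(ref, k=21)) == 0

    def test_matches_bruteforce_on_multichromosome_reference(self):
        rng = random.Random(1)
        ref = [SequenceRecord(f"chr{i}", random_seq(rng, 800)) for i in range(7)]
        index = build_anchor_index(ref, k=21)
        assert set(index.anchors) == unique_kmers_bruteforce(
            [c.seq for c in ref], 21
        )

    def test_k_larger_than_reference_rejected(self):
        with pytest.raises(ValueError):
            build_anchor_index([SequenceRecord("chr1", "ACGT")], k=21)

    def test_even_k_rejected(self):
        with pytest.raises(ValueError):
            build_anchor_index([SequenceRecord("chr1", "ACGTACGT")], k=4)


@pytest.fixture(scope="module")
def reference():
    rng = random.Random(7)
    return [SequenceRecord(f"chr{i + 1}", random_seq(rng, 4000)) for i in range(3)]


@pytest.fixture(scope="module")
def index(reference):
    return build_anchor_index(reference, k=21)


class TestPlaceContig:
    def test_exact_slice_places_with_full_confidence(self, reference, index):
        contig = SequenceRecord("ctg", reference[2].seq[1000:2000])
        p = place_contig(contig, index)
        assert p.status == "placed"
        assert p.chromosome_id == "chr3"
        assert p.orientation == "+"
        assert p.confidence == 1.0
        assert 1000 <= p.position <= 2000

    def test_reverse_complement_flips_orientation_only(self, reference, index):
        fwd = SequenceRecord("f", reference[1].seq[500:1500])
        rev = SequenceRecord("r", revcomp(fwd.seq))
        pf, pr = place_contig(fwd, index), place_contig(rev, index)
        assert pr.chromosome_id == pf.chromosome_id == "chr2"
        assert (pf.orientation, pr.orientation) == ("+", "-")
        # vote tallies are strand-invariant
        assert dict(pr.anchor_votes) == dict(pf.anchor_votes)

    def test_foreign_sequence_stays_unplaced(self, index):
        contig = SequenceRecord("x", random_seq(random.Random(99), 1000))
        p = place_contig(contig, index)
        assert p.status == "unplaced"
        assert p.total_votes <= 2  # chance collisions only

    def test_balanced_chimera_is_ambiguous(self, reference, index):
        half = 800
        contig = SequenceRecord(
            "chimera", reference[0].seq[:half] + reference[1].seq[:half]
        )
        p = place_contig(contig, index)
        assert p.status == "ambiguous"

    def test_deterministic(self, reference, index):
        contig = SequenceRecord("ctg", reference[0].seq[100:1100])
        assert place_contig(contig, index) == place_contig(contig, index)


class TestOrderAndExport:
    def make_placement(self, cid, chrom, pos):
        return Placement(
            contig_id=cid, status="placed", chromosome_id=chrom,
            anchor_votes={chrom: 50}, position=pos, orientation="+",
            confidence=1.0,
        )

    def test_position_order_preserved_with_gaps(self):
        placements = [
            self.make_placement("b", "Chr1", 500),
            self.make_placement("a", "Chr1", 10),
            self.make_placement("c", "Chr1", 900),
        ]
        agp = order_and_export(placements, {"a": 100, "b": 200, "c": 50}, "refX")
        w = [r for r in agp if r.component_type == "W"]
        gaps = [r for r in agp if r.component_type == "U"]
        assert [r.component_id for r in w] == ["a", "b", "c"]
        assert len(gaps) == 2  # 2n-1 parts for n contigs
        assert all(r.object_id == "Chr1_refX" for r in agp)

    def test_unplaced_become_singletons(self):
        placements = [Placement("lone", "unplaced")]
        (rec,) = order_and_export(placements, {"lone": 70}, "refX")
        assert rec.object_id == rec.component_id == "lone"
        assert (rec.object_beg, rec.object_end) == (1, 70)

    def test_duplicate_contig_rejected(self):
        p = self.make_placement("a", "Chr1", 10)
        with pytest.raises(ValueError, match="duplicate"):
            order_and_export([p, p], {"a": 100}, "refX")


class TestAgpToEvidence:
    def test_chromosome_w_lines_become_claims(self):
        placements = [
            Placement("ctg105", "placed", "Chr2", {"Chr2": 9}, 10.0, "+", 1.0),
            Placement("ctg9", "unplaced"),
        ]
        agp = order_and_export(placements, {"ctg105": 100, "ctg9": 50}, "9930")
        evidence = agp_to_evidence(agp, "9930")
        assert evidence == [
            EvidenceRecord(
                contig_id="ctg105", chromosome="Chr2", source="scaffold:9930"
            )
        ]

    def test_record_count_equals_chromosome_w_lines(self, default_study, pipeline_result):
        agp = pipeline_result.agp
        n_chrom_w = sum(
            1
            for r in agp
            if r.component_type == "W" and r.object_id != r.component_id
        )
        evidence = agp_to_evidence(agp, "ref")
        assert len(evidence) == n_chrom_w


class TestSyntheticRecovery:
    def test_true_chromosome_recovered_for_long_unique_contigs(
        self, default_study, pipeline_result
    ):
        truth = default_study.truth
        eligible = [
            p
            for p in pipeline_result.placements
            if not truth.contig_is_repeat[p.contig_id]
            and len(default_study.contigs[int(p.contig_id[3:]) - 1]) >= 5000
        ]
        correct = [
            p
            for p in eligible
            if p.status == "placed"
            and p.chromosome_id == truth.contig_chrom[p.contig_id]
        ]
        assert len(correct) / len(eligible) >= 0.95

    def test_repeat_array_contigs_all_unplaced(self, default_study, pipeline_result):
        truth = default_study.truth
        repeat_statuses = {
            p.status
            for p in pipeline_result.placements
            if truth.contig_is_repeat[p.contig_id]
        }
        assert repeat_statuses == {"unplaced"}

    def test_orientation_recovered(self, default_study, pipeline_result):
        truth = default_study.truth
        placed = [p for p in pipeline_result.placements if p.status == "placed"]
        agree = sum(
            1
            for p in placed
            if p.orientation == truth.contig_orientation[p.contig_id]
        )
        assert agree / len(placed) >= 0.95

    def test_agp_order_matches_true_order(self, default_study, pipeline_result):
        truth = default_study.truth
        by_object = {}
        for rec in pipeline_result.agp:
            if rec.component_type == "W" and rec.object_id != rec.component_id:
                by_object.setdefault(rec.object_id, []).append(rec.component_id)
        for contig_ids in by_object.values():
            orders = [truth.contig_order[cid] for cid in contig_ids]
            assert orders == sorted(orders)
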