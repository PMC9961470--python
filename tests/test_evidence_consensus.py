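"""Majority-vote consensus: voting, conflicts, aggregation, integration."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from ctga.evidence_consensus import (
    BACFISH_SOURCE,
    EvidenceRecord,
    build_integrated_table,
    consensus_assign,
    loci_to_evidence,
    normalize_chromosome,
)
from ctga.io_formats import LocusHit


def rec(contig, chrom, source, locus=None, weight=1.0):
    return EvidenceRecord(contig, chrom, source, locus_id=locus, weight=weight)


class TestNormalization:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("Chr2_9930", "Chr2"),
            ("Chr2_Gy14", "Chr2"),
            ("Chr7", "Chr7"),
            ("chr3_ref", "Chr3"),
        ],
    )
    def test_suffix_stripping(self, raw, expected):
        assert normalize_chromosome(raw) == expected

    def test_unrecognized_label_rejected(self):
        with pytest.raises(ValueError):
            normalize_chromosome("scaffold_17")


class TestConsensusAssign:
    def test_single_source(self):
        c = consensus_assign("ctg", [rec("ctg", "Chr5", "markers")])
        assert (c.consensus, c.support, c.conflicts) == ("Chr5", 1.0, ())

    def test_dissenter_flagged_with_fractional_support(self):
        records = [
            rec("ctg", "Chr3", s)
            for s in ("markers", "scaffold:9930", "scaffold:Gy14",
                      "blastp:9930", "blastp:gy14", "dart")
        ] + [rec("ctg", "Chr1", BACFISH_SOURCE)]
        c = consensus_assign("ctg", records)
        assert c.consensus == "Chr3"
        assert c.support == pytest.approx(6 / 7)
        assert c.conflicts == ((BACFISH_SOURCE, "Chr1"),)

    def test_tie_is_ambiguous(self):
        records = [
            rec("ctg", "Chr1", "markers"),
            rec("ctg", "Chr1", "dart"),
            rec("ctg", "Chr2", "scaffold:a"),
            rec("ctg", "Chr2", "scaffold:b"),
        ]
        c = consensus_assign("ctg", records)
        assert c.status == "ambiguous"
        assert c.consensus is None

    def test_empty_evidence(self):
        c = consensus_assign("ctg", [])
        assert c.status == "no_evidence"

    def test_order_invariance_and_dedup(self):
        records = [
            rec("ctg", "Chr1", "markers", locus="m1"),
            rec("ctg", "Chr2", "dart", locus="d1"),
            rec("ctg", "Chr2", "dart", locus="d2"),
        ]
        base = consensus_assign("ctg", records)
        shuffled = consensus_assign("ctg", list(reversed(records)))
        duplicated = consensus_assign("ctg", records + records)
        assert base == shuffled == duplicated

    def test_source_internal_majority_then_abstention(self):
        # dart claims Chr2 twice and Chr3 once -> dart votes Chr2
        records = [
            rec("ctg", "Chr2", "dart", locus="d1"),
            rec("ctg", "Chr2", "dart", locus="d2"),
            rec("ctg", "Chr3", "dart", locus="d3"),
            rec("ctg", "Chr3", "markers", locus="m1"),
        ]
        c = consensus_assign("ctg", records)
        assert c.status == "ambiguous"  # dart:Chr2 vs markers:Chr3
        # internal tie -> dart abstains entirely
        records = records[:2] + [
            rec("ctg", "Chr3", "dart", locus="d3"),
            rec("ctg", "Chr3", "dart", locus="d4"),
            rec("ctg", "Chr3", "markers", locus="m1"),
        ]
        c = consensus_assign("ctg", records)
        assert c.consensus == "Chr3"
        assert c.votes == {"Chr3": 1.0}

    def test_all_agree_full_support(self):
        records = [rec("ctg", "Chr2", s) for s in ("a", "b", "c", "d")]
        c = consensus_assign("ctg", records)
        assert c.support == 1.0
        assert c.conflicts == ()

    @given(
        n_sources=st.integers(2, 6),
        winner=st.integers(1, 7),
        data=st.data(),
    )
    @settings(max_examples=60, deadline=None)
    def test_weight_dominance(self, n_sources, winner, data):
        """A source outweighing the sum of all others dictates the consensus."""
        sources = [f"s{i}" for i in range(n_sources)]
        chroms = [
            data.draw(st.integers(1, 7).filter(lambda c: c != winner))
            for _ in sources[1:]
        ]
        records = [rec("ctg", f"Chr{winner}", sources[0], weight=float(n_sources))]
        records += [
            rec("ctg", f"Chr{c}", s, weight=1.0)
            for s, c in zip(sources[1:], chroms)
        ]
        c = consensus_assign("ctg", records)
        assert c.consensus == f"Chr{winner}"


class TestLociToEvidence:
    def hit(self, locus, contig, pident, evalue=1e-30):
        return LocusHit(locus, contig, pident, 1, 60, evalue)

    def test_best_hit_rule(self):
        hits = [self.hit("L1", "ctgA", 95.0, 1e-40), self.hit("L1", "ctgB", 91.0, 1e-20)]
        (record,) = loci_to_evidence(hits, {"L1": "Chr2"}, "dart")
        assert (record.contig_id, record.chromosome, record.source) == (
            "ctgA", "Chr2", "dart",
        )

    def test_identity_threshold_boundary(self):
        assert loci_to_evidence(
            [self.hit("L1", "ctgA", 89.9)], {"L1": "Chr2"}, "dart", min_identity=90
        ) == []
        assert len(
            loci_to_evidence(
                [self.hit("L1", "ctgA", 90.0)], {"L1": "Chr2"}, "dart", min_identity=90
            )
        ) == 1

    def test_unmapped_locus_dropped(self):
        assert loci_to_evidence([self.hit("L9", "ctgA", 99.0)], {}, "dart") == []


class TestIntegratedTable:
    def test_blank_cells_and_consensus_columns(self):
        records = [
            rec("c1", "Chr1", "markers"),
            rec("c1", "Chr1", "dart"),
            rec("c2", "Chr2", "markers"),
        ]
        table = build_integrated_table(
            ["c1", "c2", "c3"], records, source_order=("markers", "dart")
        )
        assert list(table["contig"]) == ["c1", "c2", "c3"]
        assert table.loc[1, "dart"] == ""  # c2 has no dart claim
        assert table.loc[0, "consensus_all"] == "Chr1"
        assert table.loc[2, "consensus_all"] == "no_evidence"

    def test_stray_contig_warns_but_row_emitted(self):
        records = [rec("ghost", "Chr1", "markers")]
        with pytest.warns(UserWarning, match="ghost"):
            table = build_integrated_table(["c1"], records, source_order=("markers",))
        assert set(table["contig"]) == {"c1", "ghost"}

    def test_injected_errors_surface_as_conflicts(
        self, default_study, pipeline_result
    ):
        """Every corrupted claim, and nothing else, shows up as a conflict."""
        detected = {
            (cid, source)
            for cid, c in pipeline_result.consensus_all.items()
            for source, _ in c.conflicts
        }
        injected = {
            (c["contig_id"], c["source"]) for c in default_study.truth.corruptions
        }
        assert detected == injected
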