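"""Interval merging and placed/unplaced partition accounting."""

import pytest
from hypothesis import given, settings, strategies as st

from ctga.composition import (
    compute_composition,
    merge_intervals,
    merged_coverage,
    protein_coding_placement_rate,
    PartitionComposition,
)
from ctga.homology_placement import Placement
from ctga.io_formats import FeatureInterval, SequenceRecord


def iv(seq_id, start1, end1):
    return FeatureInterval(seq_id, start1 - 1, end1, "+", "repeat", "x")


def coverage_bitmap(intervals, length=10_000):
    """Oracle: per-base bitmap union."""
    mask = [False] * length
    for interval in intervals:
        for pos in range(interval.start, interval.end):
            mask[pos] = True
    return sum(mask)


class TestMergeIntervals:
    def test_overlap_union(self):
        merged = merge_intervals([iv("c", 1, 50), iv("c", 41, 60)])
        assert merged == {"c": [(0, 60)]}
        assert merged_coverage([iv("c", 1, 50), iv("c", 41, 60)]) == 60

    def test_disjoint_preserved(self):
        assert merged_coverage([iv("c", 1, 10), iv("c", 20, 30)]) == 21

    def test_empty(self):
        assert merged_coverage([]) == 0

    def test_beyond_contig_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            merged_coverage([iv("c", 1, 100)], {"c": 50})

    @given(
        st.lists(
            st.tuples(st.integers(0, 9_000), st.integers(1, 1_000)),
            min_size=0,
            max_size=30,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_bitmap_oracle_and_is_idempotent(self, spans):
        intervals = [
            FeatureInterval("c", s, s + l, "+", "repeat", "x") for s, l in spans
        ]
        assert merged_coverage(intervals) == coverage_bitmap(intervals)
        # permutation invariance + idempotence
        merged_once = merge_intervals(intervals)
        reversed_merge = merge_intervals(list(reversed(intervals)))
        assert merged_once == reversed_merge
        remerged = merge_intervals(
            [
                FeatureInterval("c", s, e, "+", "repeat", "x")
                for s, e in merged_once.get("c", [])
            ]
        )
        assert remerged == merged_once


def make_world():
    contigs = [
        SequenceRecord("p1", "A" * 1000),
        SequenceRecord("p2", "A" * 500),
        SequenceRecord("u1", "A" * 300),
    ]
    placements = [
        Placement("p1", "placed", "Chr1", {"Chr1": 9}, 1.0, "+", 1.0),
        Placement("p2", "placed", "Chr2", {"Chr2": 9}, 1.0, "+", 1.0),
        Placement("u1", "ambiguous"),
    ]
    repeats = [iv("p1", 1, 100), iv("p1", 51, 150), iv("u1", 1, 300)]
    genes = [
        FeatureInterval("p1", 0, 90, "+", "gene", "protein_coding"),
        FeatureInterval("p2", 0, 90, "+", "gene", "protein_coding"),
        FeatureInterval("u1", 0, 90, "+", "gene", "lncRNA"),
    ]
    return contigs, placements, repeats, genes


class TestComposition:
    def test_partition_accounting(self):
        contigs, placements, repeats, genes = make_world()
        placed, unplaced = compute_composition(placements, contigs, repeats, genes)
        assert placed.total_bp == 1500
        assert placed.repeat_bp == 150  # merged, not 200
        assert unplaced.total_bp == 300  # ambiguous counts as unplaced
        assert unplaced.repeat_fraction == 1.0
        assert (placed.n_genes, placed.n_protein_coding) == (2, 2)
        assert (unplaced.n_genes, unplaced.n_lncRNA) == (1, 1)

    def test_total_bp_conservation(self):
        contigs, placements, repeats, genes = make_world()
        placed, unplaced = compute_composition(placements, contigs, repeats, genes)
        assert placed.total_bp + unplaced.total_bp == sum(len(c) for c in contigs)

    def test_moving_a_contig_moves_exactly_its_mass(self):
        contigs, placements, repeats, genes = make_world()
        before = compute_composition(placements, contigs, repeats, genes)
        # flip p2 to unplaced
        flipped = [
            p if p.contig_id != "p2" else Placement("p2", "unplaced")
            for p in placements
        ]
        after = compute_composition(flipped, contigs, repeats, genes)
        assert before[0].total_bp - after[0].total_bp == 500
        assert after[1].total_bp - before[1].total_bp == 500
        assert before[0].n_genes - after[0].n_genes == 1
        assert before[0].repeat_bp == after[0].repeat_bp  # p2 had no repeats

    def test_unknown_contig_rejected(self):
        contigs, placements, repeats, genes = make_world()
        with pytest.raises(ValueError, match="unknown contig"):
            compute_composition(
                placements, contigs, repeats + [iv("ghost", 1, 10)], genes
            )

    def test_synthetic_truth_bookkeeping_recovered(
        self, default_study, pipeline_result
    ):
        """Merged repeat coverage equals the generator's planted totals."""
        truth = default_study.truth
        placed_ids = {
            p.contig_id for p in pipeline_result.placements if p.status == "placed"
        }
        want_placed = sum(
            bp for cid, bp in truth.repeat_bp.items() if cid in placed_ids
        )
        want_unplaced = sum(
            bp for cid, bp in truth.repeat_bp.items() if cid not in placed_ids
        )
        assert pipeline_result.composition_placed.repeat_bp == want_placed
        assert pipeline_result.composition_unplaced.repeat_bp == want_unplaced
        n_genes = (
            pipeline_result.composition_placed.n_genes
            + pipeline_result.composition_unplaced.n_genes
        )
        assert n_genes == len(truth.gene_contig)


class TestPlacementRate:
    def test_simple_fraction(self):
        placed = PartitionComposition("placed", 100, 0, 98, 98, 0)
        unplaced = PartitionComposition("unplaced", 100, 0, 2, 2, 0)
        assert protein_coding_placement_rate(placed, unplaced) == pytest.approx(0.98)

    def test_published_style_complement(self):
        # 317 of 16,099 protein-coding genes off-chromosome is a 1.97% miss
        placed = PartitionComposition("placed", 1, 0, 15782, 15782, 0)
        unplaced = PartitionComposition("unplaced", 1, 0, 317, 317, 0)
        rate = protein_coding_placement_rate(placed, unplaced)
        assert 1 - rate == pytest.approx(0.0197, abs=5e-4)
        assert rate > 0.98

    def test_zero_protein_coding_rejected(self):
        empty = PartitionComposition("placed", 1, 0, 0, 0, 0)
        with pytest.raises(ValueError):
            protein_coding_placement_rate(empty, empty)
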