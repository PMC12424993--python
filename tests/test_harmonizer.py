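"""Placement engine: support thresholds, regenotyping, CNA phases."""

import numpy as np
import pytest

import treeharmonize as th
from treeharmonize.harmonizer import (
    Clonality,
    PlacementParams,
    _LossIndex,
    min_support,
    regenotype,
)
from treeharmonize.variants import (
    GenomicInterval,
    LossRegion,
    LossSource,
    SnvCall,
    VariantStatus,
)
from conftest import random_tree
from intervaltree import IntervalTree


def brute_force_min_support(clade_size: int, fn_rate: float) -> int:
    if clade_size <= 2:
        return clade_size
    ok = [s for s in range(1, clade_size + 1)
          if (clade_size - s) / clade_size >= fn_rate]
    return max(ok) if ok else 1


class TestMinSupport:
    def test_small_clades_require_full_support(self):
        assert min_support(1, 0.15) == 1
        assert min_support(2, 0.15) == 2

    def test_clade_three_tolerates_one_miss(self):
        assert min_support(3, 0.15) == 2
        assert th.effective_fn_rate(3, 0.15) == pytest.approx(1 / 3)

    def test_matches_inequality_scan_for_all_clade_sizes(self):
        for c in range(1, 24):
            for fn in (0.0, 0.05, 0.15, 0.2, 0.5):
                assert min_support(c, fn) == brute_force_min_support(c, fn), (c, fn)

    def test_scan_example_clade_ten(self):
        assert min_support(10, 0.15) == 8


class TestPlaceVariant:
    def test_single_subline_private(self, balanced4):
        p = th.place_variant("v", {"A"}, balanced4)
        assert p.assigned_node == "A" and p.clonality is Clonality.PRIVATE
        assert (p.support, p.clade_size) == (1, 1)

    def test_full_clade_subclonal(self):
        tree = th.Phylogeny.from_newick("(((A,B),(C,D)),(E,F));")
        node = tree.mrca({"A", "B", "C", "D"})
        p = th.place_variant("v", {"A", "B", "C", "D"}, tree)
        assert p.assigned_node == node and p.clonality is Clonality.SUBCLONAL

    def test_insufficient_support_unplaced(self, balanced4):
        # 2 carriers spanning a size-4 clade: threshold min_support(4,.15)=3
        p = th.place_variant("v", {"A", "C"}, balanced4)
        assert not p.placed and p.clonality is Clonality.UNPLACED

    def test_all_leaves_clonal(self, balanced4):
        p = th.place_variant("v", set("ABCD"), balanced4)
        assert p.assigned_node == balanced4.root
        assert p.clonality is Clonality.CLONAL

    def test_zero_carriers_rejected(self, balanced4):
        with pytest.raises(ValueError):
            th.place_variant("v", set(), balanced4)

    def test_oracle_deepest_satisfying_node(self):
        # brute force over all nodes: deepest node containing the carriers
        # whose clade meets the threshold
        rng = np.random.default_rng(42)
        params = PlacementParams()
        for _ in range(200):
            tree = random_tree(rng, int(rng.integers(3, 9)))
            leaves = tree.leaf_labels
            k = int(rng.integers(1, len(leaves) + 1))
            present = set(rng.choice(leaves, size=k, replace=False))
            p = th.place_variant("v", present, tree, params)
            best, best_depth = None, -1
            for node in tree.nodes():
                clade = tree.leaves_below(node)
                if present <= clade and len(present) >= min_support(
                    len(clade), params.fn_rate
                ):
                    d = tree.depth(node)
                    if d > best_depth:
                        best, best_depth = node, d
            assert p.assigned_node == (best if best is not None else th.UNPLACED)


def _loss(subline, chrom="chr1", start=50, end=150):
    return LossRegion(GenomicInterval(chrom, start, end), subline,
                      LossSource.SV_DELETION)


def _snv_tree(subline_positions):
    trees = {}
    for s, positions in subline_positions.items():
        t = IntervalTree()
        for p in positions:
            t.addi(p - 1, p, p - 1)
        trees[s] = t
    return trees


class TestRegenotype:
    def test_loss_rescue_places_at_clade(self, balanced4):
        # called in {A,B}, C has an overlapping deletion: candidate 3 of
        # clade 4 meets threshold 3; C becomes "lost"
        idx = _LossIndex([_loss("C")])
        p = regenotype("v", "chr1", 100, {"A", "B"}, idx, balanced4,
                       PlacementParams(), _snv_tree({}))
        assert p.assigned_node == balanced4.root
        assert p.regenotyped_sublines == frozenset({"C"})
        assert (p.support, p.clade_size) == (3, 4)

    def test_parsimony_guard_reverts(self, balanced4):
        # C carries another SNV inside the loss span: loss was on the other
        # haplotype, so the rescue is rejected and {A,B} placement stands
        idx = _LossIndex([_loss("C")])
        p = regenotype("v", "chr1", 100, {"A", "B"}, idx, balanced4,
                       PlacementParams(), _snv_tree({"C": [120]}))
        assert p.assigned_node == balanced4.mrca({"A", "B"})
        assert not p.regenotyped_sublines

    def test_reinclusion_cap_reverts(self, balanced4):
        # adding 2 sublines to a called set of 2 is a 100% reinclusion rate
        idx = _LossIndex([_loss("C"), _loss("D")])
        p = regenotype("v", "chr1", 100, {"A", "B"}, idx, balanced4,
                       PlacementParams(), _snv_tree({}))
        assert p.assigned_node == balanced4.mrca({"A", "B"})
        assert not p.regenotyped_sublines

    def test_no_overlapping_loss_is_identity(self, balanced4):
        idx = _LossIndex([_loss("C", start=500, end=600)])
        p = regenotype("v", "chr1", 100, {"A", "B"}, idx, balanced4,
                       PlacementParams(), _snv_tree({}))
        assert p.assigned_node == balanced4.mrca({"A", "B"})


class TestPlaceAll:
    def test_noise_free_bundle_fully_recovered(self):
        b = th.simulate(th.SimConfig(seed=21, n_snvs=400, n_svs=30,
                                     fn_rate=0.0, fp_rate=0.0))
        placements, summary = th.place_all_snvs(
            b.snv_calls, b.loss_regions, b.tree, PlacementParams()
        )
        assert summary.unplaced == 0
        by_id = {p.variant_id: p for p in placements}
        for vt in b.truth.variants.values():
            assert by_id[vt.variant_id].assigned_node == vt.branch

    def test_deletion_masked_variants_recovered(self, bundle):
        placements, summary = th.place_all_snvs(
            bundle.snv_calls, bundle.loss_regions, bundle.tree, PlacementParams()
        )
        by_id = {p.variant_id: p for p in placements}
        masked_only = [
            v for v in bundle.truth.variants.values()
            if v.observed and v.deletion_fn and not v.plain_fn
        ]
        assert masked_only, "bundle should plant deletion-masked variants"
        for vt in masked_only:
            p = by_id[vt.variant_id]
            assert p.assigned_node == vt.branch
            assert vt.deletion_fn <= p.regenotyped_sublines

    def test_fp_private_call_placed_private(self, balanced4):
        calls = [SnvCall("chr1", 100, "A", "T", "A", VariantStatus.PRESENT, 30, 10)]
        placements, summary = th.place_all_snvs(calls, [], balanced4)
        assert placements[0].clonality is Clonality.PRIVATE

    def test_placement_order_independent(self, bundle):
        calls = list(bundle.snv_calls)
        p1, _ = th.place_all_snvs(calls, bundle.loss_regions, bundle.tree)
        p2, _ = th.place_all_snvs(calls[::-1], bundle.loss_regions, bundle.tree)
        assert [(p.variant_id, p.assigned_node) for p in p1] == [
            (p.variant_id, p.assigned_node) for p in p2
        ]

    def test_support_invariant(self, bundle):
        placements, _ = th.place_all_snvs(
            bundle.snv_calls, bundle.loss_regions, bundle.tree
        )
        for p in placements:
            if p.placed:
                assert p.support >= min_support(p.clade_size, 0.15)
                assert p.regenotyped_sublines <= bundle.tree.leaves_below(
                    p.assigned_node
                )


class TestPlaceSvs:
    def test_clonal_and_subclonal(self):
        tree = th.Phylogeny.from_newick("(((A,B),C),(D,E));")
        svs = [
            th.SvCall("sv_all", th.SvType.INS, ("chr1", 100), None, 50,
                      set("ABCDE")),
            th.SvCall("sv_clade", th.SvType.INS, ("chr1", 200), None, 50,
                      {"A", "B", "C"}),
        ]
        placements, _ = th.place_all_svs(svs, tree)
        by_id = {p.variant_id: p for p in placements}
        assert by_id["sv_all"].clonality is Clonality.CLONAL
        assert by_id["sv_clade"].assigned_node == tree.mrca({"A", "B", "C"})

    def test_cross_clade_pair_unplaced(self):
        # 2 carriers under an 8-leaf MRCA: threshold min_support(8,.15)=6
        tree = th.Phylogeny.from_newick(
            "(((A,B),(C,D)),((E,F),(G,H)));"
        )
        svs = [th.SvCall("sv", th.SvType.INS, ("chr1", 100), None, 50,
                         {"A", "H"})]
        placements, _ = th.place_all_svs(svs, tree)
        assert not placements[0].placed


class TestCnaRanges:
    def test_extract_directions(self):
        segs = [
            th.CnaSegment(GenomicInterval("chr1", 0, 100), 3, "A"),
            th.CnaSegment(GenomicInterval("chr1", 200, 300), 2, "A"),
            th.CnaSegment(GenomicInterval("chr1", 400, 500), 1, "A"),
        ]
        gains, losses = th.extract_cn_ranges(segs)
        assert gains["A"] == [GenomicInterval("chr1", 0, 100)]
        assert losses["A"] == [GenomicInterval("chr1", 400, 500)]

    def test_adjacent_same_direction_merged(self):
        segs = [
            th.CnaSegment(GenomicInterval("chr1", 0, 100), 3, "A"),
            th.CnaSegment(GenomicInterval("chr1", 100, 200), 4, "A"),
        ]
        gains, _ = th.extract_cn_ranges(segs)
        assert gains["A"] == [GenomicInterval("chr1", 0, 200)]


class TestPlaceCnas:
    def test_identical_pair_assigned_to_cherry(self, balanced4):
        iv = GenomicInterval("chr1", 0, 100)
        ranges = {"A": [iv], "B": [iv]}
        out = th.place_cnas(ranges, balanced4)
        cherry = balanced4.mrca({"A", "B"})
        assert [(o.branch, o.interval) for o in out] == [(cherry, iv)]

    def test_partial_overlap_split_to_private_remainder(self, balanced4):
        ranges = {
            "A": [GenomicInterval("chr1", 0, 150)],
            "B": [GenomicInterval("chr1", 0, 100)],
        }
        out = th.place_cnas(ranges, balanced4)
        got = {(o.branch, o.interval.start, o.interval.end) for o in out}
        cherry = balanced4.mrca({"A", "B"})
        assert (cherry, 0, 100) in got
        assert ("A", 100, 150) in got
        assert len(got) == 2

    def test_parallel_events_stay_on_distinct_branches(self):
        # same region altered in two clades of a 12-leaf tree with distinct
        # breakpoints: the union does not meet the root threshold, so two
        # separate ranges are reported, never merged across branches
        tree = th.Phylogeny.from_newick(
            "(((A,B),(C,D)),((E,F),((G,H),(I,(J,(K,L))))));"
        )
        clade1 = tree.mrca({"A", "B", "C", "D"})
        clade2 = tree.mrca({"E", "F"})
        ranges = {}
        for l in "ABCD":
            ranges[l] = [GenomicInterval("chr1", 1000, 5000)]
        for l in "EF":
            ranges[l] = [GenomicInterval("chr1", 500, 4500)]
        out = th.place_cnas(ranges, tree)
        branches = {o.branch for o in out}
        assert branches == {clade1, clade2}

    def test_root_to_leaf_spans_disjoint(self, bundle):
        gains, _ = th.extract_cn_ranges(bundle.cna_segments)
        out = th.place_cnas(gains, bundle.tree)
        for leaf in bundle.tree.leaf_labels:
            path = set(bundle.tree.path_from_root(leaf))
            on_path = [o for o in out if o.branch in path]
            for i in range(len(on_path)):
                for j in range(i + 1, len(on_path)):
                    assert not on_path[i].interval.overlaps(on_path[j].interval)

    def test_bundle_parallel_pair_recovered(self, bundle):
        gains, _ = th.extract_cn_ranges(bundle.cna_segments)
        out = th.place_cnas(gains, bundle.tree)
        truth_parallel = [
            e for e in bundle.truth.cna_events if e.parallel_group == 0
        ]
        assert len(truth_parallel) == 2
        for event in truth_parallel:
            hits = [
                o for o in out
                if o.branch == event.branch and o.interval.overlaps(event.interval)
            ]
            assert hits, f"parallel event on {event.branch} not recovered"
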