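"""Phylogeny-constrained placement of SNVs, SVs and CNAs.

A variant called in a set of sublines is placed at the most recent common
ancestor (MRCA) of its carriers, provided enough of the MRCA clade carries
it. "Enough" is a clade-size-dependent support threshold derived from an
assumed false-negative call rate: for a clade of size c and FN rate f, the
minimal support is the largest integer s with (c - s)/c >= f, i.e. the
placement tolerates up to the expected number of missed calls but no more.
Clades of size 1 or 2 always require full support.

SNVs additionally get loss-aware *regenotyping*: a subline whose genome lost
the locus (SV deletion or copy-number <= 1) cannot show the variant, so it
may be re-included as a "lost" carrier, subject to a haplotype-parsimony
guard and a cap on how far the placement may jump.

CNAs are placed by a three-phase interval procedure over the tree: overlap
ranges are built bottom-up from pairwise intersections, thresholded and
merged per branch, then finalized top-down so that no genomic span is
attributed to both an ancestor and a descendant on the same path.
"""

from __future__ import annotations

import enum
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from intervaltree import IntervalTree

from .tree import BranchClass, Phylogeny
from .variants import (
    CnaSegment,
    GenomicInterval,
    LossRegion,
    SnvCall,
    SvCall,
    VariantStatus,
)

logger = logging.getLogger(__name__)

UNPLACED = "UNPLACED"


@dataclass
class PlacementParams:
    """Placement thresholds.

    fn_rate: assumed per-subline false-negative call rate (0.15)
    fp_rate: assumed false-positive rate; at the default the called carrier
        set is trusted outright and no leave-one-out search is attempted
    reinclusion_cap: regenotyping is rejected when
        |added sublines| / |originally called sublines| >= cap (1.0)
    parsimony_guard: reject regenotyping when another SNV of the same
        subline is called inside the loss span (the loss was likely on the
        other haplotype)
    """

    fn_rate: float = 0.15
    fp_rate: float = 1e-5
    reinclusion_cap: float = 1.0
    parsimony_guard: bool = True
    fp_leaveout: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.fn_rate < 1:
            raise ValueError("fn_rate must be in [0,1)")
        if self.reinclusion_cap <= 0:
            raise ValueError("reinclusion_cap must be positive")


class Clonality(str, enum.Enum):
    CLONAL = "clonal"
    SUBCLONAL = "subclonal"
    PRIVATE = "private"
    UNPLACED = "unplaced"


_CLONALITY_OF_BRANCH = {
    BranchClass.TRUNCAL: Clonality.CLONAL,
    BranchClass.INTERNAL: Clonality.SUBCLONAL,
    BranchClass.TERMINAL: Clonality.PRIVATE,
}


@dataclass
class Placement:
    variant_id: str
    assigned_node: str  # node id or UNPLACED
    clonality: Clonality
    regenotyped_sublines: FrozenSet[str] = frozenset()
    support: int = 0
    clade_size: int = 0

    @property
    def placed(self) -> bool:
        return self.assigned_node != UNPLACED


@dataclass
class OverlapRange:
    """A shared CNA span attributed to one branch."""

    interval: GenomicInterval
    sublines: FrozenSet[str]
    branch: str
    direction: str  # "gain" | "loss"


# ---------------------------------------------------------------------------
# Support threshold
# ---------------------------------------------------------------------------

def min_support(clade_size: int, fn_rate: float) -> int:
    """Minimal carrier count to place a variant at a clade of given size.

    Largest integer s with (clade_size - s)/clade_size >= fn_rate, floored
    at 1; clades of size 1 or 2 require every subline.
    """
    if clade_size < 1:
        raise ValueError("clade_size must be >= 1")
    if clade_size <= 2:
        return clade_size
    for s in range(clade_size, 0, -1):
        if (clade_size - s) / clade_size >= fn_rate:
            return s
    return 1


def effective_fn_rate(clade_size: int, fn_rate: float) -> float:
    """FN rate actually tolerated at the clade: (c - min_support)/c."""
    s = min_support(clade_size, fn_rate)
    return (clade_size - s) / clade_size


# ---------------------------------------------------------------------------
# SNV / SV placement
# ---------------------------------------------------------------------------

def place_variant(
    variant_id: str,
    present_sublines: Iterable[str],
    tree: Phylogeny,
    params: PlacementParams = PlacementParams(),
) -> Placement:
    """Place one variant at the MRCA of its carriers if support suffices."""
    present = set(present_sublines)
    if not present:
        raise ValueError(f"{variant_id}: no carrier sublines")
    node = tree.mrca(present)
    clade = tree.clade_size(node)
    support = len(present)
    if support >= min_support(clade, params.fn_rate):
        return Placement(
            variant_id=variant_id,
            assigned_node=node,
            clonality=_CLONALITY_OF_BRANCH[tree.classify_branch(node)],
            support=support,
            clade_size=clade,
        )
    return Placement(
        variant_id=variant_id,
        assigned_node=UNPLACED,
        clonality=Clonality.UNPLACED,
        support=support,
        clade_size=clade,
    )


class _LossIndex:
    """Per-(subline, chrom) interval index over loss regions."""

    def __init__(self, losses: Iterable[LossRegion]):
        self.trees: Dict[Tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
        for l in losses:
            self.trees[(l.subline, l.interval.chrom)].addi(
                l.interval.start, l.interval.end, l
            )
        self.sublines = {k[0] for k in self.trees}

    def overlapping(self, subline: str, chrom: str, pos0: int) -> List[LossRegion]:
        t = self.trees.get((subline, chrom))
        if t is None:
            return []
        return [iv.data for iv in t.at(pos0)]


def regenotype(
    variant_id: str,
    chrom: str,
    pos: int,
    called_sublines: Set[str],
    loss_index: _LossIndex,
    tree: Phylogeny,
    params: PlacementParams,
    snv_positions: Dict[str, IntervalTree],
) -> Placement:
    """Loss-aware re-evaluation of one SNV.

    Candidate carriers = called sublines plus every subline with a loss
    region overlapping the position. The candidate placement is accepted iff
    (a) the clade support threshold is met, (b) the parsimony guard holds
    (no other SNV of a rescued subline is called inside the rescuing loss
    span), and (c) the reinclusion rate |added|/|called| stays below the
    cap. Otherwise the original called set and its placement stand.
    ``snv_positions`` maps subline -> interval tree of that subline's called
    SNV positions keyed by position, used by the guard.
    """
    pos0 = pos - 1
    original = place_variant(variant_id, called_sublines, tree, params)
    rescues: Dict[str, List[LossRegion]] = {}
    for subline in loss_index.sublines - called_sublines:
        hits = loss_index.overlapping(subline, chrom, pos0)
        if hits:
            rescues[subline] = hits
    if not rescues:
        return original

    added = set(rescues)
    candidate = called_sublines | added

    # (c) dramatic-shift cap
    if len(added) / len(called_sublines) >= params.reinclusion_cap:
        return original

    # (b) parsimony guard: a called SNV of the rescued subline inside the
    # loss span implies the loss hit the other haplotype
    if params.parsimony_guard:
        for subline, losses in rescues.items():
            tree_pos = snv_positions.get(subline)
            if tree_pos is None:
                continue
            for loss in losses:
                if loss.interval.chrom != chrom:
                    continue
                t = tree_pos.get(loss.interval.chrom) if isinstance(tree_pos, dict) else tree_pos
                hits = [
                    iv
                    for iv in t.overlap(loss.interval.start, loss.interval.end)
                    if iv.data != pos0
                ] if t is not None else []
                if hits:
                    return original

    # (a) threshold on the candidate set
    node = tree.mrca(candidate)
    clade = tree.clade_size(node)
    if len(candidate) >= min_support(clade, params.fn_rate):
        return Placement(
            variant_id=variant_id,
            assigned_node=node,
            clonality=_CLONALITY_OF_BRANCH[tree.classify_branch(node)],
            regenotyped_sublines=frozenset(added),
            support=len(candidate),
            clade_size=clade,
        )
    return original


@dataclass
class PlacementSummary:
    clonal: int = 0
    subclonal: int = 0
    private: int = 0
    unplaced: int = 0
    regenotyped: int = 0

    @property
    def total(self) -> int:
        return self.clonal + self.subclonal + self.private + self.unplaced

    @property
    def placed_fraction(self) -> float:
        return (self.total - self.unplaced) / self.total if self.total else 0.0


def _tally(placements: Iterable[Placement]) -> PlacementSummary:
    s = PlacementSummary()
    for p in placements:
        setattr(s, p.clonality.value, getattr(s, p.clonality.value) + 1)
        if p.regenotyped_sublines:
            s.regenotyped += 1
    return s


def place_all_snvs(
    calls: Iterable[SnvCall],
    losses: Iterable[LossRegion],
    tree: Phylogeny,
    params: PlacementParams = PlacementParams(),
) -> Tuple[List[Placement], PlacementSummary]:
    """Place every unique SNV, with regenotyping, in genome order."""
    by_key: Dict[Tuple[str, int, str, str], Set[str]] = defaultdict(set)
    per_subline_pos: Dict[str, Dict[str, IntervalTree]] = defaultdict(dict)
    for c in calls:
        if c.status is VariantStatus.PRESENT:
            by_key[c.key].add(c.subline)
            trees = per_subline_pos[c.subline]
            if c.chrom not in trees:
                trees[c.chrom] = IntervalTree()
            trees[c.chrom].addi(c.pos - 1, c.pos, c.pos - 1)

    loss_index = _LossIndex(losses)
    # flatten per-subline chrom trees for the guard lookup
    guard_index = {s: trees for s, trees in per_subline_pos.items()}

    placements = []
    for key in sorted(by_key):
        chrom, pos, ref, alt = key
        vid = f"{chrom}:{pos}:{ref}>{alt}"
        called = by_key[key]
        p = regenotype(
            vid, chrom, pos, called, loss_index, tree, params,
            {s: t.get(chrom) for s, t in guard_index.items()},
        )
        placements.append(p)
    summary = _tally(placements)
    logger.info(
        "SNV placement: %d variants, %.2f%% placed (%d clonal, %d subclonal, "
        "%d private, %d unplaced), %d regenotyped",
        summary.total, 100 * summary.placed_fraction, summary.clonal,
        summary.subclonal, summary.private, summary.unplaced, summary.regenotyped,
    )
    return placements, summary


def place_all_svs(
    sv_calls: Iterable[SvCall],
    tree: Phylogeny,
    params: PlacementParams = PlacementParams(),
) -> Tuple[List[Placement], PlacementSummary]:
    """Place SVs with the same thresholding as SNVs; no regenotyping."""
    placements = [
        place_variant(sv.variant_id, sv.sublines_present, tree, params)
        for sv in sorted(sv_calls, key=lambda s: (s.breakend_1, s.variant_id))
    ]
    return placements, _tally(placements)


# ---------------------------------------------------------------------------
# CNA placement
# ---------------------------------------------------------------------------

def extract_cn_ranges(
    segments: Iterable[CnaSegment],
) -> Tuple[Dict[str, List[GenomicInterval]], Dict[str, List[GenomicInterval]]]:
    """Per-subline gain (CN>2) and loss (CN<2) ranges, direction-merged.

    Adjacent or overlapping same-direction segments of one subline merge
    into a single range regardless of their exact copy number.
    """
    raw: Dict[Tuple[str, str], List[GenomicInterval]] = defaultdict(list)
    for seg in segments:
        if seg.copy_number > 2:
            raw[("gain", seg.subline)].append(seg.interval)
        elif seg.copy_number < 2:
            raw[("loss", seg.subline)].append(seg.interval)
    gains: Dict[str, List[GenomicInterval]] = defaultdict(list)
    losses: Dict[str, List[GenomicInterval]] = defaultdict(list)
    for (direction, subline), ivs in raw.items():
        merged = _merge_touching(ivs)
        (gains if direction == "gain" else losses)[subline] = merged
    return dict(gains), dict(losses)


def _merge_touching(ivs: Sequence[GenomicInterval]) -> List[GenomicInterval]:
    out: List[GenomicInterval] = []
    for iv in sorted(ivs):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            out[-1] = GenomicInterval(iv.chrom, out[-1].start, max(out[-1].end, iv.end))
        else:
            out.append(iv)
    return out


_Range = Tuple[GenomicInterval, FrozenSet[str]]


def place_cnas(
    per_subline_ranges: Dict[str, List[GenomicInterval]],
    tree: Phylogeny,
    params: PlacementParams = PlacementParams(),
    direction: str = "gain",
) -> List[OverlapRange]:
    """Attribute per-subline CNA ranges to tree branches (one direction).

    Phase 1 builds overlap ranges bottom-up: whenever ranges carried by
    different children of a node overlap, their intersection, tagged with
    the union of carriers, is recorded at the node. Phase 2 keeps, per
    branch, ranges whose carrier count meets the branch's support threshold
    and merges mutually overlapping survivors (union interval, union
    carriers). Phase 3 walks top-down and strips every span already
    attributed to an ancestor, splitting ranges as needed, so spans are
    disjoint along any root-to-leaf path; per-subline residue falls out at
    the terminal branches.
    """
    # Phases 1+2 via a sweep per node: decompose the ranges of the node's
    # subtree sublines into atomic intervals with carrier sets; an overlap
    # range belongs to this node when its carriers span >= 2 children (the
    # carriers' MRCA is the node); threshold, then merge contiguous
    # qualifying atomics back into maximal ranges.
    child_of: Dict[str, Dict[str, str]] = {}
    kept: Dict[str, List[_Range]] = {}
    for node in tree.reverse_level_order():
        if tree.is_leaf(node):
            kept[node] = [
                (iv, frozenset([node])) for iv in per_subline_ranges.get(node, [])
            ]
            continue
        # map each subtree leaf to the child it descends from
        leaf_child = {}
        for c in tree.children[node]:
            for l in tree.leaves_below(c):
                leaf_child[l] = c
        child_of[node] = leaf_child
        thresh = min_support(tree.clade_size(node), params.fn_rate)

        events: Dict[str, List[Tuple[int, int, str]]] = defaultdict(list)
        for leaf in sorted(tree.leaves_below(node)):
            for iv in per_subline_ranges.get(leaf, []):
                events[iv.chrom].append((iv.start, 0, leaf))
                events[iv.chrom].append((iv.end, 1, leaf))
        ranges: List[_Range] = []
        for chrom, evs in events.items():
            evs.sort()
            active: Set[str] = set()
            prev: Optional[int] = None
            run: Optional[Tuple[int, int, Set[str]]] = None  # start,end,carriers
            for pos, kind, leaf in evs:
                if prev is not None and pos > prev and active:
                    carriers = set(active)
                    spans = {leaf_child[l] for l in carriers}
                    if len(spans) >= 2 and len(carriers) >= thresh:
                        if run is not None and run[1] == prev:
                            run = (run[0], pos, run[2] | carriers)
                        else:
                            if run is not None:
                                ranges.append(
                                    (GenomicInterval(chrom, run[0], run[1]),
                                     frozenset(run[2]))
                                )
                            run = (prev, pos, carriers)
                    else:
                        if run is not None:
                            ranges.append(
                                (GenomicInterval(chrom, run[0], run[1]),
                                 frozenset(run[2]))
                            )
                            run = None
                if kind == 0:
                    active.add(leaf)
                else:
                    active.discard(leaf)
                prev = pos
            if run is not None:
                ranges.append(
                    (GenomicInterval(chrom, run[0], run[1]), frozenset(run[2]))
                )
        kept[node] = _merge_mutual(ranges)

    # Phase 3: top-down exclusion of ancestor-assigned spans
    assigned: Dict[str, List[GenomicInterval]] = defaultdict(list)
    out: List[OverlapRange] = []
    for node in tree.level_order():
        blocked: List[GenomicInterval] = []
        for anc in tree.ancestors(node):
            blocked.extend(assigned[anc])
        for iv, subs in kept[node]:
            for piece in _subtract(iv, blocked):
                assigned[node].append(piece)
                out.append(
                    OverlapRange(
                        interval=piece, sublines=subs, branch=node, direction=direction
                    )
                )
    return out


def _dedupe(ranges: Sequence[_Range]) -> List[_Range]:
    seen = set()
    out = []
    for iv, s in ranges:
        key = (iv, s)
        if key not in seen:
            seen.add(key)
            out.append((iv, s))
    return out


def _merge_mutual(ranges: Sequence[_Range]) -> List[_Range]:
    """Merge chains of mutually overlapping ranges (union/union)."""
    items = sorted(ranges, key=lambda r: (r[0].chrom, r[0].start, r[0].end))
    out: List[_Range] = []
    for iv, s in items:
        if out and out[-1][0].chrom == iv.chrom and iv.start < out[-1][0].end:
            prev_iv, prev_s = out[-1]
            out[-1] = (
                GenomicInterval(iv.chrom, prev_iv.start, max(prev_iv.end, iv.end)),
                prev_s | s,
            )
        else:
            out.append((iv, s))
    return out


def _subtract(
    iv: GenomicInterval, blocked: Sequence[GenomicInterval]
) -> List[GenomicInterval]:
    """Pieces of ``iv`` not covered by any blocked interval."""
    pieces = [iv]
    for b in blocked:
        nxt: List[GenomicInterval] = []
        for p in pieces:
            if not p.overlaps(b):
                nxt.append(p)
                continue
            if p.start < b.start:
                nxt.append(GenomicInterval(p.chrom, p.start, b.start))
            if b.end < p.end:
                nxt.append(GenomicInterval(p.chrom, b.end, p.end))
        pieces = nxt
    return pieces
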