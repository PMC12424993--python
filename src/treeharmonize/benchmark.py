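"""Pseudobulk truth sets and clonality-stratified precision/recall.

A pseudobulk sample is an in-silico mixture of sublines; every variant the
harmonizer placed in at least one member becomes a truth-set entry with a
mixture-level clonality (clonal if all members carry it, private if exactly
one does, subclonal otherwise) and an expected VAF of carriers/(2 x members)
for heterozygous diploid loci. Candidate call sets from external variant
callers are scored against the truth at the variant level.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .harmonizer import Placement
from .tree import Phylogeny
from .variants import SnvCall, SvCall, SvType

logger = logging.getLogger(__name__)


@dataclass
class PseudobulkSpec:
    name: str
    members: FrozenSet[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("pseudobulk spec with no members")


class MixClonality(str, enum.Enum):
    CLONAL = "clonal"
    SUBCLONAL = "subclonal"
    PRIVATE = "private"


@dataclass
class TruthVariant:
    variant_id: str
    variant_type: str  # "snv" | SV type
    locus: Tuple[str, int]
    clonality: MixClonality
    expected_vaf: float
    ref: str = ""
    alt: str = ""
    length: Optional[int] = None


@dataclass
class TruthSet:
    spec: PseudobulkSpec
    variants: List[TruthVariant]

    def by_clonality(self) -> Dict[MixClonality, List[TruthVariant]]:
        out: Dict[MixClonality, List[TruthVariant]] = {c: [] for c in MixClonality}
        for v in self.variants:
            out[v.clonality].append(v)
        return out


def build_truth_set(
    placements: Iterable[Placement],
    spec: PseudobulkSpec,
    tree: Phylogeny,
    loci: Optional[Mapping[str, Tuple[str, int, str, str]]] = None,
    variant_types: Optional[Mapping[str, str]] = None,
) -> TruthSet:
    """Truth set for one pseudobulk mixture from harmonizer placements.

    Unplaced variants never enter a truth set. A variant's carriers in the
    mixture are the members below its branch, minus members in which it was
    regenotyped as "lost". ``loci`` maps variant_id -> (chrom, pos, ref,
    alt) for SNV matching; ``variant_types`` maps variant_id -> type label
    (default "snv").
    """
    members = spec.members & set(tree.leaf_labels)
    variants: List[TruthVariant] = []
    if not members:
        logger.warning("pseudobulk %s shares no members with the tree", spec.name)
        return TruthSet(spec=spec, variants=[])
    n = len(spec.members)
    for p in placements:
        if not p.placed:
            continue
        carriers = (tree.leaves_below(p.assigned_node) - p.regenotyped_sublines) & members
        k = len(carriers)
        if k == 0:
            continue
        if k == n:
            clon = MixClonality.CLONAL
        elif k == 1:
            clon = MixClonality.PRIVATE
        else:
            clon = MixClonality.SUBCLONAL
        chrom, pos, ref, alt = (
            loci[p.variant_id] if loci and p.variant_id in loci else ("", 0, "", "")
        )
        variants.append(
            TruthVariant(
                variant_id=p.variant_id,
                variant_type=(variant_types or {}).get(p.variant_id, "snv"),
                locus=(chrom, pos),
                clonality=clon,
                expected_vaf=k / (2 * n),
                ref=ref,
                alt=alt,
            )
        )
    return TruthSet(spec=spec, variants=variants)


@dataclass
class ScoreResult:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")


@dataclass
class CandidateVariant:
    """One record from an external caller's output."""

    variant_type: str
    chrom: str
    pos: int
    ref: str = ""
    alt: str = ""
    length: Optional[int] = None


def score_calls(
    candidates: Sequence[CandidateVariant],
    truth: TruthSet,
    sv_tolerance: int = 50,
    ins_length_tolerance: float = 0.2,
) -> Dict[str, ScoreResult]:
    """Precision/recall overall and per mixture-clonality stratum.

    SNVs match on exact (chrom, pos, ref, alt); SVs match on type with
    breakend position within ``sv_tolerance`` bp (insertions additionally
    on length within 20%). Deterministic and order-independent.
    """
    truth_by_clon = truth.by_clonality()
    matched_truth: Set[int] = set()
    matched_cand: Set[int] = set()

    # index truth by type for matching
    snv_index: Dict[Tuple[str, int, str, str], int] = {}
    sv_entries: List[Tuple[int, TruthVariant]] = []
    for i, tv in enumerate(truth.variants):
        if tv.variant_type == "snv":
            snv_index[(tv.locus[0], tv.locus[1], tv.ref, tv.alt)] = i
        else:
            sv_entries.append((i, tv))

    for j, cand in enumerate(sorted(
        range(len(candidates)),
        key=lambda k: (candidates[k].chrom, candidates[k].pos, candidates[k].alt),
    )):
        c = candidates[cand]
        if c.variant_type == "snv":
            i = snv_index.get((c.chrom, c.pos, c.ref, c.alt))
            if i is not None and i not in matched_truth:
                matched_truth.add(i)
                matched_cand.add(cand)
        else:
            for i, tv in sv_entries:
                if i in matched_truth or tv.variant_type != c.variant_type:
                    continue
                if tv.locus[0] != c.chrom or abs(tv.locus[1] - c.pos) > sv_tolerance:
                    continue
                if (
                    c.variant_type == SvType.INS.value
                    and c.length is not None
                    and tv.length is not None
                    and abs(c.length - tv.length) > ins_length_tolerance * tv.length
                ):
                    continue
                matched_truth.add(i)
                matched_cand.add(cand)
                break

    results: Dict[str, ScoreResult] = {}
    tp = len(matched_truth)
    fp = len(candidates) - len(matched_cand)
    fn = len(truth.variants) - tp
    results["overall"] = ScoreResult(tp=tp, fp=fp, fn=fn)
    for clon, tvs in truth_by_clon.items():
        idxs = {i for i, tv in enumerate(truth.variants) if tv.clonality is clon}
        s_tp = len(idxs & matched_truth)
        results[clon.value] = ScoreResult(tp=s_tp, fp=0, fn=len(idxs) - s_tp)
    return results
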