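"""Seeded generator of complete synthetic subline datasets.

Emulates the statistical structure of a multi-clade clonal-subline study:
a rooted tree with a caterpillar (linearly differentiating) clade, branch-
assigned SNVs and SVs propagated to descendant leaves, false negatives a
configurable fraction of which are realized as small overlapping deletions
(so loss-aware regenotyping is well-posed), copy-number events whose
boundaries coincide with emitted SV breakpoints (including parallel events
hitting the same region from different lineages via distinct breakpoints),
beta-binomial CpG methylation with branch-shifted and monotonically
drifting regions, per-mutation signature probabilities biased toward a UV
signature at the trunk, and functional annotations.

Variant loci are kept clear of unrelated deletion spans by construction, so
placement accuracy on the bundle is attributable to the placement logic
rather than to coincidental overlaps; planted masks are the only intended
loss/SNV interactions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .branch_dynamics import SignatureProbTable
from .harmonizer import min_support
from .methylome import MethylMatrix
from .tree import Phylogeny
from .variants import (
    CnaSegment,
    GenomicInterval,
    LossRegion,
    LossSource,
    SnvCall,
    SvCall,
    SvType,
    VariantStatus,
    write_cna_tsv,
    write_loss_bed,
)

BASES = ("A", "C", "G", "T")


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic dataset.

    Defaults emulate the reference design: 23 sublines in 4 major clades,
    the first clade an 8-subline caterpillar, 15% FN rate with half of the
    FNs caused by deletions, and a 0.001% FP rate.
    """

    seed: int
    n_sublines: int = 23
    n_clades: int = 4
    clade_sizes: Optional[Tuple[int, ...]] = None  # first clade = caterpillar
    n_snvs: int = 2000
    n_svs: int = 120
    fn_rate: float = 0.15
    fp_rate: float = 1e-5
    deletion_fn_fraction: float = 0.5
    clonal_fraction: float = 0.08
    subclonal_fraction: float = 0.08
    n_cna_events: int = 8
    n_parallel_pairs: int = 1
    meth_n_regions: int = 80
    meth_cpgs_per_region: int = 12
    meth_n_branch_shift: int = 2
    meth_n_monotonic: int = 4
    meth_effect_size: float = 0.3
    meth_coverage_mean: float = 20.0
    meth_coverage_dispersion: float = 0.1
    meth_subline_sd: float = 0.03
    snv_depth_mean: float = 30.0
    nonsyn_fraction: float = 0.25
    syn_fraction: float = 0.10
    chrom_sizes: Dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 10_000_000 for i in range(1, 6)}
    )

    def __post_init__(self) -> None:
        if self.clade_sizes is None:
            self.clade_sizes = _default_clade_sizes(self.n_sublines, self.n_clades)
        if sum(self.clade_sizes) != self.n_sublines:
            raise ValueError("clade sizes must sum to n_sublines")
        if len(self.clade_sizes) != self.n_clades:
            raise ValueError("need one size per clade")
        if self.n_parallel_pairs > 0 and self.n_clades < 2:
            raise ValueError("parallel CNA events need >= 2 clades")
        for frac in (self.fn_rate, self.fp_rate, self.deletion_fn_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("rates must be fractions in [0,1]")


def _default_clade_sizes(n: int, k: int) -> Tuple[int, ...]:
    """First clade gets the larger (caterpillar) share, as in the study."""
    if n == 23 and k == 4:
        return (8, 5, 5, 5)
    base = n // k
    sizes = [base] * k
    for i in range(n - base * k):
        sizes[i] += 1
    sizes.sort(reverse=True)
    return tuple(sizes)


@dataclass
class VariantTruth:
    variant_id: str
    branch: str
    carriers: FrozenSetStr = frozenset()
    plain_fn: FrozenSetStr = frozenset()
    deletion_fn: FrozenSetStr = frozenset()
    is_fp: bool = False
    observed: bool = True


FrozenSetStr = frozenset


@dataclass
class CnaTruth:
    branch: str
    interval: GenomicInterval
    direction: str
    parallel_group: Optional[int] = None


@dataclass
class MethRegionTruth:
    interval: GenomicInterval
    kind: str  # "null" | "branch_shift" | "monotonic"
    effect: float = 0.0
    clade_node: Optional[str] = None


@dataclass
class GroundTruth:
    tree_newick: str
    variants: Dict[str, VariantTruth]
    sv_branches: Dict[str, str]
    cna_events: List[CnaTruth]
    meth_regions: List[MethRegionTruth]
    caterpillar_order: List[str]


@dataclass
class SimBundle:
    config: SimConfig
    tree: Phylogeny
    snv_calls: List[SnvCall]
    sv_calls: List[SvCall]
    cna_segments: List[CnaSegment]
    loss_regions: List[LossRegion]
    methylation: MethylMatrix
    signature_probs: SignatureProbTable
    consequences: Dict[str, str]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Tree construction
# ---------------------------------------------------------------------------

def build_tree(config: SimConfig) -> Tuple[Phylogeny, List[str]]:
    """Deterministic tree: first clade caterpillar, others ladderized balanced.

    Returns the tree and the caterpillar clade's trajectory order
    (earliest-diverging subline first).
    """
    labels = [f"C{i+1}" for i in range(config.n_sublines)]
    clades = []
    idx = 0
    for k, size in enumerate(config.clade_sizes):
        members = labels[idx : idx + size]
        idx += size
        if size == 1:
            clades.append(members[0])
        elif k == 0:
            # caterpillar: earliest-diverging member attaches highest
            nwk = f"({members[-1]},{members[-2]})"
            for m in reversed(members[:-2]):
                nwk = f"({m},{nwk})"
            clades.append(nwk)
        else:
            clades.append(_balanced(members))
    spine = clades[-1]
    for c in reversed(clades[:-1]):
        spine = f"({c},{spine})"
    tree = Phylogeny.from_newick(spine + ";")
    caterpillar_order = labels[: config.clade_sizes[0]]
    return tree, caterpillar_order


def _balanced(members: Sequence[str]) -> str:
    if len(members) == 1:
        return members[0]
    mid = len(members) // 2
    return f"({_balanced(members[:mid])},{_balanced(members[mid:])})"


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------

def simulate(config: SimConfig) -> SimBundle:
    """Generate a full dataset bundle plus ground truth (deterministic per seed)."""
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_snv = np.random.default_rng(streams[0])
    rng_sv = np.random.default_rng(streams[1])
    rng_cna = np.random.default_rng(streams[2])
    rng_meth = np.random.default_rng(streams[3])
    rng_sig = np.random.default_rng(streams[4])
    rng_ann = np.random.default_rng(streams[5])

    tree, caterpillar = build_tree(config)
    leaves = tree.leaf_labels
    nodes = tree.nodes()
    internal = [n for n in nodes if n != tree.root and not tree.is_leaf(n)]

    # branch weights: clonal / subclonal / private shares
    weights = {}
    weights[tree.root] = config.clonal_fraction
    for n in internal:
        weights[n] = config.subclonal_fraction / max(len(internal), 1)
    private_share = 1 - config.clonal_fraction - config.subclonal_fraction
    for l in leaves:
        weights[l] = private_share / len(leaves)
    node_list = list(weights)
    probs = np.array([weights[n] for n in node_list])
    probs /= probs.sum()

    chroms = list(config.chrom_sizes)

    used_positions: Set[Tuple[str, int]] = set()

    def fresh_site(rng) -> Tuple[str, int]:
        while True:
            chrom = chroms[rng.integers(len(chroms))]
            pos = int(rng.integers(1, config.chrom_sizes[chrom]))
            if (chrom, pos) not in used_positions:
                used_positions.add((chrom, pos))
                return chrom, pos

    # ---- SNVs ------------------------------------------------------------
    variants: Dict[str, VariantTruth] = {}
    calls: List[SnvCall] = []
    called_pos: Dict[str, Set[Tuple[str, int]]] = defaultdict(set)
    planned: List[Tuple[str, str, int, str, str, Set[str], Set[str], Set[str]]] = []

    for _ in range(config.n_snvs):
        branch = node_list[rng_snv.choice(len(node_list), p=probs)]
        chrom, pos = fresh_site(rng_snv)
        ref = BASES[rng_snv.integers(4)]
        alt = rng_snv.choice([b for b in BASES if b != ref])
        vid = f"{chrom}:{pos}:{ref}>{alt}"
        carriers = set(tree.leaves_below(branch))
        clade = len(carriers)

        # iterate in sorted order: set order is hash-randomized per process
        # and the rng draws must be reproducible across runs
        fn: Set[str] = {
            s for s in sorted(carriers) if rng_snv.random() < config.fn_rate
        }
        del_fn = {
            s for s in sorted(fn) if rng_snv.random() < config.deletion_fn_fraction
        }
        if clade < 3:
            del_fn = set()  # a rescue here would always trip the reinclusion cap
        # keep the rescue below the reinclusion cap: |del_fn| < |called|
        called = carriers - fn
        while del_fn and len(del_fn) >= len(called):
            del_fn.remove(sorted(del_fn)[-1])
        plain_fn = fn - del_fn
        planned.append((vid, branch, pos, chrom, alt, carriers, plain_fn, del_fn))
        variants[vid] = VariantTruth(
            variant_id=vid,
            branch=branch,
            carriers=frozenset(carriers),
            plain_fn=frozenset(plain_fn),
            deletion_fn=frozenset(del_fn),
            observed=bool(called),
        )
        for s in sorted(called):
            depth = max(1, int(rng_snv.poisson(config.snv_depth_mean)))
            alt_depth = int(rng_snv.binomial(depth, 0.5))
            alt_depth = max(1, alt_depth)
            calls.append(
                SnvCall(
                    chrom=chrom,
                    pos=pos,
                    ref_allele=ref,
                    alt_allele=str(alt),
                    subline=s,
                    status=VariantStatus.PRESENT,
                    depth=depth,
                    alt_depth=min(alt_depth, depth),
                )
            )
            called_pos[s].add((chrom, pos))

    # false positives: private singleton calls
    n_fp = rng_snv.poisson(config.fp_rate * config.n_snvs * config.n_sublines)
    for _ in range(n_fp):
        chrom, pos = fresh_site(rng_snv)
        ref = BASES[rng_snv.integers(4)]
        alt = str(rng_snv.choice([b for b in BASES if b != ref]))
        s = leaves[rng_snv.integers(len(leaves))]
        vid = f"{chrom}:{pos}:{ref}>{alt}"
        variants[vid] = VariantTruth(
            variant_id=vid, branch=s, carriers=frozenset([s]), is_fp=True
        )
        depth = max(1, int(rng_snv.poisson(config.snv_depth_mean)))
        calls.append(
            SnvCall(chrom, pos, ref, alt, s, VariantStatus.PRESENT,
                    depth=depth, alt_depth=max(1, depth // 3))
        )
        called_pos[s].add((chrom, pos))

    # ---- masking deletions (one small private DEL per deletion-caused FN)
    sv_calls: List[SvCall] = []
    losses: List[LossRegion] = []
    mask_k = 0
    for vid, branch, pos, chrom, alt, carriers, plain_fn, del_fn in planned:
        for s in sorted(del_fn):
            half = 30
            start0 = max(0, pos - 1 - half)
            end0 = pos - 1 + half
            clash = any(
                start0 <= p - 1 < end0 and p != pos
                for (c, p) in called_pos[s]
                if c == chrom
            )
            if clash:  # shrink to the locus itself
                start0, end0 = pos - 1, pos
            iv = GenomicInterval(chrom, start0, end0)
            losses.append(LossRegion(iv, s, LossSource.SV_DELETION))
            sv_calls.append(
                SvCall(
                    variant_id=f"mask_del_{mask_k}",
                    sv_type=SvType.DEL,
                    breakend_1=(chrom, start0),
                    breakend_2=(chrom, end0),
                    length=end0 - start0,
                    sublines_present={s},
                )
            )
            mask_k += 1

    # ---- unrelated SVs (avoid SNV loci so placements stay attributable)
    sv_branches: Dict[str, str] = {}
    sv_types = [SvType.DEL, SvType.INS, SvType.DUP, SvType.INV, SvType.BND]
    sv_type_p = np.array([0.45, 0.25, 0.10, 0.10, 0.10])
    for k in range(config.n_svs):
        branch = node_list[rng_sv.choice(len(node_list), p=probs)]
        svt = sv_types[rng_sv.choice(len(sv_types), p=sv_type_p)]
        for _ in range(50):
            chrom = chroms[rng_sv.integers(len(chroms))]
            length = int(rng_sv.lognormal(5.5, 1.0)) + 50
            start = int(rng_sv.integers(1, config.chrom_sizes[chrom] - length - 1))
            span = range(start, start + length)
            if svt is SvType.DEL and any(
                (chrom, p) in used_positions for p in span
            ):
                continue
            break
        vid = f"sv_{k}_{svt.value}"
        carriers = set(tree.leaves_below(branch))
        if svt is SvType.INS:
            be2 = None
        elif svt is SvType.BND:
            other = chroms[rng_sv.integers(len(chroms))]
            be2 = (other, int(rng_sv.integers(1, config.chrom_sizes[other])))
        else:
            be2 = (chrom, start + length)
        sv_calls.append(
            SvCall(
                variant_id=vid,
                sv_type=svt,
                breakend_1=(chrom, start),
                breakend_2=be2,
                length=length,
                sublines_present=carriers,
            )
        )
        sv_branches[vid] = branch
        if svt is SvType.DEL:
            for s in sorted(carriers):
                losses.append(
                    LossRegion(
                        GenomicInterval(chrom, start, start + length),
                        s,
                        LossSource.SV_DELETION,
                    )
                )

    # ---- CNA events ------------------------------------------------------
    segments: List[CnaSegment] = []
    cna_truth: List[CnaTruth] = []
    slot_bp = 400_000
    slot = 0

    def cna_slot() -> Tuple[str, int]:
        nonlocal slot
        chrom = chroms[slot % len(chroms)]
        offset = 1_000_000 + (slot // len(chroms)) * (2 * slot_bp)
        slot += 1
        return chrom, offset

    def emit_event(branch: str, chrom: str, start: int, end: int,
                   direction: str, group: Optional[int]) -> None:
        cn = 3 if direction == "gain" else 1
        iv = GenomicInterval(chrom, start, end)
        for s in sorted(tree.leaves_below(branch)):
            segments.append(CnaSegment(iv, cn, s))
            if cn <= 1:
                losses.append(LossRegion(iv, s, LossSource.CN_LOSS))
        sv_calls.append(
            SvCall(
                variant_id=f"cna_sv_{len(cna_truth)}",
                sv_type=SvType.DUP if direction == "gain" else SvType.DEL,
                breakend_1=(chrom, start),
                breakend_2=(chrom, end),
                length=end - start,
                sublines_present=set(tree.leaves_below(branch)),
            )
        )
        cna_truth.append(CnaTruth(branch, iv, direction, group))

    clade_roots = tree.children[tree.root]
    # resolve the actual clade root nodes (the spine nests clades)
    def clade_nodes() -> List[str]:
        out = []
        node = tree.root
        for _ in range(config.n_clades - 1):
            kids = tree.children[node]
            out.append(kids[0])
            node = kids[1]
        out.append(node)
        return out

    majors = clade_nodes()

    for k in range(config.n_cna_events):
        chrom, offset = cna_slot()
        direction = "gain" if rng_cna.random() < 0.7 else "loss"
        branch = majors[rng_cna.integers(len(majors))]
        if rng_cna.random() < 0.3:  # some events are private
            sub = sorted(tree.leaves_below(branch))
            branch = sub[rng_cna.integers(len(sub))]
        start = offset + int(rng_cna.integers(0, 50_000))
        end = start + int(rng_cna.integers(100_000, slot_bp - 60_000))
        emit_event(branch, chrom, start, end, direction, None)

    for g in range(config.n_parallel_pairs):
        chrom, offset = cna_slot()
        b1, b2 = rng_cna.choice(len(majors), size=2, replace=False)
        core = (offset + 100_000, offset + 250_000)
        # same region, distinct SV-defined breakpoints, independent branches
        emit_event(majors[b1], chrom, core[0] - int(rng_cna.integers(10_000, 40_000)),
                   core[1] + int(rng_cna.integers(10_000, 40_000)), "gain", g)
        emit_event(majors[b2], chrom, core[0] - int(rng_cna.integers(45_000, 80_000)),
                   core[1] + int(rng_cna.integers(45_000, 80_000)), "gain", g)

    # ---- methylation -----------------------------------------------------
    methylation, meth_truth = _simulate_methylation(
        config, tree, caterpillar, rng_meth, chroms
    )

    # ---- signature probabilities and annotations -------------------------
    signatures = ["SBS1", "SBS17a", "SBS5", "SBS7a", "SBS7b", "SBS85"]
    trunk_w = np.array([0.5, 0.3, 0.8, 4.0, 2.5, 0.4])
    other_w = np.array([2.5, 1.0, 3.0, 0.4, 0.3, 0.8])
    prob_rows: Dict[Tuple[str, str], Dict[str, float]] = {}
    consequences: Dict[str, str] = {}
    for vid, vt in variants.items():
        if not vt.observed:
            continue
        w = trunk_w if vt.branch == tree.root else other_w
        for s in sorted(vt.carriers):
            vec = rng_sig.dirichlet(w)
            prob_rows[(vid, s)] = dict(zip(signatures, vec.tolist()))
        u = rng_ann.random()
        if u < config.nonsyn_fraction:
            consequences[vid] = "nonsynonymous"
        elif u < config.nonsyn_fraction + config.syn_fraction:
            consequences[vid] = "synonymous"
        else:
            consequences[vid] = "other"

    truth = GroundTruth(
        tree_newick=tree.to_newick(),
        variants=variants,
        sv_branches=sv_branches,
        cna_events=cna_truth,
        meth_regions=meth_truth,
        caterpillar_order=caterpillar,
    )
    return SimBundle(
        config=config,
        tree=tree,
        snv_calls=calls,
        sv_calls=sv_calls,
        cna_segments=segments,
        loss_regions=losses,
        methylation=methylation,
        signature_probs=SignatureProbTable(prob_rows),
        consequences=consequences,
        truth=truth,
    )


def _simulate_methylation(
    config: SimConfig,
    tree: Phylogeny,
    caterpillar: Sequence[str],
    rng: np.random.Generator,
    chroms: Sequence[str],
) -> Tuple[MethylMatrix, List[MethRegionTruth]]:
    leaves = tree.leaf_labels
    cat_set = set(caterpillar)
    kinds = (
        ["branch_shift"] * config.meth_n_branch_shift
        + ["monotonic"] * config.meth_n_monotonic
        + ["null"] * (config.meth_n_regions - config.meth_n_branch_shift
                      - config.meth_n_monotonic)
    )
    rng.shuffle(kinds)

    clade_root = tree.mrca(cat_set) if len(cat_set) > 1 else caterpillar[0]
    r = 1.0 / config.meth_coverage_dispersion
    sites: List[Tuple[str, int]] = []
    mod_rows: List[List[int]] = []
    tot_rows: List[List[int]] = []
    meth_truth: List[MethRegionTruth] = []
    region_gap = 10_000

    for ridx, kind in enumerate(kinds):
        chrom = chroms[ridx % len(chroms)]
        start = 500_000 + (ridx // len(chroms)) * region_gap
        mu = float(rng.uniform(0.25, 0.75))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        means = {}
        for s in leaves:
            m = mu + rng.normal(0, config.meth_subline_sd)
            if kind == "branch_shift" and s in cat_set:
                m += sign * config.meth_effect_size
            if kind == "monotonic" and s in cat_set:
                k = caterpillar.index(s)
                m += sign * config.meth_effect_size * (
                    k / (len(caterpillar) - 1) - 0.5
                )
            means[s] = float(np.clip(m, 0.02, 0.98))
        pos = start
        region_positions = []
        for _ in range(config.meth_cpgs_per_region):
            pos += int(rng.integers(15, 40))
            region_positions.append(pos)
            mods, tots = [], []
            for s in leaves:
                p_nb = r / (r + config.meth_coverage_mean)
                cov = int(rng.negative_binomial(r, p_nb))
                p_site = float(rng.beta(means[s] * 40, (1 - means[s]) * 40))
                mods.append(int(rng.binomial(cov, p_site)) if cov else 0)
                tots.append(cov)
            sites.append((chrom, pos))
            mod_rows.append(mods)
            tot_rows.append(tots)
        meth_truth.append(
            MethRegionTruth(
                interval=GenomicInterval(
                    chrom, region_positions[0], region_positions[-1] + 1
                ),
                kind=kind,
                effect=config.meth_effect_size if kind != "null" else 0.0,
                clade_node=clade_root if kind != "null" else None,
            )
        )

    idx = pd.MultiIndex.from_tuples(sites, names=["chrom", "pos"])
    n_mod = pd.DataFrame(mod_rows, index=idx, columns=leaves).sort_index()
    n_tot = pd.DataFrame(tot_rows, index=idx, columns=leaves).sort_index()
    sites_sorted = list(n_mod.index)
    return MethylMatrix(sites_sorted, list(leaves), n_mod, n_tot), meth_truth


# ---------------------------------------------------------------------------
# Worked example
# ---------------------------------------------------------------------------

def make_worked_example() -> SimBundle:
    """Tiny fixed dataset (6 sublines, 2 clades, <=50 variants).

    Small enough that every placement is hand-checkable against the support
    threshold; includes one deletion-masked variant whose regenotyping
    outcome flips if the deletion record is removed.
    """
    config = SimConfig(
        seed=7,
        n_sublines=6,
        n_clades=2,
        clade_sizes=(4, 2),
        n_snvs=40,
        n_svs=8,
        n_cna_events=2,
        n_parallel_pairs=0,
        meth_n_regions=12,
        meth_n_branch_shift=1,
        meth_n_monotonic=1,
    )
    return simulate(config)


# ---------------------------------------------------------------------------
# Bundle serialization (plain-text formats only)
# ---------------------------------------------------------------------------

def write_bundle(bundle: SimBundle, outdir: str) -> Dict[str, str]:
    """Write the bundle to a directory; returns a manifest of checksums."""
    os.makedirs(outdir, exist_ok=True)
    tree_path = os.path.join(outdir, "tree.nwk")
    bundle.tree.write_newick(tree_path)

    snv_dir = os.path.join(outdir, "snv")
    os.makedirs(snv_dir, exist_ok=True)
    by_subline: Dict[str, List[SnvCall]] = defaultdict(list)
    for c in bundle.snv_calls:
        by_subline[c.subline].append(c)
    for s in bundle.tree.leaf_labels:
        _write_snv_vcf(
            sorted(by_subline.get(s, []), key=lambda c: (c.chrom, c.pos)),
            s,
            os.path.join(snv_dir, f"{s}.vcf"),
            bundle.config.chrom_sizes,
        )

    _write_sv_vcf(
        bundle.sv_calls,
        bundle.tree.leaf_labels,
        os.path.join(outdir, "sv.vcf"),
        bundle.config.chrom_sizes,
    )
    write_cna_tsv(bundle.cna_segments, os.path.join(outdir, "cna.tsv"))
    write_loss_bed(bundle.loss_regions, os.path.join(outdir, "loss.bed"))
    bundle.methylation.to_tsv(os.path.join(outdir, "methylation.tsv"))
    bundle.signature_probs.to_tsv(os.path.join(outdir, "signature_probs.tsv"))
    pd.DataFrame(
        sorted(bundle.consequences.items()), columns=["mutation_id", "consequence"]
    ).to_csv(os.path.join(outdir, "annotations.tsv"), sep="\t", index=False)

    manifest = {"config": _config_dict(bundle.config), "checksums": {}}
    for root, _, files in os.walk(outdir):
        for f in sorted(files):
            if f == "manifest.json":
                continue
            path = os.path.join(root, f)
            rel = os.path.relpath(path, outdir)
            with open(path, "rb") as fh:
                manifest["checksums"][rel] = hashlib.sha256(fh.read()).hexdigest()
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest["checksums"]


def _config_dict(config: SimConfig) -> Dict:
    d = dataclasses.asdict(config)
    d["clade_sizes"] = list(d["clade_sizes"])
    return d


def _vcf_header(chrom_sizes: Dict[str, int], samples: Sequence[str]) -> str:
    lines = ["##fileformat=VCFv4.2"]
    for chrom, size in chrom_sizes.items():
        lines.append(f"##contig=<ID={chrom},length={size}>")
    lines += [
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
    ]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    return "\n".join(lines) + "\n"


def _write_snv_vcf(
    calls: Sequence[SnvCall], subline: str, path: str, chrom_sizes: Dict[str, int]
) -> None:
    with open(path, "w") as fh:
        fh.write(_vcf_header(chrom_sizes, [subline]))
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.pos}\t.\t{c.ref_allele}\t{c.alt_allele}\t.\tPASS\t.\t"
                f"GT:DP:AD\t0/1:{c.depth}:{c.depth - c.alt_depth},{c.alt_depth}\n"
            )


def _write_sv_vcf(
    svs: Sequence[SvCall], samples: Sequence[str], path: str,
    chrom_sizes: Dict[str, int],
) -> None:
    with open(path, "w") as fh:
        fh.write(_vcf_header(chrom_sizes, samples))
        for sv in sorted(svs, key=lambda s: (s.breakend_1, s.variant_id)):
            chrom, pos = sv.breakend_1
            pos = max(pos, 1)
            info = [f"SVTYPE={sv.sv_type.value}"]
            if sv.sv_type in (SvType.DEL, SvType.DUP, SvType.INV):
                info.append(f"END={sv.breakend_2[1]}")
            if sv.length is not None:
                sign = "-" if sv.sv_type is SvType.DEL else ""
                info.append(f"SVLEN={sign}{sv.length}")
            if sv.sv_type is SvType.BND and sv.breakend_2 is not None:
                alt = f"N[{sv.breakend_2[0]}:{sv.breakend_2[1]}["
            else:
                alt = f"<{sv.sv_type.value}>"
            gts = "\t".join(
                "0/1" if s in sv.sublines_present else "0/0" for s in samples
            )
            fh.write(
                f"{chrom}\t{pos}\t{sv.variant_id}\tN\t{alt}\t.\tPASS\t"
                f"{';'.join(info)}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Null-model helpers used by calibration studies
# ---------------------------------------------------------------------------

def simulate_exchangeable_methylation(
    sublines: Sequence[str],
    n_regions: int,
    cpgs_per_region: int,
    seed: int,
    subline_sd: float = 0.12,
    cpg_sd: float = 0.10,
    cpg_spacing: Tuple[int, int] = (250, 500),
    coverage_mean: float = 20.0,
    idio_rate: float = 0.0,
    idio_effect: float = 0.35,
) -> MethylMatrix:
    """Methylation with i.i.d. per-subline region means (exchangeable null).

    Sublines differ region by region (``subline_sd``) and CpG by CpG
    (``cpg_sd``), but with no group structure, so any case/control
    bipartition is exchangeable — the regime under which a permutation
    p-value is uniform. ``idio_rate`` adds, per subline, a Poisson number
    of idiosyncratic drift regions shifted by ±``idio_effect`` (focal
    epigenetic drift private to a subline); this keeps the null DMR count
    genuinely variable across bipartitions instead of being pinned by the
    genome-wide quantile cut.
    """
    rng = np.random.default_rng(seed)
    n_sub = len(sublines)
    n_sites = n_regions * cpgs_per_region
    mu = rng.uniform(0.3, 0.7, size=n_regions)
    region_means = np.clip(
        mu[:, None] + rng.normal(0, subline_sd, size=(n_regions, n_sub)), 0.02, 0.98
    )
    if idio_rate > 0:
        for j in range(n_sub):
            # per-subline drift burden is itself random (overdispersed),
            # mirroring how some clones drift epigenetically far more than
            # others; keeps bipartition null counts well spread
            k = rng.poisson(rng.exponential(idio_rate))
            if k:
                hit = rng.choice(n_regions, size=min(k, n_regions), replace=False)
                signs = rng.choice([-1.0, 1.0], size=len(hit))
                region_means[hit, j] = np.clip(
                    region_means[hit, j] + signs * idio_effect, 0.02, 0.98
                )
    site_means = np.clip(
        np.repeat(region_means, cpgs_per_region, axis=0)
        + rng.normal(0, cpg_sd, size=(n_sites, n_sub)),
        0.01,
        0.99,
    )
    cov = rng.poisson(coverage_mean, size=(n_sites, n_sub))
    mod = rng.binomial(cov, site_means)
    gaps = rng.integers(*cpg_spacing, size=(n_regions, cpgs_per_region))
    pos = (
        100_000
        + 50_000 * np.repeat(np.arange(n_regions), cpgs_per_region)
        + np.cumsum(gaps, axis=1).ravel()
    )
    sites = [("chr1", int(p)) for p in pos]
    idx = pd.MultiIndex.from_tuples(sites, names=["chrom", "pos"])
    n_mod = pd.DataFrame(mod, index=idx, columns=list(sublines)).sort_index()
    n_tot = pd.DataFrame(cov, index=idx, columns=list(sublines)).sort_index()
    return MethylMatrix(list(n_mod.index), list(sublines), n_mod, n_tot)
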