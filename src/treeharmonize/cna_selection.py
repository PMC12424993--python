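"""Selection signals in copy-number output: ONC/TSG enrichment, boundary
orientation, and copy-neutral LOH timing.

Genes with curated oncogene (ONC) / tumor-suppressor (TSG) labels are
scored by whether they fall entirely inside gain or loss segments; two
chi-square tests ask whether ONCs are preferentially gained-only and TSGs
preferentially lost-only. A label-permutation test asks whether, at
copy-number boundaries separating an adjacent ONC/TSG pair, the ONC sits on
the higher-copy side more often than chance. Finally, a counting argument
on clonal homozygous SNVs times a whole-chromosome copy-neutral LOH event
as a fraction of the phylogeny trunk.
"""

from __future__ import annotations

import enum
import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .variants import CnaSegment, GenomicInterval

logger = logging.getLogger(__name__)


class GeneLabel(str, enum.Enum):
    ONC = "ONC"
    TSG = "TSG"
    ND = "ND"


@dataclass
class GeneRecord:
    gene: str
    interval: GenomicInterval
    label: GeneLabel


def read_gene_table(path: str, overrides: Optional[Mapping[str, str]] = None) -> List[GeneRecord]:
    """Read a gene/label TSV (gene, chrom, start, end, label); apply overrides."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for r in df.itertuples():
        label = overrides.get(r.gene, r.label) if overrides else r.label
        out.append(
            GeneRecord(
                gene=str(r.gene),
                interval=GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
                label=GeneLabel(str(label)),
            )
        )
    return out


class CnStatus(str, enum.Enum):
    LOSS = "loss"
    NEUTRAL = "neutral"
    GAIN = "gain"


def gene_cn_status(
    genes: Sequence[GeneRecord],
    segments: Iterable[CnaSegment],
) -> pd.DataFrame:
    """Copy-number status per (gene, subline): gain/loss only on full containment.

    A gene entirely inside a CN>2 segment is "gain", inside a CN<2 segment
    "loss"; genes straddling a segment boundary stay "neutral".
    """
    by_subline: Dict[str, List[CnaSegment]] = defaultdict(list)
    for seg in segments:
        by_subline[seg.subline].append(seg)
    rows = []
    for subline, segs in sorted(by_subline.items()):
        for g in genes:
            status = CnStatus.NEUTRAL
            for seg in segs:
                if seg.copy_number != 2 and seg.interval.contains(g.interval):
                    status = CnStatus.GAIN if seg.copy_number > 2 else CnStatus.LOSS
                    break
            rows.append((g.gene, subline, status.value))
    return pd.DataFrame(rows, columns=["gene", "subline", "status"])


def onc_tsg_enrichment_tests(
    status_table: pd.DataFrame,
    genes: Sequence[GeneRecord],
    yates: bool = False,
) -> Dict[str, Dict[str, float]]:
    """Two chi-square tests on CNA-impacted ONC/TSG genes.

    Test "gained_only": 2x2 of label (ONC vs TSG) x whether the gene was
    gained in >= 1 subline and lost in none. Test "lost_only": the mirrored
    construction. Restricted to ONC/TSG genes impacted by CNA in >= 1
    subline. Expected cells < 1 raise a continuity warning in the result.
    """
    if status_table.empty:
        raise ValueError("empty status table")
    labels = {g.gene: g.label for g in genes}
    per_gene = status_table.groupby("gene")["status"].agg(
        gained=lambda s: (s == "gain").any(),
        lost=lambda s: (s == "loss").any(),
    )
    impacted = per_gene[(per_gene.gained | per_gene.lost)]
    impacted = impacted[
        [labels.get(g) in (GeneLabel.ONC, GeneLabel.TSG) for g in impacted.index]
    ]
    if impacted.empty:
        raise ValueError("no CNA-impacted ONC/TSG genes")

    is_onc = np.array([labels[g] is GeneLabel.ONC for g in impacted.index])
    gained_only = (impacted.gained & ~impacted.lost).to_numpy()
    lost_only = (impacted.lost & ~impacted.gained).to_numpy()

    results = {}
    for name, flag in (("gained_only", gained_only), ("lost_only", lost_only)):
        table = np.array(
            [
                [np.sum(is_onc & flag), np.sum(is_onc & ~flag)],
                [np.sum(~is_onc & flag), np.sum(~is_onc & ~flag)],
            ]
        )
        if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
            results[name] = {"chi2": float("nan"), "p": float("nan"),
                             "continuity_warning": True}
            continue
        chi2, p, _, expected = stats.chi2_contingency(table, correction=yates)
        results[name] = {
            "chi2": float(chi2),
            "p": float(p),
            "continuity_warning": bool((expected < 1).any()),
        }
    return results


# ---------------------------------------------------------------------------
# Boundary orientation permutation test
# ---------------------------------------------------------------------------

@dataclass
class BoundaryPair:
    """Adjacent labelled genes flanking a copy-number boundary.

    ``high_gene``/``low_gene`` are the genes on the higher- and lower-copy
    sides of the boundary (side defined by copy number, not coordinate).
    """

    high_gene: str
    low_gene: str


def boundary_orientation_test(
    pairs: Sequence[BoundaryPair],
    labels: Mapping[str, GeneLabel],
    n_perm: int = 5000,
    seed: int = 0,
) -> Tuple[int, float]:
    """Observed ONC-high/TSG-low pair count and its label-permutation p.

    The null shuffles the ONC/TSG/ND labels over all labelled genes and
    recounts; p is the fraction of permutations with a count >= observed.
    """
    if not pairs:
        logger.warning("no eligible boundary pairs")
        return 0, 1.0
    genes = sorted(labels)
    lab_array = np.array([labels[g].value for g in genes])
    gene_idx = {g: i for i, g in enumerate(genes)}

    def count(lab: np.ndarray) -> int:
        c = 0
        for p in pairs:
            if (
                lab[gene_idx[p.high_gene]] == "ONC"
                and lab[gene_idx[p.low_gene]] == "TSG"
            ):
                c += 1
        return c

    observed = count(lab_array)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm, dtype=int)
    for k in range(n_perm):
        null[k] = count(rng.permutation(lab_array))
    p = float(np.mean(null >= observed))
    return observed, p


def find_boundary_pairs(
    genes: Sequence[GeneRecord],
    segments: Iterable[CnaSegment],
) -> List[BoundaryPair]:
    """Adjacent ONC/TSG gene pairs with different copy numbers in some subline.

    Genes are ordered along each chromosome; consecutive pairs where one is
    ONC and the other TSG are eligible when, in at least one subline, the
    two genes sit at different absolute copy numbers. Each eligible pair is
    counted once (study-level), oriented by which gene had the higher copy
    number in the subline exhibiting the difference.
    """
    by_subline: Dict[str, List[CnaSegment]] = defaultdict(list)
    for seg in segments:
        by_subline[seg.subline].append(seg)

    def cn_of(gene: GeneRecord, segs: List[CnaSegment]) -> Optional[int]:
        for seg in segs:
            if seg.interval.contains(gene.interval):
                return seg.copy_number
        return None

    ordered = sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start))
    out: List[BoundaryPair] = []
    for a, b in zip(ordered, ordered[1:]):
        if a.interval.chrom != b.interval.chrom:
            continue
        pair_labels = {a.label, b.label}
        if pair_labels != {GeneLabel.ONC, GeneLabel.TSG}:
            continue
        for subline, segs in by_subline.items():
            ca, cb = cn_of(a, segs), cn_of(b, segs)
            if ca is None or cb is None or ca == cb:
                continue
            high, low = (a, b) if ca > cb else (b, a)
            out.append(BoundaryPair(high_gene=high.gene, low_gene=low.gene))
            break  # count each adjacent pair once at study level
    return out


# ---------------------------------------------------------------------------
# Copy-neutral LOH timing
# ---------------------------------------------------------------------------

@dataclass
class LohCounts:
    """Clonal SNV counts on the LOH chromosome.

    homozygous_clonal: clonal SNVs with (median) VAF 1 across sublines —
    acquired before the event on the retained haplotype.
    total_clonal: all observed clonal SNVs on the chromosome.
    """

    homozygous_clonal: int
    total_clonal: int

    def __post_init__(self) -> None:
        if self.homozygous_clonal > self.total_clonal:
            raise ValueError("homozygous count exceeds total")


def cn_loh_timing(counts: LohCounts, scenario: str = "loh_then_duplication") -> float:
    """Fraction of the trunk elapsed before the copy-neutral LOH event.

    Scenario "loh_then_duplication": at most 2H SNVs predate the
    duplication (H observed homozygous plus as many unobserved on the lost
    copy); the denominator adds those unobserved SNVs: 2H / (C + H).

    Scenario "nondisjunction_then_loh": 2H SNVs predate nondisjunction; the
    C - H heterozygous clonal SNVs arose after, already normalized to two
    copies: 2H / (2H + (C - H)).

    Both scenarios reduce to the same fraction for every valid count pair.
    """
    H, C = counts.homozygous_clonal, counts.total_clonal
    if C <= 0:
        raise ValueError("total_clonal must be positive")
    if scenario == "loh_then_duplication":
        return 2 * H / (C + H)
    if scenario == "nondisjunction_then_loh":
        return 2 * H / (2 * H + (C - H))
    raise ValueError(f"unknown scenario: {scenario}")
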