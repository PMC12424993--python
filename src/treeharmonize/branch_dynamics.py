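"""Branch-level analytics over placed variants.

Covers mutational-signature timing (per-mutation signature labels from
externally fitted per-subline probabilities, aggregated over the subtree
below the mutation's branch), cumulative dN/dS along root-to-branch paths,
per-branch SNV/SV count correlation, and ANOVA + Tukey HSD contrasts of
per-branch signature activities across timing classes and clades.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .harmonizer import Placement
from .tree import Phylogeny

logger = logging.getLogger(__name__)

#: default COSMIC sub-signature aggregation (SBS7a-d -> SBS7, SBS17a/b -> SBS17)
DEFAULT_AGGREGATE_GROUPS: Dict[str, str] = {
    "SBS7a": "SBS7",
    "SBS7b": "SBS7",
    "SBS7c": "SBS7",
    "SBS7d": "SBS7",
    "SBS17a": "SBS17",
    "SBS17b": "SBS17",
}


@dataclass
class SignatureProbTable:
    """Per-(mutation, subline) probability vectors over signature names.

    ``probs[(mutation_id, subline)]`` is a mapping signature -> probability;
    each row sums to 1 (tolerance 1e-6).
    """

    probs: Dict[Tuple[str, str], Dict[str, float]]

    def __post_init__(self) -> None:
        for key, row in self.probs.items():
            total = sum(row.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"probability row {key} sums to {total}")

    @classmethod
    def from_tsv(cls, path: str) -> "SignatureProbTable":
        df = pd.read_csv(path, sep="\t")
        probs: Dict[Tuple[str, str], Dict[str, float]] = defaultdict(dict)
        for r in df.itertuples():
            probs[(str(r.mutation_id), str(r.subline))][str(r.signature)] = float(
                r.probability
            )
        return cls(dict(probs))

    def to_tsv(self, path: str) -> None:
        rows = [
            (m, s, sig, p)
            for (m, s), row in sorted(self.probs.items())
            for sig, p in sorted(row.items())
        ]
        pd.DataFrame(
            rows, columns=["mutation_id", "subline", "signature", "probability"]
        ).to_csv(path, sep="\t", index=False)


def assign_branch_signatures(
    placements: Iterable[Placement],
    probs: SignatureProbTable,
    tree: Phylogeny,
) -> Dict[str, str]:
    """Most probable signature per placed mutation.

    The probability vectors of the sublines in the subtree below the
    mutation's branch are summed and the argmax taken (ties break by
    signature name order). Mutations with no probability rows get "NA".
    """
    rows_by_mutation: Dict[str, Dict[str, Dict[str, float]]] = defaultdict(dict)
    for (mid, subline), row in probs.probs.items():
        rows_by_mutation[mid][subline] = row

    labels: Dict[str, str] = {}
    for p in placements:
        if not p.placed:
            continue
        sub_rows = rows_by_mutation.get(p.variant_id, {})
        carriers = tree.leaves_below(p.assigned_node)
        total: Dict[str, float] = defaultdict(float)
        for subline in carriers:
            for sig, prob in sub_rows.get(subline, {}).items():
                total[sig] += prob
        if not total:
            logger.warning("no signature probabilities for %s", p.variant_id)
            labels[p.variant_id] = "NA"
            continue
        labels[p.variant_id] = min(total, key=lambda s: (-total[s], s))
    return labels


@dataclass
class BranchActivity:
    node: str
    activities: Dict[str, float]
    mutation_count: int


def branch_activity(
    labels: Mapping[str, str],
    placements: Iterable[Placement],
    aggregate_groups: Optional[Mapping[str, str]] = None,
) -> Dict[str, BranchActivity]:
    """Per-branch signature activity = labelled-mutation proportions."""
    groups = DEFAULT_AGGREGATE_GROUPS if aggregate_groups is None else aggregate_groups
    counts: Dict[str, Dict[str, int]] = defaultdict(lambda: defaultdict(int))
    totals: Dict[str, int] = defaultdict(int)
    for p in placements:
        if not p.placed or p.variant_id not in labels:
            continue
        sig = labels[p.variant_id]
        sig = groups.get(sig, sig)
        counts[p.assigned_node][sig] += 1
        totals[p.assigned_node] += 1
    out = {}
    for node, total in totals.items():
        out[node] = BranchActivity(
            node=node,
            activities={s: c / total for s, c in sorted(counts[node].items())},
            mutation_count=total,
        )
    return out


# ---------------------------------------------------------------------------
# dN/dS and branch counts
# ---------------------------------------------------------------------------

@dataclass
class SiteCounts:
    """Genome-wide counts of synonymous and non-synonymous sites."""

    synonymous_sites: int
    nonsynonymous_sites: int

    def __post_init__(self) -> None:
        if self.synonymous_sites <= 0 or self.nonsynonymous_sites <= 0:
            raise ValueError("site counts must be positive")


@dataclass
class BranchCounts:
    node: str
    snv_count: int = 0
    sv_count: int = 0
    cumulative_snv_count: int = 0
    cumulative_sv_count: int = 0
    nonsyn_count: int = 0  # cumulative from trunk through this branch
    syn_count: int = 0


def cumulative_dnds(counts: BranchCounts, sites: SiteCounts) -> float:
    """dN/dS = (cumulative nonsyn / cumulative syn) x (syn sites / nonsyn sites).

    Returns NaN when no synonymous SNVs have accumulated (undefined ratio);
    zero nonsynonymous counts give 0.
    """
    if counts.syn_count == 0:
        return float("nan")
    return (counts.nonsyn_count / counts.syn_count) * (
        sites.synonymous_sites / sites.nonsynonymous_sites
    )


def compute_branch_counts(
    snv_placements: Iterable[Placement],
    sv_placements: Iterable[Placement],
    tree: Phylogeny,
    consequences: Optional[Mapping[str, str]] = None,
) -> Dict[str, BranchCounts]:
    """Per-branch and root-path-cumulative variant counts.

    ``consequences`` maps variant_id -> {"synonymous","nonsynonymous",...};
    unknown variants contribute to totals but not to dN/dS counts.
    """
    counts = {node: BranchCounts(node=node) for node in tree.nodes()}
    syn_local: Dict[str, int] = defaultdict(int)
    nonsyn_local: Dict[str, int] = defaultdict(int)
    for p in snv_placements:
        if not p.placed:
            continue
        counts[p.assigned_node].snv_count += 1
        if consequences:
            c = consequences.get(p.variant_id)
            if c == "synonymous":
                syn_local[p.assigned_node] += 1
            elif c == "nonsynonymous":
                nonsyn_local[p.assigned_node] += 1
    for p in sv_placements:
        if p.placed:
            counts[p.assigned_node].sv_count += 1

    for node in tree.level_order():
        path = tree.path_from_root(node)
        bc = counts[node]
        bc.cumulative_snv_count = sum(counts[n].snv_count for n in path)
        bc.cumulative_sv_count = sum(counts[n].sv_count for n in path)
        bc.syn_count = sum(syn_local[n] for n in path)
        bc.nonsyn_count = sum(nonsyn_local[n] for n in path)
    return counts


def branch_count_correlation(
    branch_counts: Mapping[str, BranchCounts],
) -> Tuple[float, float]:
    """Pearson r (and p) between per-branch SNV and SV counts."""
    nodes = sorted(branch_counts)
    if len(nodes) < 3:
        raise ValueError("need >= 3 branches for a correlation")
    x = np.array([branch_counts[n].snv_count for n in nodes], dtype=float)
    y = np.array([branch_counts[n].sv_count for n in nodes], dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Group contrasts
# ---------------------------------------------------------------------------

def branch_group_tests(
    values: Mapping[str, float],
    group_labels: Mapping[str, Optional[str]],
) -> pd.DataFrame:
    """One-way ANOVA with post-hoc Tukey HSD over labelled branches.

    ``values`` maps branch -> measurement (e.g. a signature's activity);
    ``group_labels`` maps branch -> group name or None (excluded). Groups
    with fewer than 2 members are suppressed from the pairwise report.
    Returns a DataFrame (group1, group2, meandiff, p_adj) plus attributes
    ``anova_f``/``anova_p`` in ``df.attrs``.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    rows = [
        (b, v, group_labels[b])
        for b, v in values.items()
        if group_labels.get(b) is not None
    ]
    df = pd.DataFrame(rows, columns=["branch", "value", "group"])
    sizes = df.groupby("group").size()
    valid = sizes[sizes >= 2].index
    dropped = set(sizes.index) - set(valid)
    if dropped:
        logger.warning("suppressing singleton groups: %s", sorted(dropped))
    df = df[df["group"].isin(valid)]
    if df["group"].nunique() < 2:
        raise ValueError("need >= 2 groups with >= 2 branches each")

    grouped = [g["value"].to_numpy() for _, g in df.groupby("group")]
    f, p = stats.f_oneway(*grouped)

    if np.allclose(df["value"].var(ddof=1), 0):
        # identical values in every group: every contrast is null
        pairs = []
        names = sorted(df["group"].unique())
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                pairs.append((names[i], names[j], 0.0, 1.0))
        out = pd.DataFrame(pairs, columns=["group1", "group2", "meandiff", "p_adj"])
    else:
        tk = pairwise_tukeyhsd(df["value"].to_numpy(), df["group"].to_numpy())
        data = tk._results_table.data
        out = pd.DataFrame(data[1:], columns=data[0])[
            ["group1", "group2", "meandiff", "p-adj"]
        ].rename(columns={"p-adj": "p_adj"})
    out.attrs["anova_f"] = float(f)
    out.attrs["anova_p"] = float(p)
    return out
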