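"""Subclone-specific differential methylation analysis.

Per-CpG modified/total read counts per subline are smoothed with a
coverage-weighted tricube kernel over a fixed genomic window, per-CpG
signal-to-noise t statistics are computed between the case/control
bipartition a tree branch induces, and differentially methylated regions
(DMRs) are maximal runs of consecutive CpGs whose statistics fall in the
extreme empirical-quantile tails with a sufficient group mean difference.

Two permutation tests accompany the calling: one on the number of DMRs at a
branch under random case/control bipartitions of the sublines, and one on
the number of genes with monotonic methylation trajectories along a linear
(caterpillar) clade, under permuted subline orderings sampled from
equivalence classes induced by sibling swaps and order reversal.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .variants import GenomicInterval

logger = logging.getLogger(__name__)


@dataclass
class MethylMatrix:
    """CpG-by-subline modified and total read counts.

    ``sites`` are (chrom, pos) with 0-based positions; ``n_mod`` and
    ``n_total`` are DataFrames indexed by site (MultiIndex) with one column
    per subline.
    """

    sites: List[Tuple[str, int]]
    sublines: List[str]
    n_mod: pd.DataFrame
    n_total: pd.DataFrame

    def __post_init__(self) -> None:
        if ((self.n_mod < 0) | (self.n_mod > self.n_total)).any().any():
            raise ValueError("need 0 <= n_mod <= n_total")

    @classmethod
    def from_tsv(cls, path: str) -> "MethylMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        piv_mod = df.pivot_table(
            index=["chrom", "pos"], columns="subline", values="n_mod"
        ).sort_index()
        piv_tot = df.pivot_table(
            index=["chrom", "pos"], columns="subline", values="n_total"
        ).sort_index()
        sublines = sorted(piv_mod.columns)
        sites = list(piv_mod.index)
        return cls(sites, sublines, piv_mod[sublines], piv_tot[sublines])

    def to_tsv(self, path: str) -> None:
        rows = []
        for (chrom, pos) in self.sites:
            for s in self.sublines:
                rows.append(
                    (chrom, pos, s,
                     int(self.n_mod.loc[(chrom, pos), s]),
                     int(self.n_total.loc[(chrom, pos), s]))
                )
        pd.DataFrame(
            rows, columns=["chrom", "pos", "subline", "n_mod", "n_total"]
        ).to_csv(path, sep="\t", index=False)


@dataclass
class DmrParams:
    min_cov: int = 3
    min_cpgs: int = 10
    t_quantile_low: float = 0.025
    t_quantile_high: float = 0.975
    min_meandiff: float = 0.2
    smoothing_window: int = 1000  # bp

    def __post_init__(self) -> None:
        if not 0 < self.t_quantile_low < self.t_quantile_high < 1:
            raise ValueError("quantiles must satisfy 0 < low < high < 1")


@dataclass
class DmrRecord:
    interval: GenomicInterval
    n_cpgs: int
    mean_diff: float  # case minus control
    direction: str  # "hyper" | "hypo"
    branch: Optional[str] = None


# ---------------------------------------------------------------------------
# Smoothing and per-CpG statistics
# ---------------------------------------------------------------------------

def smooth_methylation(
    matrix: MethylMatrix, params: DmrParams = DmrParams()
) -> pd.DataFrame:
    """Coverage-weighted tricube-kernel local mean of methylation fractions.

    Sites with coverage below ``min_cov`` in any subline are dropped first.
    The kernel weight of neighbor j for site i is
    cov_j * (1 - |d_ij/h|^3)^3 with h = smoothing_window; an isolated site
    keeps its raw fraction. Values stay in [0, 1].
    """
    cov_ok = (matrix.n_total >= params.min_cov).all(axis=1)
    mod = matrix.n_mod[cov_ok]
    tot = matrix.n_total[cov_ok]
    if mod.empty:
        return pd.DataFrame(columns=matrix.sublines)

    frac = (mod / tot).to_numpy(dtype=float)
    cov = tot.to_numpy(dtype=float)
    chroms = mod.index.get_level_values(0).to_numpy()
    pos = mod.index.get_level_values(1).to_numpy()

    h = float(params.smoothing_window)
    out = np.empty_like(frac)
    start = 0
    n = len(pos)
    for i in range(n):
        # window of neighbors on the same chromosome within h bp
        lo = i
        while lo > 0 and chroms[lo - 1] == chroms[i] and pos[i] - pos[lo - 1] <= h:
            lo -= 1
        hi = i
        while hi + 1 < n and chroms[hi + 1] == chroms[i] and pos[hi + 1] - pos[i] <= h:
            hi += 1
        d = np.abs(pos[lo : hi + 1] - pos[i]) / h
        w = cov[lo : hi + 1] * ((1 - d**3) ** 3)[:, None]
        wsum = w.sum(axis=0)
        out[i] = (w * frac[lo : hi + 1]).sum(axis=0) / wsum
    return pd.DataFrame(out, index=mod.index, columns=mod.columns)


def cpg_t_statistics(
    smoothed: pd.DataFrame,
    case: Sequence[str],
    control: Sequence[str],
) -> pd.DataFrame:
    """Per-CpG signal-to-noise t statistic with empirical quantile ranks.

    t(i) = (mean_case - mean_control) / (pooled_sd(i) + sd_floor), where
    sd_floor is the genome-wide 75th percentile of the pooled standard
    deviation (a variance floor against near-zero local noise estimates).
    Returns columns ``t``, ``rank`` (empirical quantile in (0, 1]) and
    ``diff``.
    """
    case, control = list(case), list(control)
    if len(case) < 2 or len(control) < 2:
        raise ValueError("case and control groups both need >= 2 sublines")
    a = smoothed[case].to_numpy(dtype=float)
    b = smoothed[control].to_numpy(dtype=float)
    diff = a.mean(axis=1) - b.mean(axis=1)
    n1, n2 = len(case), len(control)
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    pooled = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    floor = float(np.percentile(pooled, 75))
    denom = pooled + floor
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0),
                     np.sign(diff) * np.inf)
    t = np.where((denom == 0) & (diff == 0), 0.0, t)
    rank = stats.rankdata(t, method="average") / len(t)
    return pd.DataFrame(
        {"t": t, "rank": rank, "diff": diff}, index=smoothed.index
    )


def call_dmrs(
    tstats: pd.DataFrame,
    params: DmrParams = DmrParams(),
    branch: Optional[str] = None,
) -> List[DmrRecord]:
    """Maximal same-sign runs of extreme-rank CpGs passing length/effect cuts."""
    qualifies = (
        (tstats["rank"] < params.t_quantile_low)
        | (tstats["rank"] > params.t_quantile_high)
    ).to_numpy()
    sign = np.sign(tstats["t"].to_numpy())
    chroms = tstats.index.get_level_values(0).to_numpy()
    pos = tstats.index.get_level_values(1).to_numpy()
    diffs = tstats["diff"].to_numpy()
    n = len(tstats)
    if n == 0 or not qualifies.any():
        return []

    # vectorized maximal-run detection: a run breaks at the start of the
    # array, at a non-qualifying site, on a sign flip, or a chromosome change
    brk = np.ones(n, dtype=bool)
    brk[1:] = (
        ~qualifies[:-1]
        | (sign[1:] != sign[:-1])
        | (chroms[1:] != chroms[:-1])
    )
    run_id = np.cumsum(brk) - 1
    out: List[DmrRecord] = []
    q_idx = np.flatnonzero(qualifies)
    # boundaries of each qualifying run
    q_runs = run_id[q_idx]
    starts = q_idx[np.r_[True, q_runs[1:] != q_runs[:-1]]]
    ends = q_idx[np.r_[q_runs[1:] != q_runs[:-1], True]]
    csum = np.concatenate([[0.0], np.cumsum(diffs)])
    for i, j in zip(starts, ends):
        n_cpgs = int(j - i + 1)
        mean_diff = float((csum[j + 1] - csum[i]) / n_cpgs)
        if n_cpgs >= params.min_cpgs and abs(mean_diff) >= params.min_meandiff:
            out.append(
                DmrRecord(
                    interval=GenomicInterval(chroms[i], int(pos[i]), int(pos[j]) + 1),
                    n_cpgs=n_cpgs,
                    mean_diff=mean_diff,
                    direction="hyper" if mean_diff > 0 else "hypo",
                    branch=branch,
                )
            )
    return out


def dmr_pipeline(
    matrix: MethylMatrix,
    case: Sequence[str],
    control: Sequence[str],
    params: DmrParams = DmrParams(),
    smoothed: Optional[pd.DataFrame] = None,
    branch: Optional[str] = None,
) -> List[DmrRecord]:
    """Smooth (once), compute statistics for the bipartition, call DMRs."""
    if smoothed is None:
        smoothed = smooth_methylation(matrix, params)
    if smoothed.empty:
        return []
    tstats = cpg_t_statistics(smoothed, case, control)
    return call_dmrs(tstats, params, branch=branch)


# ---------------------------------------------------------------------------
# DMR-count permutation test
# ---------------------------------------------------------------------------

def dmr_count_permutation_test(
    matrix: MethylMatrix,
    case_size: int,
    observed_count: int,
    n_perm: int = 1000,
    seed: int = 0,
    params: DmrParams = DmrParams(),
    sublines: Optional[Sequence[str]] = None,
) -> Tuple[float, List[int]]:
    """p-value for the observed DMR count under random bipartitions.

    All distinct case assignments of the given size are enumerated when
    there are at most ``n_perm`` of them (e.g. all 253 for case size 2 over
    23 sublines); otherwise ``n_perm`` distinct assignments are sampled.
    p is the literal fraction of null counts >= observed (no add-one).
    Returns (p, null_counts).
    """
    sublines = list(sublines if sublines is not None else matrix.sublines)
    if not 2 <= case_size <= len(sublines) - 2:
        raise ValueError("case_size must leave >= 2 sublines on each side")
    from math import comb

    total = comb(len(sublines), case_size)
    smoothed = smooth_methylation(matrix, params)
    if total <= n_perm:
        assignments: Iterable[Tuple[str, ...]] = itertools.combinations(
            sublines, case_size
        )
    else:
        rng = np.random.default_rng(seed)
        chosen: Set[Tuple[str, ...]] = set()
        while len(chosen) < n_perm:
            pick = tuple(sorted(rng.choice(sublines, size=case_size, replace=False)))
            chosen.add(pick)
        assignments = sorted(chosen)

    null_counts = []
    for case in assignments:
        control = [s for s in sublines if s not in case]
        dmrs = dmr_pipeline(matrix, list(case), control, params, smoothed=smoothed)
        null_counts.append(len(dmrs))
    p = float(np.mean([c >= observed_count for c in null_counts]))
    return p, null_counts


# ---------------------------------------------------------------------------
# Monotonic trajectories along a caterpillar clade
# ---------------------------------------------------------------------------

def caterpillar_cuts(ordering: Sequence[str]) -> List[Tuple[List[str], List[str]]]:
    """Nested suffix case groups along a linear clade.

    For a clade of size k the case groups are the order suffixes of sizes
    k-3 down to 2, each tested against the remaining clade members (both
    sides must have >= 2 sublines, hence k >= 4).
    """
    k = len(ordering)
    if k < 4:
        raise ValueError("caterpillar cuts need a clade of >= 4 sublines")
    cuts = []
    for size in range(max(k - 3, 2), 1, -1):
        case = list(ordering[k - size :])
        control = list(ordering[: k - size])
        cuts.append((case, control))
    return cuts


def merge_intervals(intervals: Iterable[GenomicInterval]) -> List[GenomicInterval]:
    """Union of intervals with overlapping (or touching) spans merged."""
    out: List[GenomicInterval] = []
    for iv in sorted(intervals):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            out[-1] = GenomicInterval(iv.chrom, out[-1].start, max(out[-1].end, iv.end))
        else:
            out.append(iv)
    return out


@dataclass
class TrajectoryResult:
    region: GenomicInterval
    max_abs_tau: float
    best_ordering: Tuple[str, ...]
    gene: Optional[str] = None


def admissible_orderings(
    base: Sequence[str], swappable_pairs: Sequence[Tuple[int, int]]
) -> List[Tuple[str, ...]]:
    """Base ordering plus every combination of sibling-pair swaps."""
    orderings = [tuple(base)]
    for pair_subset in range(1, 2 ** len(swappable_pairs)):
        o = list(base)
        for k, (i, j) in enumerate(swappable_pairs):
            if pair_subset >> k & 1:
                o[i], o[j] = o[j], o[i]
        orderings.append(tuple(o))
    return orderings


def mann_kendall_max_tau(
    values: Mapping[str, float],
    orderings: Sequence[Sequence[str]],
    region: Optional[GenomicInterval] = None,
) -> TrajectoryResult:
    """Kendall tau-b of values against each admissible ordering; max |tau|.

    ``values`` maps subline -> region methylation level; each ordering is a
    sequence of sublines. Ties are handled by the tau-b denominator.
    """
    if len(next(iter(orderings))) < 3:
        raise ValueError("need >= 3 values for a trend test")
    best_tau = 0.0
    best_ord = tuple(orderings[0])
    for o in orderings:
        v = [values[s] for s in o]
        tau, _ = stats.kendalltau(range(len(v)), v)
        if np.isnan(tau):
            tau = 0.0
        if abs(tau) > abs(best_tau):
            best_tau, best_ord = float(tau), tuple(o)
    return TrajectoryResult(
        region=region
        if region is not None
        else GenomicInterval("NA", 0, 1),
        max_abs_tau=abs(best_tau),
        best_ordering=best_ord,
    )


def kendall_to_pearson(tau: float) -> float:
    """Bivariate-normal conversion r = sin(pi * tau / 2) (Greiner's relation).

    Used to justify the |tau| >= 0.7 trajectory threshold: tau = 0.7
    corresponds to a Pearson correlation of about 0.9.
    """
    return float(np.sin(np.pi * tau / 2))


# ---------------------------------------------------------------------------
# Ordering equivalence classes
# ---------------------------------------------------------------------------

def ordering_equivalence_classes(
    labels: Sequence[str],
    swappable_pairs: Sequence[Tuple[int, int]] = (),
) -> List[List[Tuple[str, ...]]]:
    """Partition all orderings of ``labels`` into statistic-equivalence classes.

    Two orderings are equivalent when one is obtained from the other by
    swapping the entries at a swappable sibling-pair position, by reversing
    the whole ordering, or by any composition of these. Classes are orbit
    closures under the generated group. With two sibling pairs placed
    mirror-symmetrically in an 8-leaf clade each orbit has 8 members,
    giving 8!/8 = 7! classes.
    """
    n = len(labels)
    if n > 10:
        raise ValueError("exhaustive enumeration limited to <= 10 leaves")

    def neighbors(o: Tuple[str, ...]) -> List[Tuple[str, ...]]:
        out = [tuple(reversed(o))]
        for (i, j) in swappable_pairs:
            lo = list(o)
            lo[i], lo[j] = lo[j], lo[i]
            out.append(tuple(lo))
        return out

    seen: Set[Tuple[str, ...]] = set()
    classes: List[List[Tuple[str, ...]]] = []
    for perm in itertools.permutations(labels):
        if perm in seen:
            continue
        orbit = {perm}
        frontier = [perm]
        while frontier:
            cur = frontier.pop()
            for nb in neighbors(cur):
                if nb not in orbit:
                    orbit.add(nb)
                    frontier.append(nb)
        seen |= orbit
        classes.append(sorted(orbit))
    return classes


def sample_orderings(
    classes: List[List[Tuple[str, ...]]],
    n_perm: int,
    seed: int,
) -> List[Tuple[str, ...]]:
    """Seeded draw of <= 1 representative ordering from each of n_perm classes."""
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(classes))[: min(n_perm, len(classes))]
    return [classes[i][rng.integers(len(classes[i]))] for i in idx]


def count_monotonic_genes(
    region_values: pd.DataFrame,
    region_genes: Mapping[int, Set[str]],
    ordering: Sequence[str],
    swappable_pairs: Sequence[Tuple[int, int]],
    tau_threshold: float = 0.7,
) -> int:
    """Genes whose regions show |tau| >= threshold along the ordering.

    ``region_values`` is regions x sublines (region-mean smoothed methylation);
    ``region_genes`` maps row position -> gene names overlapping the region.
    """
    orderings = admissible_orderings(ordering, swappable_pairs)
    genes: Set[str] = set()
    for row_idx in range(len(region_values)):
        values = region_values.iloc[row_idx].to_dict()
        res = mann_kendall_max_tau(values, orderings)
        if res.max_abs_tau >= tau_threshold:
            genes |= region_genes.get(row_idx, set())
    return len(genes)


def trajectory_permutation_test(
    region_values: pd.DataFrame,
    region_genes: Mapping[int, Set[str]],
    observed_gene_count: int,
    base_ordering: Sequence[str],
    swappable_pairs: Sequence[Tuple[int, int]],
    n_perm: int = 1000,
    seed: int = 0,
    tau_threshold: float = 0.7,
) -> Tuple[float, List[int]]:
    """p-value for the number of monotonic-trajectory genes.

    Orderings are sampled (<= 1 per equivalence class) and the gene count
    recomputed for each; p is the fraction of permuted counts >= observed.
    """
    classes = ordering_equivalence_classes(list(base_ordering), swappable_pairs)
    sampled = sample_orderings(classes, n_perm, seed)
    null_counts = [
        count_monotonic_genes(
            region_values, region_genes, o, swappable_pairs, tau_threshold
        )
        for o in sampled
    ]
    p = float(np.mean([c >= observed_gene_count for c in null_counts]))
    return p, null_counts
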