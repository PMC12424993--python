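"""SNV filter cascade producing the tree-building genotype matrix.

Raw per-subline somatic SNV calls are noisy: sites inside copy-number
losses violate the infinite-sites assumption, low-coverage sites cannot be
genotyped reliably, and sites with diffuse low-level alt support in "absent"
sublines are usually artifacts. The cascade below removes these, in a fixed
order, and reports a per-rule audit so the cost of each rule is visible.

Rule order:
  1. drop sites overlapping a loss region in at least one subline
  2. drop private (one carrier) and clonal (all carriers) sites
  3. set status to "missing" where site depth <= missing_cov_max
  4. drop sites whose mean/median depth across sublines < site_cov_min
  5. drop sites whose mean/median VAF over carriers < vaf_min
  6. drop sites with alt support in >= absent_alt_fraction of absent sublines

For rules 4 and 5 "mean or median below threshold" defaults to the
permissive reading (drop only when BOTH are below); ``filter_logic="either"``
gives the strict reading.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .variants import GenomicInterval, LossRegion, SnvCall, VariantStatus

logger = logging.getLogger(__name__)

SiteKey = Tuple[str, int, str, str]  # chrom, 1-based pos, ref, alt


@dataclass
class SiteFilterParams:
    """Thresholds of the filter cascade.

    missing_cov_max: depth at or below which a call becomes "missing" (<=10)
    site_cov_min: minimum mean/median site depth across sublines (20)
    vaf_min: minimum mean/median VAF over carrier sublines (1/3)
    absent_alt_fraction: fraction of absent sublines with alt support at
        which a site is discarded (1/2)
    filter_logic: "both" drops when mean AND median fall below the
        threshold; "either" drops when either does
    """

    missing_cov_max: int = 10
    site_cov_min: int = 20
    vaf_min: float = 1.0 / 3.0
    absent_alt_fraction: float = 0.5
    filter_logic: str = "both"

    def __post_init__(self) -> None:
        if not 0 < self.vaf_min < 1:
            raise ValueError("vaf_min must be in (0,1)")
        if self.filter_logic not in ("both", "either"):
            raise ValueError("filter_logic must be 'both' or 'either'")


@dataclass
class GenotypeMatrix:
    """Site x subline genotype matrix with depth companions."""

    sites: List[SiteKey]
    sublines: List[str]
    entries: pd.DataFrame  # values in {"present","absent","missing"}
    depth: pd.DataFrame
    alt_depth: pd.DataFrame

    def __post_init__(self) -> None:
        for df in (self.entries, self.depth, self.alt_depth):
            assert df.shape == (len(self.sites), len(self.sublines))

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def _summaries_fail(mean: float, median: float, thresh: float, logic: str) -> bool:
    if logic == "both":
        return mean < thresh and median < thresh
    return mean < thresh or median < thresh


def prepare_tree_snvs(
    calls: Iterable[SnvCall],
    loss_regions: Iterable[LossRegion],
    params: SiteFilterParams = SiteFilterParams(),
    sublines: Optional[Sequence[str]] = None,
    default_depth: int = 30,
) -> Tuple[GenotypeMatrix, Dict[str, int]]:
    """Run the filter cascade and return the matrix plus per-rule counts.

    ``calls`` may contain explicit "absent" records carrying depth/alt-depth
    observed at the site; sublines without any record at a site are absent
    with ``default_depth`` and zero alt support.
    """
    calls = list(calls)
    if sublines is None:
        sublines = sorted({c.subline for c in calls})
    sublines = list(sublines)
    audit = {f"rule{i}_removed": 0 for i in (1, 2, 4, 5, 6)}
    audit["rule3_set_missing"] = 0

    if not calls:
        empty = pd.DataFrame(index=[], columns=sublines)
        return GenotypeMatrix([], sublines, empty, empty.copy(), empty.copy()), audit

    site_keys = sorted({c.key for c in calls})
    idx = pd.MultiIndex.from_tuples(site_keys, names=["chrom", "pos", "ref", "alt"])
    status = pd.DataFrame("absent", index=idx, columns=sublines)
    depth = pd.DataFrame(float(default_depth), index=idx, columns=sublines)
    alt = pd.DataFrame(0.0, index=idx, columns=sublines)
    for c in calls:
        status.loc[c.key, c.subline] = (
            "present" if c.status is VariantStatus.PRESENT else c.status.value
        )
        depth.loc[c.key, c.subline] = float(c.depth)
        alt.loc[c.key, c.subline] = float(c.alt_depth)

    n0 = len(status)

    # Rule 1: loss-overlapping sites (pooled losses over all sublines)
    losses = [l.interval for l in loss_regions]
    if losses:
        pos0 = status.index.get_level_values("pos") - 1
        chroms = status.index.get_level_values("chrom")
        hit = np.zeros(len(status), dtype=bool)
        for r in losses:
            hit |= (chroms == r.chrom) & (pos0 >= r.start) & (pos0 < r.end)
        audit["rule1_removed"] = int(hit.sum())
        status, depth, alt = status[~hit], depth[~hit], alt[~hit]

    # Rule 2: uninformative (private or clonal) sites
    n_present = (status == "present").sum(axis=1)
    keep = (n_present > 1) & (n_present < len(sublines))
    audit["rule2_removed"] = int((~keep).sum())
    status, depth, alt = status[keep], depth[keep], alt[keep]

    # Rule 3: per-entry missing status at low depth (inclusive threshold)
    low = depth <= params.missing_cov_max
    audit["rule3_set_missing"] = int(low.values.sum())
    status = status.mask(low, "missing")

    # Rule 4: consistently low-coverage sites (missing entries included)
    if len(status):
        mean_d = depth.mean(axis=1)
        med_d = depth.median(axis=1)
        drop4 = pd.Series(
            [
                _summaries_fail(m, md, params.site_cov_min, params.filter_logic)
                for m, md in zip(mean_d, med_d)
            ],
            index=status.index,
        )
        audit["rule4_removed"] = int(drop4.sum())
        status, depth, alt = status[~drop4], depth[~drop4], alt[~drop4]

    # Rule 5: low VAF over carrier sublines (missing entries excluded)
    if len(status):
        vaf = (alt / depth.replace(0, np.nan)).where(status == "present")
        mean_v = vaf.mean(axis=1)
        med_v = vaf.median(axis=1)
        drop5 = pd.Series(
            [
                not np.isnan(m)
                and _summaries_fail(m, md, params.vaf_min, params.filter_logic)
                for m, md in zip(mean_v, med_v)
            ],
            index=status.index,
        )
        audit["rule5_removed"] = int(drop5.sum())
        status, depth, alt = status[~drop5], depth[~drop5], alt[~drop5]

    # Rule 6: alt support in too many absent sublines
    if len(status):
        absent = status == "absent"
        n_absent = absent.sum(axis=1)
        n_support = (absent & (alt >= 1)).sum(axis=1)
        with np.errstate(invalid="ignore"):
            frac = n_support / n_absent.replace(0, np.nan)
        drop6 = (frac >= params.absent_alt_fraction).fillna(False)
        audit["rule6_removed"] = int(drop6.sum())
        status, depth, alt = status[~drop6], depth[~drop6], alt[~drop6]

    matrix = GenotypeMatrix(
        sites=list(status.index),
        sublines=sublines,
        entries=status,
        depth=depth,
        alt_depth=alt,
    )
    logger.info(
        "filter cascade: %d -> %d sites (%s)", n0, matrix.n_sites, audit
    )
    return matrix, audit


#: prior grids for the external tree-search tool's configuration sweep
DEFAULT_FP_PRIORS = (1e-2, 5e-2, 1e-3, 1e-4, 1e-5, 1e-6, 1e-7, 1e-8)
DEFAULT_FN_PRIORS = (0.05, 0.075, 0.1, 0.125, 0.15, 0.175, 0.2)


def tree_search_grid(
    fp_priors: Sequence[float] = DEFAULT_FP_PRIORS,
    fn_priors: Sequence[float] = DEFAULT_FN_PRIORS,
    n_row_permutations: int = 100,
) -> List[Tuple[float, float, int]]:
    """Enumerate the (FP prior, FN prior, row permutation) configurations.

    The external heuristic tree search is run once per configuration and
    the maximum-likelihood tree kept; with the default grids this is
    8 x 7 x 100 = 5,600 configurations.
    """
    return [
        (fp, fn, k)
        for fp in fp_priors
        for fn in fn_priors
        for k in range(n_row_permutations)
    ]


_SYMBOL = {"present": "1", "absent": "0", "missing": "?"}
_SYMBOL_INV = {v: k for k, v in _SYMBOL.items()}


def export_genotype_matrix(matrix: GenotypeMatrix, path: str) -> None:
    """Write the matrix as TSV with entries {0,1,?} in (chrom,pos,alt) order."""
    order = sorted(
        range(matrix.n_sites),
        key=lambda i: (matrix.sites[i][0], matrix.sites[i][1], matrix.sites[i][3]),
    )
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\t" + "\t".join(matrix.sublines) + "\n")
        for i in order:
            chrom, pos, ref, altb = matrix.sites[i]
            row = matrix.entries.iloc[i]
            symbols = "\t".join(_SYMBOL[row[s]] for s in matrix.sublines)
            fh.write(f"{chrom}\t{pos}\t{ref}\t{altb}\t{symbols}\n")


def import_genotype_matrix(path: str) -> GenotypeMatrix:
    """Read a matrix written by :func:`export_genotype_matrix` (statuses only)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    sublines = [c for c in df.columns if c not in ("chrom", "pos", "ref", "alt")]
    sites = [
        (str(r.chrom), int(r.pos), str(r.ref), str(r.alt)) for r in df.itertuples()
    ]
    idx = pd.MultiIndex.from_tuples(sites, names=["chrom", "pos", "ref", "alt"])
    entries = pd.DataFrame(
        [[_SYMBOL_INV[str(df.iloc[i][s])] for s in sublines] for i in range(len(df))],
        index=idx,
        columns=sublines,
    )
    zeros = pd.DataFrame(0.0, index=idx, columns=sublines)
    return GenotypeMatrix(sites, sublines, entries, zeros, zeros.copy())
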