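"""Copy-neutral LOH timing and ONC/TSG selection tests.

LOH timing: with H clonal homozygous SNVs and C total clonal SNVs on the
chromosome, both candidate event orders (loss-then-duplication,
nondisjunction-then-loss) date the event at 2H/(C+H) of the trunk.

Selection: genes fully inside gain/loss segments are scored; chi-square
tests ask whether oncogenes are gained-only and suppressors lost-only, and
a label permutation asks whether oncogenes sit on the high-copy side of
copy-number boundaries more often than chance.
"""

import numpy as np

import treeharmonize as th
from treeharmonize.cna_selection import GeneLabel, GeneRecord, find_boundary_pairs
from treeharmonize.variants import CnaSegment, GenomicInterval

counts = th.LohCounts(homozygous_clonal=100, total_clonal=255)
t1 = th.cn_loh_timing(counts, "loh_then_duplication")
t2 = th.cn_loh_timing(counts, "nondisjunction_then_loh")
print(f"LOH timing: scenario 1 = {t1:.3f}, scenario 2 = {t2:.3f} "
      "(fraction of the trunk elapsed before the event)")

# a toy gene panel where selection is obvious: oncogenes amplified,
# suppressors deleted
rng = np.random.default_rng(0)
genes, segments = [], []
for i in range(12):
    start = i * 100_000
    label = GeneLabel.ONC if i % 2 == 0 else GeneLabel.TSG
    genes.append(GeneRecord(f"gene{i}", GenomicInterval("chr1", start + 10_000,
                                                        start + 20_000), label))
    cn = 3 if label is GeneLabel.ONC else 1
    segments.append(CnaSegment(GenomicInterval("chr1", start, start + 50_000),
                               cn, "S1"))

status = th.gene_cn_status(genes, segments)
res = th.onc_tsg_enrichment_tests(status, genes)
print(f"gained-only enrichment: chi2={res['gained_only']['chi2']:.1f} "
      f"p={res['gained_only']['p']:.4f}")
print(f"lost-only enrichment:   chi2={res['lost_only']['chi2']:.1f} "
      f"p={res['lost_only']['p']:.4f}")

pairs = find_boundary_pairs(genes, segments)
labels = {g.gene: g.label for g in genes}
observed, p = th.boundary_orientation_test(pairs, labels, n_perm=2000, seed=1)
print(f"boundary orientation: {observed}/{len(pairs)} pairs ONC-high, "
      f"permutation p = {p:.4f}")
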