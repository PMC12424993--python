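"""Build a pseudobulk truth set and score a candidate call set.

A pseudobulk mixture of sublines inherits every placed variant carried by
at least one member; clonality-in-mixture and expected VAF follow from the
carrier count. Candidate calls (here: the truth minus its private
variants, to mimic a caller that misses low-VAF events) are scored by
precision/recall per clonality stratum.
"""

import treeharmonize as th
from treeharmonize.benchmark import CandidateVariant, MixClonality, PseudobulkSpec

bundle = th.simulate(th.SimConfig(seed=8, n_snvs=1000))
placements, _ = th.place_all_snvs(
    bundle.snv_calls, bundle.loss_regions, bundle.tree
)
loci = {}
for p in placements:
    chrom, pos, rest = p.variant_id.split(":")
    ref, alt = rest.split(">")
    loci[p.variant_id] = (chrom, int(pos), ref, alt)

spec = PseudobulkSpec("all_sublines", frozenset(bundle.tree.leaf_labels))
truth = th.build_truth_set(placements, spec, bundle.tree, loci=loci)
by_clon = truth.by_clonality()
print(f"truth set '{spec.name}': {len(truth.variants)} variants "
      f"({len(by_clon[MixClonality.CLONAL])} clonal, "
      f"{len(by_clon[MixClonality.SUBCLONAL])} subclonal, "
      f"{len(by_clon[MixClonality.PRIVATE])} private)")

candidate = [
    CandidateVariant("snv", tv.locus[0], tv.locus[1], tv.ref, tv.alt)
    for tv in truth.variants if tv.clonality is not MixClonality.PRIVATE
]
res = th.score_calls(candidate, truth)
print("\nscores for a caller that misses every private variant:")
for stratum in ("overall", "clonal", "subclonal", "private"):
    r = res[stratum]
    print(f"  {stratum:10s} precision={r.precision:.3f} recall={r.recall:.3f}")
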