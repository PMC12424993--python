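"""Time mutational signatures along the tree and compute cumulative dN/dS.

Each placed mutation gets the most probable signature after summing its
per-subline probability vectors over the subtree below its branch; branch
activity is the labelled-mutation proportion. dN/dS at a branch uses the
cumulative nonsynonymous/synonymous counts from the trunk through the
branch, normalized by the genome-wide site ratio.
"""

import treeharmonize as th

bundle = th.simulate(th.SimConfig(seed=7, n_snvs=1500))
placements, _ = th.place_all_snvs(
    bundle.snv_calls, bundle.loss_regions, bundle.tree
)

labels = th.assign_branch_signatures(
    placements, bundle.signature_probs, bundle.tree
)
activities = th.branch_activity(labels, placements)

trunk = activities[bundle.tree.root]
print(f"trunk: {trunk.mutation_count} mutations, activities:")
for sig, act in sorted(trunk.activities.items(), key=lambda kv: -kv[1]):
    print(f"  {sig}: {act:.2f}")
print("(the generator biases trunk mutations toward the UV signature SBS7)")

counts = th.compute_branch_counts(placements, [], bundle.tree,
                                  bundle.consequences)
sites = th.SiteCounts(synonymous_sites=10_000_000, nonsynonymous_sites=30_000_000)
print("\ncumulative dN/dS (site-ratio normalized) along one root-to-leaf path:")
leaf = bundle.tree.leaf_labels[0]
for node in bundle.tree.path_from_root(leaf):
    d = th.cumulative_dnds(counts[node], sites)
    print(f"  {node}: nonsyn={counts[node].nonsyn_count} "
          f"syn={counts[node].syn_count} dN/dS={d:.2f}")
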