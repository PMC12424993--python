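# Methods

This note documents the models, parameter choices and deliberate
approximations behind `treeharmonize`, and what the synthetic-data tests do
and do not establish about real data.

## Tree model

A phylogeny is a rooted, leaf-labelled tree; multifurcations are accepted
since heuristic tree searches can emit polytomies. The trunk (the shared
history of all sublines) is not modeled as an explicit edge: "placed at the
trunk" means placed at the root node. Branches are classified truncal
(root), terminal (leaf) or internal; placements at them are called clonal,
private and subclonal respectively. Coordinates are 0-based half-open
internally, with conversion only at I/O boundaries (VCF is 1-based);
chromosome names are taken verbatim from inputs.

## Support threshold and placement

The clade-support threshold is s\*(c) = max{s : (c−s)/c ≥ f} for clade size
c ≥ 3 and assumed false-negative rate f (default f = 0.15), floored at 1;
clades of size 1–2 require full support. This is the largest support
requirement that still tolerates the expected FN fraction; at c = 3 the
tolerated rate is 1/3, which is accepted deliberately because small clades
are the least stable part of a heuristic tree. At the default false-positive
rate (10⁻⁵) the called carrier set is trusted outright; a leave-one-out
search (`fp_leaveout`) exists but is off by default.

Because s\*(c) is non-decreasing in c, the MRCA of the carriers is the
deepest node that can satisfy both containment and support — placement at
the MRCA is therefore equivalent to a brute-force deepest-satisfying-node
scan, which the tests verify on random trees.

### Regenotyping

The candidate carrier set of an SNV is the called set plus every subline
with a loss region (SV deletion, or copy-number ≤ 1 segment) overlapping
the position — drawn from all sublines, not only the original clade. The
candidate placement is accepted iff (a) the threshold holds at the new
MRCA, (b) no other SNV of a rescued subline is called inside the rescuing
loss span (without phasing, such a call indicates the loss hit the other
haplotype), and (c) the reinclusion rate |added| / |called| is below 1.
The denominator choice (originally called sublines) makes the 100 % cap
meaningful for small called sets: rescuing one subline of a two-carrier
cherry is exactly a 100 % reinclusion and is refused as a dramatic shift.
Rejected rescues revert to the called set and its placement. Accepted
rescues mark the sublines "lost". SVs use the same threshold without
rescue.

## CNA placement

Gains are spans with copy number > 2, losses < 2, relative to a diploid
baseline; adjacent same-direction segments merge per subline, and gains and
losses are processed as disjoint pools. Conceptually the procedure is:
(1) bottom-up, overlapping ranges from different children of a node create
an overlap range (intersection span, union carriers) at the carriers' MRCA;
(2) per branch, ranges meeting the branch's support threshold are kept and
mutually overlapping survivors merge (union span, union carriers); (3)
top-down, spans already attributed to an ancestor are excluded, splitting
ranges, so spans are disjoint along any root-to-leaf path; per-subline
residue lands on terminal branches.

The implementation realizes phases 1–2 with a sweep per node: the subtree's
per-subline ranges are decomposed into atomic intervals with carrier sets;
an atomic belongs to the node when its carriers span ≥ 2 children (their
MRCA is the node) and meet the threshold; contiguous qualifying atomics are
merged back. This is equivalent to the pairwise construction absorbed by
the phase-2 merge, but polynomial — the naive all-pairs closure is
exponential in clade size when a clade shares a range. Parallel events
(the same region altered in different clades through different breakpoints)
survive as separate branch-level ranges because their union never meets the
threshold of the joint ancestor in a tree of realistic size.

## Branch dynamics

Signature labels are assigned per placed mutation as the argmax of the
summed per-subline probability vectors over the subtree below its branch
(summing is equivalent to averaging for the argmax; ties break by signature
name). Branch activity is the labelled-mutation proportion after
aggregating COSMIC sub-signatures (SBS7a–d → SBS7, SBS17a/b → SBS17). Hard
per-mutation labels (not soft probability mass) are used. dN/dS at a
branch is (cumulative nonsynonymous / cumulative synonymous from the trunk
through the branch) × (synonymous sites / nonsynonymous sites); it is
undefined (NaN) until a synonymous variant accumulates. Group contrasts of
per-branch activities use one-way ANOVA with Tukey HSD only (no further
FDR); singleton and unlabeled groups are excluded from the pairwise report.

## Methylation

Smoothing is a coverage-weighted tricube-kernel local mean over a fixed
window (default 1,000 bp), applied after excluding CpGs covered by fewer
than 3 reads in any subline. This is a contract-level stand-in for a local
likelihood smoother: the properties downstream calling depends on —
constant invariance, locality, coverage weighting, values in [0, 1] — are
pinned by tests, but the exact curve differs from likelihood-based
smoothers, so DMR boundaries on real data would differ in detail.

The per-CpG statistic is t = (mean_case − mean_control)/(pooled SD +
floor), with the floor set to the genome-wide 75th percentile of the pooled
SD; "corrected" statistics are genome-wide empirical quantile ranks of t.
DMRs are maximal same-sign runs of CpGs with rank < 0.025 or > 0.975, at
least 10 CpGs long, with |mean smoothed difference| ≥ 0.2. Both groups must
have ≥ 2 sublines.

The DMR-count permutation test enumerates all case assignments of the given
size when there are no more than `n_perm` of them (253 for pairs out of
23), otherwise samples distinct assignments; p is the literal fraction of
null counts ≥ observed, with no add-one term, so p = 0 is attainable.

Monotonic trajectories along a linear clade: candidate regions are the
merged union of DMRs from nested suffix cuts (case sizes k−3 … 2 for a
k-subline clade); each region's per-subline mean smoothed fraction is
tested with Kendall's tau-b over the base ordering and every sibling-pair
swap, keeping the largest |τ|; regions pass at |τ| ≥ 0.7, which corresponds
to a Pearson correlation of ≈ 0.9 under bivariate normality
(r = sin(πτ/2)). The ordering permutation test partitions all orderings
into equivalence classes — orbits under sibling-pair swaps and full
reversal, all of which leave max-|τ| unchanged — and samples at most one
representative per class. With two sibling pairs placed mirror-symmetrically
in an 8-leaf clade the orbits have size 8, giving 8!/8 = 7! = 5,040
classes; the implementation computes orbits generically by closure, so
asymmetric pair placements (which generate larger orbits) are also handled
correctly.

## Selection and LOH timing

Gene copy-number status requires full containment in a non-neutral
segment; boundary-straddling genes stay neutral. The two enrichment tests
are 2×2 chi-square (no Yates correction by default) of label (ONC vs TSG)
against gained-only (gained somewhere, lost nowhere) and lost-only status,
restricted to impacted ONC/TSG genes — the complement category is "not
gained-only" within that set, a choice the data structure leaves open. The
boundary-orientation test counts adjacent ONC/TSG pairs with the ONC on the
higher-copy side (side defined by copy number, not coordinate; each pair
counted once study-wide) and permutes the gene labels.

Copy-neutral LOH timing: with H clonal homozygous and C total clonal SNVs
on the chromosome, both event orders — loss then duplication, or
nondisjunction then loss — give the pre-event fraction 2H/(C+H); the
algebraic identity of the two scenarios is exercised as a test.

## Pseudobulk benchmarking

A mixture's truth set contains every placed variant carried by ≥ 1 member;
"lost" (regenotyped) members do not count as carriers. Clonality in the
mixture is defined by the carrier count (all/exactly one/other) and the
expected VAF is carriers/(2·members) under the heterozygous-diploid model.
Matching is exact for SNVs; SVs match on type with breakends within 50 bp
(insertions also on length within 20 %) — community-convention tolerances,
configurable. Benchmarking is variant-level against externally produced
call sets; read-level mixing is out of scope.

## Synthetic data generator

Defaults emulate the reference study design: 23 sublines in 4 clades
(8-subline caterpillar first, as the linearly differentiating clade), FN
rate 0.15 with half of all FNs caused by deletions, FP rate 10⁻⁵, branch
weights 8 % clonal / 8 % subclonal / 84 % private, heterozygous-diploid
SNVs (depth ~ Poisson(30), alt ~ Binomial(depth, 0.5)) on a 5 × 10 Mb
genome, CNA events bounded by emitted SV breakpoints including one
parallel pair (same region, distinct breakpoints, distinct clades), and
beta-binomial CpG methylation (coverage mean 20, NB dispersion 0.1) with
branch-shifted (effect 0.3) and linearly drifting regions.

Deletion-caused FNs are emitted as small private deletions overlapping the
masked locus, chosen so recovery is well-posed: masking is not applied to
clades of size < 3 and never removes at least as many carriers as remain
called — configurations the reinclusion cap would categorically refuse, by
design of the method, not of the test. Loci of unrelated deletions avoid
SNV positions so that placement accuracy on the bundle is attributable to
the threshold logic; on real data such collisions are precisely what the
parsimony guard and cap adjudicate, and they are exercised by the planted
masks instead. A single global seed fans out to per-component streams, so
adding a component does not reshuffle the others; a fixed seed yields a
byte-identical bundle.

The exchangeable-methylation null generator used for calibration draws
per-subline region means i.i.d. (no group structure) and adds per-subline
idiosyncratic drift regions with an overdispersed (exponential-Poisson)
burden. The overdispersion keeps the null DMR count well spread across
bipartitions; without it the genome-wide quantile cut pins the count to a
near-constant and the discrete permutation p degenerates. Exchangeability
is preserved because all per-subline draws are i.i.d.

## Problem sizes used by tests and the acceptance script

Oracle checks use 1,000 random variants on ≤ 8-leaf trees and 1,000 random
trend vectors. Parameter recovery uses one bundle at the full study design
(23 sublines, 5,000 SNVs). Calibration uses 200 replicates of a
12-subline, 3,600-region null for the DMR test (case pairs, exhaustive
66-assignment null) and 200 replicates of 400 label-shuffled boundary
pairs; the LOH identity is checked on 10,000 random count pairs. The null
is sized so that the discrete permutation p takes many distinct values —
with a narrow null the tie mass of the literal "fraction ≥ observed"
definition makes p conservatively non-uniform no matter how correct the
procedure is. These
sizes keep the whole acceptance run to a few minutes on one CPU while the
Monte-Carlo error of the calibration KS tests stays well below the decision
threshold.

## Known limitations

- The smoother is a kernel average, not a local likelihood fit; absolute
  DMR boundaries on real data will differ from likelihood-based smoothing.
- The phase-1 pair-enumeration order of the CNA procedure is not uniquely
  determined by its description for > 2 mutually overlapping ranges; the
  sweep formulation implemented here is one consistent resolution (the
  phase-2 merge absorbs the ambiguity).
- Signature probabilities are consumed, not fitted; refitting against a
  signature catalog is upstream of this package.
- The generator does not simulate reads, sequence context, or
  haplotype-specific methylation; passing tests demonstrate correctness of
  the algorithms under the stated statistical model, not caller-level
  performance on sequencing data.
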