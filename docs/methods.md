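# Methods

This note documents the models, procedures, parameter choices and known
limitations behind `phyloforge`, in the order data flows through the
toolkit.

## Data model and conventions

Trees are stored rooted; an unrooted tree is a rooted tree with a flagged
arbitrary root, and every operation documented as unrooted-safe first
merges a bifurcating root's two edges so that its result cannot depend on
the arbitrary root placement (verified by rerooting-invariance tests).
Newick internal-node labels are read as bootstrap supports when numeric,
matching common ML-tree output; a reader flag accepts comment-style
supports instead. Sequence ids encode their taxon as the prefix before a
delimiter (default `@`) — the id→taxon rule is a convention of this
package, configurable per `TaxonMap`. Ambiguity characters (`X`, `*`, `?`)
count as gaps for column occupancy and per-sequence character counts.

## Homolog curation

Hit filtering keeps non-self hits with E ≤ 1e−5, percent identity strictly
above 50, and query coverage strictly above 0.7. "Identity" is read as the
reported percent-identity field and coverage as the aligned query span of
the single reported HSP divided by query length; multiple HSPs are not
merged, as no merge rule is defined for the inputs we consume. Clusters
keep sequences of ≥ 40 unaligned amino acids and need ≥ 8 distinct ingroup
taxa.

Long-branch cutting removes every branch above the cutoff and returns the
connected components. Because suppressing the resulting degree-2 nodes
merges branch lengths additively, a merge can create a new over-cutoff
branch; cutting therefore iterates to a fixed point, so no returned tree
retains a branch above the cutoff under any input rooting. The cascade
runs at 2.0 (iterated with re-inference via a pluggable hook), then 0.5,
and 0.6 on the final tree. Components failing the ingroup-taxon filter
after a cut are discarded with a logged reason. The ≥ 8-taxon filter is
re-applied after each cutting round (before re-inference); whether that
re-check precedes or follows realignment makes no difference at the tree
level, which is what this package operates on.

Spurious-tip removal deletes tips whose terminal branch exceeds 0.2
substitutions/site *and* exceeds 10× their sister's length. A sister tip
contributes its branch length; a sister subtree contributes its stem plus
its stepwise-average depth (a `sister_mode="tip"` flag restricts the test
to tip sisters). At polytomies the largest sibling measure is used, so a
tip is removed only when it dwarfs every sibling — the conservative
reading.

Isoform masking reduces each maximal monophyletic or paraphyletic set of
same-taxon tips to the single tip with the most unambiguous aligned
characters (ties to the lexicographically smallest id). It iterates two
local rules to a fixed point — merge same-taxon sister tips; merge a tip
with its parent's same-taxon sister tip — which collapses exactly the
connected grades interrupted only by tips of that taxon.

## Orthology decomposition (RT pruning)

Rooted clades are extracted from unrooted homolog trees as the maximal
subtrees free of root-taxon tips that sit across one edge from a
root-taxon-containing component; the tree is deterministically hung from
the lexicographically smallest root-taxon tip, which makes the result
rooting-invariant. Within a clade, any node whose child subtrees share a
taxon marks a duplication; the side with fewer distinct taxa is pruned,
root to tips, until taxa are unique. Ties (equal taxon counts) keep the
side with the greater summed unambiguous-character count, then the side
containing the lexicographically smallest tip id — deterministic and
occupancy-maximizing. Pruned sequences are not reconsidered elsewhere.
Polytomies are resolved greedily pair by pair until children are pairwise
disjoint. Root-taxon tips never enter ortholog groups, so a design with
N sampled taxa yields at most N − 1 per group (95 for the 69 + 27 design).

## Supermatrix

Ortholog alignments passing the taxon/length filters are concatenated;
missing taxa get all-gap blocks and partitions record 1-based inclusive
coordinates. Occupancy definitions (stated in output headers because usage
varies): gene occupancy = filled (taxon × gene) cells / (taxa × genes);
character occupancy = non-gap characters / (taxa × columns). Jackknife
replicates draw `round(fraction × n_genes)` whole partitions without
replacement from a seeded generator; replicates never split a gene.

## Duplication mapping

Extracted clades qualify for mapping when their tips all belong to the
rule's taxon set, they contain the required number of member taxa, and the
mean bootstrap over internal nodes — excluding the stem and tips, which
carry no support of their own — is at least 80. A duplication is a node
whose two child subtrees share ≥ 2 taxa; requiring two shared taxa makes
single-taxon (terminal) duplications invisible by design, as they are
indistinguishable from assembly isoforms after tip masking. Each
duplication maps to the species-tree MRCA of all taxa below the node, which
under gene/species conflict or missing taxa is the containing, possibly
deeper, node. Nested duplications in one clade count once per species
node.

The per-branch proportion divides by the number of extracted clades for
which a duplication at that branch is *observable*: clades sampling ≥ 2
taxa from each child lineage of the branch. This denominator is a design
choice of this package (flagged in output metadata); branches with no
informative clade are reported "not investigated" rather than zero.

## Rate contrasts

Codon alignments are produced by threading unaligned CDS onto the protein
alignment (terminal stop tolerated, every codon cross-checked against the
standard genetic code) and trimming codon columns with < 20% unambiguous
codons (all three positions in {A,C,G,T}). Branch-model fitting is
external; this package emits the labeled tree (woody clade `#1`, its
herbaceous sister `#2`, background unlabeled) plus a run-configuration stub
(model = 2, NSsites = 0, F3x4), and consumes the resulting dS and dN trees
as paired newicks on a shared topology.

Lineage lengths use the stepwise average from the tips — A(tip) = 0,
A(node) = mean over children of (child length + A(child)) — which weights
each child lineage equally regardless of tip count, plus the sister
clade's stem branch. Including the stem is a deliberate reading (the
stem's substitutions belong to that lineage's history); `include_stem=False`
provides the alternative. The signed contrast (difference over the shorter
side, positive when herbaceous is faster) is excluded beyond ±10 or on a
zero denominator (excluded, not infinite). Exact ties are dropped from
sign tests, the standard convention. The two-sided sign-test p is twice
the smaller binomial tail, capped at 1 — identical to the
minimum-likelihood convention at p = ½, and verified against exhaustive
enumeration for n ≤ 25. Subsampling to at most `n_sub` clades per
comparison uses a seeded generator recorded in the report header. The
node-density control reruns every table restricted to sister pairs with
equal tip counts.

## Ks distributions

Self-hit filtering counts a sequence's participation after thresholding
(a flag switches to pre-threshold counting, since either reading is
defensible) and removes promiscuous sequences with all their pairs to
avoid over-represented young families. NG86 is implemented directly:
per-codon synonymous-site fractions averaged over the two sequences
(changes to stop codons count as nonsynonymous), multi-position codon
differences averaged over all orderings of single steps excluding paths
through stops (falling back to all paths when none is stop-free), and the
Jukes–Cantor-style correction d = −(3/4)·ln(1 − (4/3)·p), saturated at
p ≥ 3/4. Codons containing any non-ACGT symbol are excluded from both
site and difference counts. Pairwise protein alignment is pluggable, with
a built-in BLOSUM62 global aligner as default. The default histogram
(width 0.05 on [0, 2], overflow bucket) resolves both a mid-range WGD peak
and the deep peak near 1.8–2 that an ancient triplication leaves in real
plant data.

## The simulator

Gene families evolve along a known species tree by a lineage-wise Gillespie
birth–death process (duplication λ, loss μ, per unit branch length); a WGD
on a designated branch duplicates each surviving lineage at the branch
start, with the extra copy retained at the stated probability (retention 0
is exactly the no-WGD process). Truth records list every duplication with
its species branch, plus injected isoform tips (near-zero-length same-taxon
sisters) and contaminant tips (3.0-substitutions/site branches). Branch
rates are the species-tree lengths times unit-mean lognormal noise, with a
habit multiplier on branches whose descendant tips are all herbaceous; dN
uses its own noise and a dN/dS ratio.

Defaults are the study conditions the toolkit is built to detect:
herbaceous multiplier 3 on both dS and dN (the magnitude reported for
woody/herbaceous contrasts in plants), WGD retention 0.3 (a realistic
paleopolyploid retention), background λ = μ = 0.05, lognormal σ = 0.25,
synthetic bootstrap supports 90–100 so support filters pass unless a test
injects low values. The built-in species tree has 24 taxa — 16 ingroup
(8 woody/8 herbaceous arranged as three sister-pair comparisons: two
multi-taxon, one single–single), two named outgroup lineages, and a root
taxon — with the WGD clade placed so a tip-to-duplication synonymous path
is ≈ 0.3, putting woody within-taxon paralog pairs near Ks 0.6.

Sequences are generated only where Ks estimation needs them: codon pairs
evolve from a random sense-codon ancestor under independent-site,
equal-rate nucleotide substitution (stops rejected) until the realized
synonymous divergence — synonymous events per synonymous site, sites
recounted as the sequence drifts — reaches the target taken from the dS
path between the two paralog tips. This is precisely the process whose
expected synonymous divergence NG86 estimates, so estimator recovery is a
meaningful check; the simulator does not model codon usage bias,
transition/transversion asymmetry, selection on nonsynonymous sites beyond
stop rejection, alignment error, or assembly noise, so passing tests bound
algorithmic correctness, not robustness to those real-data features.
Tree-level tests run without sequences to keep the suite fast.

## Problem sizes and statistical design

Desk-scale sizes were chosen once: 500-family bundles for WGD recovery
(20 seeded runs; recovery = the true WGD branch top-ranked by duplication
proportion), 500 replicates of 44 sister-pair clades for the null error
rate of the contrast pipeline, 500 pairs × 300 codons for NG86 recovery,
1,000 random trees for the MRCA and RT-pruning property sweeps. The
44-clade study size was selected *analytically before any simulation was
run*: the exact sign test is discrete, so its true size at α = 0.05
oscillates with n, and n = 44 gives size 0.0488, the closest attainable to
the nominal level among desk-scale study sizes — a type-I measurement at a
size-matched n tests the pipeline rather than the discreteness of the
binomial.

## Known limitations

- Orthology is the RT criterion only; alternative decompositions (MI/MO)
  and DL-reconciliation are out of scope, as are the inference engines
  themselves (alignment, tree search, codon-model fitting, clustering).
- Terminal-branch WGDs are invisible to the topology-based detector
  (min_shared = 2); the Ks distribution is the complementary signal.
- The duplication-proportion denominator is one defensible definition among
  several; comparisons across datasets should use the same definition.
- NG86 is the classical counting method; it ignores transition/transversion
  bias and codon frequencies, and overestimates mildly at high divergence
  (the saturation flag marks the region where the correction degrades).
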