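# Methods

## Scope and data model

The package analyzes a set of per-gene DNA multiple sequence alignments of
single-copy orthologs over a shared taxon universe.  Alignments are stored
as uint8 code matrices over the alphabet {A, C, G, T, -, N, ?}; IUPAC
ambiguity codes are folded into N on input, and '-', 'N' and '?' are all
treated as missing by the filters and by the likelihood machinery ('-' is
written back as an indel, '?' is the padding character for genes absent
from a taxon).  Coordinates are 0-based half-open everywhere in memory;
the partition-file dialect ("DNA, gene = start-end") is 1-based inclusive,
converted only at the I/O boundary.

## Alignment filtering

Two column filters bracket the strict and relaxed ends of common practice:

* **Gap-free conserved blocks** (strict).  Only columns with zero missing
  characters survive, grouped into maximal runs; runs shorter than
  `min_block_len` (default 10 columns) are discarded, as are runs in which
  fewer than `min_conserved_frac` (default 0.5) of columns have a majority
  residue shared by more than half the taxa.  This reproduces the defining
  behavior of strict block filters — no gaps, only consistently aligned
  regions — without re-implementing any particular program's scoring; the
  defaults are our choice and are deliberately conservative.
* **Gap-fraction ceiling** (relaxed).  A column is kept iff its missing
  fraction is strictly below `max_gap_frac` (default 0.5); "less than 50%
  gaps" is a strict inequality, so a 2-of-4 gap column is dropped.

Gene selection keeps genes strictly longer than `min_len` (default 1000 bp)
— "longer than 1 kb" is read as a strict inequality — and optionally
requires a taxon set.  Both filters are idempotent and the block filter's
output provably contains no missing characters; the test suite asserts
both.

The zero-missing reduction greedily removes the non-protected taxon present
in the fewest genes.  The complete-gene count is monotone non-decreasing
under taxon removal, so unconstrained maximization would discard almost all
taxa; by default a removal is therefore accepted only if it immediately
increases the count (hill climbing), and an optional `target_genes` lets
the walk continue through zero-gain plateaus until a requested number of
complete genes is reached.  Which trade-off is "right" is a genuinely open
design point; the analysis driver uses a target of 30 genes.

## Tree inference engines

The pipeline calls no external programs.  The default engine is
deterministic: Jukes–Cantor distances d = −(3/4)·ln(1 − (4/3)p), with p
computed over columns where both taxa carry unambiguous bases, saturated
pairs (p ≥ 3/4) and pairs with no shared sites capped at `max_distance`
(default 5.0 substitutions/site); then Saitou–Nei neighbor joining with the
Q-criterion, ties broken by the lexicographically smallest pair of cluster
labels (a cluster's label is its smallest leaf label), and negative branch
lengths clamped to zero.  An optional "ml-nni" engine hill-climbs over
nearest-neighbor interchanges under the JC likelihood (Felsenstein pruning
with per-site rescaling; missing data contribute all-ones partials), with
per-branch Brent optimization on [1e-8, 10] and an improvement threshold of
1e-6 log units.  JC is a deliberate simplification — the engine exists to
make replicate inference cheap and reproducible, not to compete with
dedicated ML software — and externally inferred newick trees can be
substituted anywhere a tree is an input.  For RF comparability the
reference tree of a resampling experiment must be built with the same
engine as the replicates.

## Tree distances

Non-trivial bipartitions are canonicalized as the split side not containing
the lexicographically smallest shared leaf.  RF is the symmetric-difference
count, normalized by 2(n−3) (the binary-tree maximum, used for
multifurcating trees too, so their normalized values may not reach 1).
Trees with unequal leaf sets are pruned to the shared taxa first, and
fewer than four shared taxa is an error.  Two weighted flavours are
defined over the union of splits: the sum of |w₁(s) − w₂(s)| with weight 0
for an absent split, and the same sum divided by the total internal branch
length of both trees.  The exact weighted variants used by any particular
program differ in normalization; these two are documented as our
interpretation of the common branch-score family.  In a rooted
representation the two basal branches legitimately sum into one split
weight.

## Resampling convergence experiment

Efforts default to {0.001, 0.01, 0.1, 0.2, 0.3} with 30 replicates each.
A replicate draws ⌈e·L⌉ distinct columns uniformly without replacement from
the raw supermatrix (partition boundaries are ignored), keeping original
column order.  Per-replicate seeds derive from the master seed and the
(effort index, replicate) pair through a SeedSequence hash, so the whole
experiment is reproducible from one integer and single replicates can be
regenerated in isolation.  Engine failures flag the affected record and the
experiment continues.

Per-effort normalized-RF distributions are summarized box-plot style:
sample SD (n−1), percentiles 10/25/50/75/90 by linear interpolation, and
points outside the 10–90 whiskers listed as outliers.  Distributions are
compared with a classical one-way fixed-effects ANOVA; pairwise structure
is probed with three post hoc procedures sharing the pooled within-group
mean square: Tukey's studentized-range HSD, Bonferroni-corrected pooled-t,
and Scheffé's contrast criterion.  The **convergence effort** is the
smallest effort whose comparison with the next larger effort is
non-significant at α = 0.01 under *all three* procedures (requiring
unanimity is the conservative reading of "no significant difference
detected"; with two groups the three procedures coincide, so the adjacent
test's size is exactly α).  If every adjacent pair differs, no effort is
selected.

A Thompson Tau screen is provided for assembly-completeness values:
iteratively, the single largest |x − mean| is flagged if it exceeds τ·SD
with τ = t·(n−1)/(√n·√(n−2+t²)), t = t_{α/2,n−2} (α = 0.05), the point
removed, and the test repeated; flagging stops at the first pass with no
exceedance or when fewer than three points remain.

## Ancestral state reconstruction

The lifestyle character has k = 10 states.  Under Mk1 all ordered state
pairs share one instantaneous rate β (per unit branch length), giving
P_ii(t) = 1/k + (k−1)/k·e^{−kβt} and P_ij(t) = (1 − e^{−kβt})/k; with
k = 4 and β = 1/3 this is exactly Jukes–Cantor, an identity the test suite
exploits as a cross-module check.  The per-state root log-likelihoods are
conditional on the root state (no prior folded in), computed by pruning
with per-node rescaling; the overall likelihood for rate fitting places a
uniform prior on the root state.  β is fitted once globally by bounded
Brent search on log10 β ∈ [−6, 2] (not re-fitted per root state); a fit at
the search boundary — e.g. a constant trait driving β to 0 — is flagged
but not fatal.  Branch lengths are used as given (substitutions/site from
the source tree), with no rescaling; β is therefore expressed in trait
changes per substitution/site.

The reported **best-state set** contains every state within `threshold`
(default 2.0) log units of the maximum — the conventional cutoff of
likelihood-based reconstruction reports.  On the published ten-lifestyle
log-likelihood table this threshold reproduces exactly the two flagged
states (saprotroph and rock-inhabiting, 0.74 log units apart, with the
third state ≥ 4.28 behind).

Parsimony uses Sankoff dynamic programming with unit costs, which equals
Fitch counting on binary trees (cross-checked against an independent Fitch
implementation on 200 random trees); the set of minimal-cost root states
and the minimal change count are reported.  Reconstruction requires a
rooted tree; the CLI roots at a user-supplied outgroup (the edge splitting
the outgroup from the ingroup, branch length halved) and never guesses a
root.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume:

* **Species tree**: birth–death conditioned on the tip count (dendropy's
  sampler), rescaled to a root-to-tip depth of 0.5 substitutions/site —
  a deep, class-level divergence.  Leaves are labelled T1..Tn.
* **Genes**: unlinked alignments simulated site-independently under JC (or
  HKY) on the species tree.  Gene lengths are log-normal (σ = 0.6) with
  mean ≈ 1657 bp, matching a few hundred orthologs summing to ~1 Mb at
  full scale; the "paper-like" profile uses 200 genes over 48 taxa
  (~340 kb), a deliberate desk-scale reduction of the full study size
  (hundreds of taxa, 664 genes, 1.1 Mb).
* **Missingness**: per-taxon-per-gene Bernoulli deletion.  In the
  paper-like profile four taxa carry 0.9 missingness (poor assemblies) and
  the rest 0.1, approximating heterogeneous assembly completeness.
* **Trait**: a k = 10 state character evolved under Mk1 at β = 0.5 from a
  uniform root state, with all true internal states recorded for recovery
  scoring.

Everything regenerates bit-identically from the manifest (profile, seed);
per-gene and per-stage seeds derive from the master seed via SeedSequence.

What the generator does *not* model — and what passing tests therefore do
not establish about real data: gene-tree/species-tree discordance (gene
trees equal the species tree; coalescent-based supertree inference is out
of scope), indels produced by alignment error (gaps arise only from
whole-taxon gene absence), among-site and among-gene rate heterogeneity,
and compositional bias.  Conclusions from the convergence experiment apply
to the homogeneous-signal regime the generator produces; on real data the
selected effort is expected to shift right.

## Numerical choices and limitations

* Likelihood pruning rescales partials per node and accumulates log
  factors; impossible sites yield −∞ log-likelihood rather than an error.
* NJ tie-breaking, NNI move ordering, and resampling seed derivation are
  all deterministic; two runs with equal seeds are identical to the byte.
* Problem sizes in the tests and the acceptance script (48 taxa × 200
  genes, 30 replicates, 64-taxon trait simulations, 200–500 replicate
  fits) were chosen as the smallest sizes at which the distributional
  claims are stable; they are the package's study conditions, not tuning
  knobs.
* The ANOVA is classical and assumes homoscedastic groups; RF
  distributions at very small efforts are wider than at large ones, which
  inflates the pooled MSW and makes the convergence rule conservative.
* `convergence_effort` compares only adjacent efforts; a non-monotone
  sequence of group means could in principle plateau early and diverge
  later, which the rule would miss.
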