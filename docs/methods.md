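# Methods

## Trees, ages and sampled ancestors

All trees are rooted time trees.  Node ages are in million years before
present; branch lengths are age differences, kept consistent to 1e-9.
When a tree is parsed from Newick/NEXUS, ages are computed from branch
lengths with the *youngest tip* as the age reference — the only
well-defined "present" for non-ultrametric fossil trees — unless every
node carries an explicit `height` annotation, in which case the
annotations win.  Sampled ancestors are represented exactly as tip-dating
software serializes them: tips attached by a branch of length ≤ ε
(default ε = 1e-8 My).  No degree-2 node representation is used
internally; a single canonical form keeps clade extraction trivial, and
sampled ancestors participate in clades as ordinary tips.  The known
side effect — summarizers under-report the support of clades involving
sampled ancestors — is documented rather than corrected.

Negative branch lengths can legitimately appear in summary trees whose
node heights are taken from the target tree itself ("keep target
heights"); they are preserved on input and output, with a warning.

## Clade support and MCC summarization

`PP(C)` = fraction of posterior trees containing clade `C` (rooted taxon
subsets; singletons and the all-taxa root clade are excluded as trivial).
The MCC tree is the *sampled* tree maximizing `Σ log PP(C)` over its
nontrivial clades, ties broken by first occurrence in the sample — the
de-facto summarizer convention.  Heights are never re-estimated.  Burn-in
is `floor(n·f)` leading trees per run, removed before concatenating runs
(default f = 0.1).

A-posteriori pruning deletes tips from every posterior tree, suppresses
the resulting degree-2 nodes (branch lengths summed; surviving node ages
unchanged) and re-runs the same summarization on the same posterior.
Equivalent-node comparison takes each nontrivial pruned-MCC clade `C`,
finds the smallest full-MCC clade `F ⊇ C`, and flags the record as
contradicting when `F ∩ retained ≠ C` — i.e. when the full tree places
other retained taxa inside `F`.  `pp_full` is the PP of the MRCA clade
`F` itself (for contradicting records no better-matching clade is
searched for; the flag carries that information).

## Tree similarity

Both metrics restrict the pair to shared taxa first (≥ 4 required).

* **Bipartition similarity** = `|clades(A) ∩ clades(B)| / (n_shared − 2)`,
  on rooted clades.  `n − 2` is the nontrivial-clade count of a fully
  resolved rooted binary tree, so identical topologies score 1.  The
  normalization denominator is fixed at `n_shared − 2` (not either tree's
  own resolved count); for the fully resolved point-estimate trees this
  package targets the two coincide.
* **Quartet similarity** = fraction of the `C(n,4)` shared-taxon quartets
  resolved identically.  A quartet's resolution in a rooted time tree is
  decided from pairwise MRCA ages: among the six pairs, the pair with the
  strictly youngest MRCA is the cherry of the induced unrooted quartet.
  This is exact for binary trees with distinct internal node ages (which
  the generators guarantee almost surely) and degrades gracefully to
  "unresolved" on age ties; an unresolved quartet counts as shared only
  when unresolved in both trees.  Exact enumeration is used up to 30
  shared taxa (MRCA age matrices are built in one postorder sweep, and
  all quartets are resolved vectorized); above that a seeded
  Monte Carlo estimator with 100,000 uniform quartet draws reports the
  binomial standard error `√(p̂(1−p̂)/m)`.
* **Rescaled quartet similarity** = `(s − 1/3)/(2/3)`.  Under any
  label-exchangeable tree distribution each of a quartet's three
  resolutions is equally likely, so two independent random trees agree
  with probability 1/3; the rescaling puts the random-pair expectation at
  0, like the bipartition metric.

## Rogue diagnostics

**Node distance** between two tips = number of internal nodes on the path
(1 for sisters, and 1 for a tip and its sampled ancestor).  Each taxon's
three closest neighbours — three, so that each comparison is a quartet
statement — are fixed on the MCC tree (ties broken lexicographically) and
the distances to those same neighbours are measured in every posterior
tree; the report gives per-rank mean, max and the 95% empirical quantile
(linear interpolation).

**Leaf stability**: for focal taxon `t` and a triplet `{a,b,c}`, the
quartet `{t,a,b,c}` resolves one of three ways; over the sample these
have frequencies `f1 ≥ f2 ≥ f3` with `f1+f2+f3 ≤ 1` (the remainder is
unresolved).  Averaged over triplets: `lsDif = mean(f1 − f2)`,
`lsMax = mean(f1)`, `lsEnt = mean(1 − H(f)/log 3)` with `H` the Shannon
entropy of the resolved frequencies renormalized to sum to 1 (a triplet
with no resolved quartet contributes 0).  Unresolved mass is *not*
renormalized into `lsDif`/`lsMax`, so those indices penalize genuine
conflict rather than lack of resolution.  Triplets are enumerated
exhaustively at ≤ 20 taxa and sampled uniformly with replacement (seeded,
default budget 1000 per taxon) above that; sampling with replacement
keeps the triplet-mean estimator unbiased.

## Synthetic generators

The generators produce the *study conditions*, not MCMC output.

* **FBD simulation**: Gillespie simulation forward from the origin with
  per-lineage rates λ (speciation), μ (extinction), ψ (fossil sampling);
  extant-sampling probability is fixed at 0 because the target clades are
  entirely extinct.  The reconstructed tree keeps only lineages ancestral
  to fossils; a fossil with sampled descendants becomes a zero-length
  sampled-ancestor tip, the youngest sample on a path becomes the
  terminal tip.  Trees are conditioned on a minimum fossil count by
  rejection (capped; a lineage-count cap rejects runaway radiations).
  The truth record (fossil count, sampled-ancestor count) is bookkept
  independently of the tree and cross-checked in tests.
* **Stage slices**: a stage spanning `[start, end]` Ma is cut into
  `k` equal-duration bins; tip ages are drawn uniformly within their
  slice interval, and tips sharing a fossil-site id receive one shared
  draw (same-site fossils are contemporaneous).
* **Origin prior**: `offset + Exponential(mean)` — the informative prior
  form used for clades whose oldest certain fossil caps the plausible
  origin (defaults in the examples: offset 489.5 Ma, mean 0.1 My).
* **Pseudo-posteriors**: each sample tree is a copy of a fixed backbone;
  with probability `nni_probability` one age-valid NNI is applied; each
  designated wildcard is detached and reattached to a branch drawn with
  weight `exp(−locality · d)`, `d` being the topological distance from
  its true attachment (locality 0 = uniform wildcard; large = confined
  to its home clade).  The reattachment age is uniform within the
  feasible part of the chosen branch, and attachment above the root is
  allowed.  This reproduces the phenomenology that matters downstream —
  stable backbone, wandering wildcards with tunable reach — while giving
  exact ground truth.  What it does *not* emulate: autocorrelation along
  an MCMC chain, character-driven signal, clock-rate variation, or
  coherent uncertainty near the root; passing tests therefore demonstrate
  correctness of the summaries and diagnostics, not inference quality on
  real data.

## Problem sizes and numerical choices

Default synthetic scale is 10–24 taxa and 100–200 trees per sample —
desk scale, chosen so every statistic (including exhaustive triplet
enumeration and exact quartet similarity) runs in seconds; the reference
computations in `scripts/acceptance.py` use 1000 tree pairs on 20 taxa
and 10⁶ prior draws.  Random topologies are uniform over rooted binary
labeled shapes (sequential leaf insertion), with internal ages jittered
by `max(child ages) + U(0.5, 1.5)` so pairwise MRCA ages are almost
surely distinct.  Quantiles are empirical order statistics with linear
interpolation.  All stochastic code takes explicit seeds and is
bit-reproducible; the pipeline writes a manifest (seeds, burn-in counts,
estimator modes) next to its TSV/NEXUS/JSON outputs, and re-running a
pipeline config reproduces every output byte for byte.

## Known limitations

* Clade PPs treat sampled ancestors as ordinary tips; support of clades
  involving ancestors is therefore conservatively low.
* The bipartition metric is clade-based (rooted); comparisons against
  unrooted-split implementations will differ by the root-adjacent split.
* The quartet resolution rule assumes distinct MRCA ages; identically
  aged internal nodes (hand-built ultrametric trees with tied ages) fall
  back to "unresolved".
* Equivalent-node `pp_full` is always the MRCA clade's PP, which
  understates the best-matching support for contradicting records.
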