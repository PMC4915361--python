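# Methods

## Model and procedure

`quartetpp` scores each internal branch of an unrooted binary species tree
against n unrooted gene trees. The statistical unit is the branch's
quadripartition Q = A,B|C,D and its two rearrangements Q₂ = A,C|B,D and
Q₃ = A,D|B,C. Under the multi-species coalescent the probability that a
quartet around the branch shows the species-tree topology in a gene tree is
θ = 1 − (2/3)e^(−d) (d = internal branch length in coalescent units), with
the two alternatives at (1 − θ)/2 each; θ > 1/3 always, so the dominant
quartet topology identifies the true branch.

**Quartet counting.** For one gene tree, the number of quartets around Q
resolved as topology j is obtained from a single postorder pass that
accumulates, per node, the four intersection sizes |subtree ∩ A| … |subtree
∩ D|. Each internal node contributes through the 12 matchings between the
quadripartition and the node's tripartition (a sibling pair of Q's clusters
assigned to one tripartition part, the two remaining clusters to the two
remaining parts: 2·3·2 = 12 products of four intersection cardinalities).
Every resolved quartet is counted at exactly its two subtending nodes, so
the accumulated total is halved; an odd total raises an internal-consistency
error rather than rounding, since parity failure can only mean a counting
bug. A polytomy of degree D is scored over all C(D, 3) tripartitions formed
by choosing three of its neighbor clusters; leaves in unchosen clusters are
simply absent from the intersections, which is exactly the statement that
those quartets are unresolved at that node. The brute-force oracle —
enumerate every quartet, restrict the gene tree to its four leaves, classify
by bipartition membership — is kept in the package and must agree
bit-exactly; the test suite checks this on randomized binary,
multifurcating and taxon-deleted instances.

**Averaging and the trial count.** Quartets around one branch are strongly
dependent, so per-quartet counts are averaged, not summed, into
z̄ = (z₁, z₂, z₃): totals over genes divided by m̄, the mean number of
quartets around the branch present per *effective* gene (a gene is
effective if at least one quartet around the branch survives its missing
taxa; ineffective genes carry no information about the branch and are
excluded from both the average and the trial count). The number of
multinomial trials n defaults to z₁ + z₂ + z₃: for complete binary gene
trees this equals the effective gene count, while quartets left unresolved
by gene-tree polytomies observe no outcome and therefore contribute no
trial. A `strict_n` mode uses the literal effective-gene count instead, in
which case unresolved mass makes the posterior more conservative. The
default was chosen because trials must not exceed observed outcomes;
whether a gene whose present quartets are all unresolved should count as a
trial is genuinely ambiguous, and both conventions are exposed.

**Posterior.** With a Yule(λ) prior on branch lengths, θ has prior density
f(t) = λ(3(1−t)/2)^(2λ−1) on [1/3, 1] for each of the three topologies
(total mass 1/3 each; λ = 1/2 gives a flat density of 1/2). The posterior
for topology j is proportional to 2^{z_j} h(z_j) with
h(x) = B(x+1, n−x+2λ)(1 − I₁/₃(x+1, n−x+2λ)). A numeric-integration oracle
evaluates the defining likelihood integrals ∫ t^{z_j}((1−t)/2)^{n−z_j} f(t) dt
by adaptive quadrature and must agree with the closed form to 1e−6.

**Branch lengths.** ML = −ln(3/2(1 − z₁/n)) for z₁ ≥ n/3, else 0;
MAP = −ln(3/2(1 − z₁/(n+2λ))) for z₁ ≥ (n+2λ)/3, else 0. MAP ≤ ML always;
both are continuous in z₁. The MAP estimate is what the scorer writes on
branches by default (`length_kind="ml"` switches). Terminal branches are
never assigned coalescent lengths: with one lineage sampled per species,
gene trees carry no coalescence information about pendant edges.

## Numerical choices

- All posterior arithmetic is in log space (log pp_j = z_j ln 2 + log h(z_j)
  − logsumexp); the factor 2^{z₂−z₁} overflows double precision for
  realistic gene counts otherwise.
- 1 − I₁/₃(a, b) is evaluated as I₂/₃(b, a), which is accurate precisely
  where the direct form loses all significance. If even that tail
  underflows (extremely skewed z at n ≫ 10³), a closed-form lower bound on
  the leading series term keeps log h finite; the affected component's
  posterior is ≪ machine epsilon either way.
- z values are fractional whenever taxa are missing, so Γ-function
  continuation replaces factorials throughout; nothing assumes integer
  counts.
- A branch with z₁ = n has infinite ML length; the scorer reports a
  configurable cap (default 10 coalescent units — θ is within 3·10⁻⁵ of 1
  there, far beyond what any realistic gene count can distinguish) plus a
  `capped` flag, because downstream newick consumers reject "inf".
- Branches that no gene tree informs (n = 0) are annotated NA with length
  unknown; an NA is deliberately distinct from pp = 1/3, which would claim
  positive evidence of a hard polytomy.
- Q₂/Q₃ labels are not canonical in the model, so the scorer fixes them by
  taxon index (within each side of the branch the cluster containing the
  smaller minimum index comes first, and the pair containing the overall
  smallest index is (A, B)); outputs are reproducible run to run and
  invariant to input rerooting and gene-tree order.
- λ is fixed per run (default 1/2, the uninformative choice); it is not
  estimated from the data.

## Synthetic data

The simulator generates the same conditions the scoring model assumes, so
that every stochastic claim is testable without external data:

- **Species trees**: pure-birth Yule process, rate λ = 1/2 by default
  (matching the prior the scorer assumes), waiting times Exp(kλ) with k
  extant lineages, lengths in coalescent units. One extra waiting time is
  appended after the last speciation so the youngest pendant edges are
  positive. For fixtures that pin study conditions, internal lengths can be
  clamped into a band (the recovery fixture uses [0.3, 2]: branches long
  enough to be recoverable, short enough to leave real discordance).
- **Gene trees**: standard MSC — one lineage per species, coalescence at
  rate 1 per pair per coalescent unit within each branch, survivors promoted
  to the parent branch, free coalescence above the root. Calibration is
  tested against θ = 1 − (2/3)e^(−d) at 10,000 genes.
- **Topological noise**: each internal gene-tree edge is independently hit
  with probability r; a hit redraws the arrangement of the four surrounding
  subtrees uniformly from the three possibilities (so a hit edge changes
  topology with probability 2/3). This is a deliberately minimal stand-in
  for gene-tree estimation error: it produces the qualitative signature that
  matters (extra discordance, hence underestimated lengths and reduced
  support) without modelling alignment length or site saturation.
- **Missing data**: each leaf deleted independently with probability q.

What passing tests on these data do **not** show: robustness to biased
gene-tree error (the NNI noise is symmetric), to discordance from paralogy
or horizontal transfer, to violations of the locality assumption by badly
wrong species trees, or to multiple alleles per species (unsupported).

## Fixture and test scales

The stochastic acceptance checks use an 8-taxon species tree with 2,000
true gene trees for parameter recovery (all true branches at pp ≥ 0.95,
median relative MAP-length error ≤ 15%), 800 genes for the
noise-bias direction check, and 10,000 4-taxon genes per length point for
simulator calibration — sizes at which the binomial/multinomial standard
errors are comfortably inside the asserted tolerances while the whole suite
runs in well under a minute. Oracle-equivalence tests draw ≥ 500 randomized
gene-tree instances on 6–10 taxa, small enough for exhaustive quartet
enumeration to stay exact and fast. All seeds are fixed in the tests.

## Known limitations

- Supports on gene trees are trusted as given when collapsing; aggressive
  thresholds can bias the retained discordance.
- The quartet counting is pure Python over integer bitmasks; it comfortably
  handles hundreds of taxa × thousands of genes, but is not tuned for the
  very largest datasets.
- Branch lengths inherit the well-known downward bias under gene-tree error
  (reproduced as a directional test); they should be read as lower bounds
  when gene trees are noisy.
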