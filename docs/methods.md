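# Methods

`barcodebench` studies how well six DNA-barcode matching strategies
identify *recently diverged* species, where incomplete lineage sorting
and shared haplotypes erode both the "barcode gap" and species
monophyly.  Everything is computed on synthetic data whose generator is
part of the package, so every number the benchmark reports is
reproducible from a configuration and a seed.

## The generative model

A replicate dataset is produced by a four-stage hierarchy:

1. **Species tree.**  An ultrametric Yule (pure-birth) tree for
   `n_species` (default 50) species.  The sampler runs a forward birth
   process (rate 1 per lineage) until `n` lineages exist, observes the
   tree one further exponential waiting time later (just before the
   next speciation would occur), and rescales node ages so the root
   sits at `depth` generations (default 10^6).  The observation
   convention makes the youngest divergence small but nonzero, which
   matches how such trees look in practice: a 50-species draw spans
   divergence times from a few thousand generations to more than half
   the tree depth.  Species are split into *recent* and *old* halves by
   the rank of their divergence time (terminal branch length), ties
   broken by label.

2. **Gene trees.**  Within the species tree, one coalescent gene tree
   per replicate with `samples_per_species` (20) tips per species,
   simulated by msprime: one population per species-tree node, all with
   the same effective size, joined by population splits at the species
   divergence times.  The pairwise coalescence rate is
   `1/(ploidy_factor * Ne)` per generation.  `ploidy_factor` defaults
   to 1 (haploid convention) because the study design leaves the
   convention open; it rescales the depth of lineage sorting but not
   the ordering of conditions.  Ancestral populations use the same Ne
   as extant ones.  The benchmark grid is Ne in {1000, 10000, 50000}.

3. **Rate-heterogeneity noise.**  Each branch length `b` is replaced by
   a draw from Normal(`b`, `0.7 b`) — the factor is interpreted as a
   standard-deviation multiplier, since a *variance* of `0.7 b` (or
   `0.49 b^2` read as sd-squared) would be negligible on long branches
   and could not mimic mutation-rate heterogeneity, which is the
   noise's purpose.  Negative draws are redrawn (up to 1000 times, then
   clamped to 0).  This breaks ultrametricity, as intended.

4. **Sequences.**  650-bp alignments evolve along the noisy gene tree
   under HKY (kappa 8.3; base frequencies A/C/G/T =
   0.30/0.15/0.10/0.45) with 4 equiprobable discrete-gamma rate
   categories of shape 0.2 (category-*mean* rates).  Branch lengths in
   generations are converted to expected substitutions per site with
   `rate_scale` (default 5e-8 per site per generation), chosen so the
   deepest splits (~10^6 generations apart, ~2x10^6 generations of
   path) accumulate roughly 10% expected divergence — the level seen in
   empirical COI barcode sets.  Transition probabilities are computed
   by matrix exponentials of the scaled HKY generator; the root
   sequence is drawn from the stationary frequencies.

Each species' 20 individuals are then randomly split into 16 reference
and 4 query sequences.  All methods in a replicate see the identical
split (paired design).

What the generator does *not* emulate: indels and alignment error
(sequences are co-aligned and gapless by construction), gene flow,
hybridisation, selection, codon structure, sequencing error, and
unbalanced sampling.  Passing benchmarks on these data therefore speak
to the population-genetic difficulty of recent divergence — not to
robustness against alignment or data-quality problems.

## The six matchers

All matchers are sklearn-style classifiers: `fit(references, labels)`,
`predict(queries)`; an unidentifiable query yields the distinguished
label `UNCERTAIN`, which counts as a failure in every metric.

**Neighbor joining (tree-based).**  Canonical Saitou–Nei agglomeration
on the K2P distance matrix of references plus queries, after a seeded
random shuffle of the input order (tie-breaking must not depend on the
input sort).  The tree is midpoint-rooted once; each query is assessed
with all other queries logically pruned from its neighbourhoods.
*Liberal* assessment assigns species X when the query's sister group is
purely X; *strict* additionally requires the next-enclosing
neighbourhood to be purely X ("nested within a mono-specific clade").
A query attached so high that no second neighbourhood exists is
UNCERTAIN under strict.  Strict assignments are by construction a
subset of liberal ones.

**Parsimony (tree-based).**  Duplicate sequences are collapsed, a
heuristic search minimises the Fitch score, and duplicates are
re-grafted as zero-length ladders resolved deterministically by label.
The engine exploits the two-value property of unit-cost Sankoff
vectors: a subtree is exactly summarised per site by (Fitch set, score),
so NNI rearrangement deltas and stepwise-addition insertion costs are
exact, not approximations.  Two search modes exist: random stepwise
addition plus NNI hill-climbing (the default for the module-level
`parsimony_search`), and a fast setting that seeds hill-climbing with
the NJ topology (used by the benchmark; one tree is kept, ties broken
first-found).  Branch lengths are Fitch mutation counts under one
deterministic minimal reconstruction, used only for midpoint rooting.
Assessment is identical to NJ.

**Nearest neighbour (similarity).**  K2P distance from the query to
every reference; the species of the minimal-distance reference is
assigned.  A minimal-distance tie among conspecific references is still
an assignment; a tie spanning species is UNCERTAIN.  Saturated
(undefined) K2P distances act as +infinity; if every distance is
undefined the query is UNCERTAIN with a warning.

**Local-alignment best hit (similarity).**  An exact affine-gap
Smith-Waterman (match +2, mismatch −3, gap open 5, extend 2 — BLASTN-like
conventions) against every reference; up to 100 hits with at least 80%
alignment identity are retained and the species of the top-scoring
qualifying hit is assigned (top-score tie across species, or no
qualifying hit: UNCERTAIN).  Scores are raw; for fixed scoring
parameters bit-score conversion is monotone and changes no ranking.
The DP is jit-compiled and optionally *banded*: the benchmark runs with
a ±32-diagonal band, which is exact whenever the optimal path stays
within 32 diagonals of the main one — always the case for co-aligned
gap-free barcodes, where the optimum is essentially the best diagonal
segment.  `band=None` computes the full matrix and is used in the
exactness tests.  Identical sequences (among references or among
queries) are deduplicated before alignment; results are provably
unchanged.

**Substring distinguishers (diagnostic, alignment-free).**  Candidate
substrings of lengths {5, 8, 12, 20} are enumerated from a random
subsample of references (pool capped at 50 000 candidates), and a
greedy set cover selects distinguishers until every pair of distinct
reference sequences differs in presence/absence on at least
`redundancy` (default 3) selected substrings, or no candidate helps.
The greedy step uses lazy (priority-queue) marginal evaluation with the
upper bound k(u−k) on a candidate's separable pairs, and candidates
with identical presence profiles are collapsed first.  A query's
profile is compared to every reference profile by agreement count;
best-agreeing references of a single species give the assignment,
otherwise UNCERTAIN.  Identical sequences shared across species are
logged as inseparable.  Probe thermodynamics (GC content, melting
temperature) are out of scope: the selection is purely combinatorial.

**Logic formulas (diagnostic, alignment-bound).**  Per species, up to
35 alignment columns are kept, ranked by the separating-pair count of
their best nucleotide value; then sequential covering greedily grows
conjunctions of `column = base` literals, each step excluding the most
remaining non-target sequences (ties: retaining the most target
sequences, then lowest column), closing a conjunction when no
non-target sequence satisfies it, and opening new conjunctions (up to
5) for uncovered target sequences.  Training false-positive and
false-negative rates are recorded.  A query satisfying exactly one
species' formula is assigned that species; multiple matches are broken
by lowest training FP rate, exact FP ties and zero matches are
UNCERTAIN.  The formulas double as human-readable species descriptions
(`describe()` prints position=nucleotide lists, 0-based columns).

## Metrics and statistics

*Species identification success* is the fraction of species whose
queries were all correctly identified; *sequence identification
success* is correct queries over all queries (sensitivity).  Both are
reported by species age class and Ne.  The barcode-gap analysis scores
a species as lacking a gap when its minimum between-species K2P
distance does not strictly exceed its maximum within-species distance
(ties count as no gap), on reference sequences only.  Monophyly is
scored as an unrooted bipartition test (rooting-independent) on the
reference-only NJ tree.

Methods are compared with a Friedman test (replicates as blocks,
midranks, the standard tie correction; a tie-degenerate table returns
statistic 0, p 1) and post-hoc pairwise Wilcoxon signed-rank tests
(zero differences dropped; exact null for ≤25 pairs, normal
approximation above).  All p-values are Bonferroni-corrected by the
total number of tests performed across the analysis, significant at
corrected P < 0.01.

## Numerical and design choices

* K2P distances with a non-positive log argument are *undefined* (NaN),
  never capped: capping would silently bias nearest-neighbour ranking.
  NJ refuses matrices with undefined entries (naming the pairs); the
  parsimony starting tree, which only needs a rough topology,
  substitutes 1.5x the largest finite distance.
* Distance matrices are computed with one-hot float32 matrix products
  (transition/transversion counts via purine/pyrimidine indicators);
  the brute-force double loop is kept as the test oracle.
* Midpoint rooting happens once per tree, with all queries present;
  per-query pruning is done logically during the assessment walk.  On
  1000-tip trees a query tip on the midpoint path is possible in
  principle but vanishingly rare and was not observed.
* Seeds: every stochastic stage derives its seed from the master seed
  plus a stage tag (CRC-hashed through `numpy.random.SeedSequence`),
  so reruns are bit-identical and stages are independently
  reproducible.
* Degenerate inputs: all-identical alignments yield a trivial ladder
  tree (score 0); species with fewer than two references are excluded
  from the gap report with a log message; empty query sets are legal.

## Benchmark scale

The packaged study conditions run 10 replicates per Ne level (30 in
total) on one seeded species tree — the package's scaled-down
replication of the original 100-per-Ne design, sized so the whole
benchmark (simulation, six matchers, statistics) completes in roughly
a quarter of an hour on a single CPU.  Replicate failures are logged
and dropped pairwise from all methods; none occur under the default
conditions.  The `scripts/acceptance.py` entry point reruns the whole
pipeline from a seed and writes the headline measures as JSON.

## Known limitations

* The benchmark's absolute numbers inherit the variance of a single
  species-tree draw; reported tolerances are calibrated for that.
* The parsimony search is a documented heuristic (stepwise addition /
  NJ start + NNI), not a TNT replication; its identification scores
  are somewhat better than a search that holds one of many co-optimal
  trees at random, as the original design did.
* The distinguisher matcher scores per-sequence profiles, so on
  sister species that share polymorphisms it inherits the same
  haplotype confusion as nearest neighbour; species-level diagnosis is
  the logic-formula matcher's role.
* Empirical (unaligned, variable-length) data are supported through
  the 80/20 split procedure and the alignment-free/local-alignment
  matchers, but multiple sequence alignment itself is out of scope:
  alignment-bound matchers expect pre-aligned input.
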