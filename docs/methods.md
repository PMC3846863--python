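# Methods

## Model

The knowledgebase is a signed directed graph over named biological entities.
Each statement `A increases B` (+1) or `A decreases B` (−1) is one edge;
duplicate (source, sign, target) triples are merged with their evidence
strings concatenated, while a `+1` and a `−1` edge between the same pair —
contradictory literature — are both retained.  Targets carry an explicit
layer tag (`transcript`, `activity`, `compound`, `process`); the transcript
layer is the measurement layer and is never inferred from identifiers.

A hypothesis is an (entity, sign) pair.  Its predictions are computed by a
breadth-first search over (node, accumulated sign) states: every directed
walk of length 1..δ from the entity contributes the product of its edge signs
times the hypothesis sign, and a transcript reachable with both net signs is
AMBIGUOUS.  Walk semantics (revisits allowed) rather than simple paths were
chosen because they are the cheapest semantics consistent with "all possible
downstream changes", and the (node, sign)-state search decides them exactly.
Transcript nodes are terminal for traversal by default (`traverse_transcripts`
re-enables expansion for knowledgebases encoding transcript-level feedback).
The default depth is δ = 2 — hypothesis → regulator → transcript — matching
the structure in which an upstream cause explains transcripts through one
intermediate regulator; δ is a logged configuration value everywhere it
matters.  Ambiguous predictions never count as correct or incorrect and are
excluded from the enrichment draw (K = q₊ + q₋), keeping k ≤ K consistent
with counting only correct + incorrect genes.

## Statistics

**Enrichment.** P(X ≥ k), X ~ Hypergeom(N, m, K): N measured genes, m
changed, K unambiguous predictions, k changed among them.  Computed through
`scipy.stats.hypergeom`; when the survival function underflows, the tail is
recomputed as a log-sum-exp of log-pmf terms.  P-values are never reported as
exactly zero.

**Correctness.** The null keeps the observed margins (m₊ up calls, m₋ down
calls, N genes) and reassigns the calls uniformly.  With a, b the up/down
calls landing on the q₊ predicted-up slots and c, d those on the q₋
predicted-down slots, the null score is S = a − b − c + d and the p-value is
P(S ≥ score).  The exact computation enumerates the joint law of (a, b, c, d)
— a multivariate hypergeometric for the q₊ slots convolved with the
conditional one for the q₋ slots — fully vectorised in log space.  Its cost
is bounded by `correctness_exact_cost`; above a configurable budget (2·10⁵
terms) a Monte Carlo estimator draws the four occupancies through a chain of
conditional hypergeometric draws (equivalent to a full label permutation,
but vectorised over permutations) and reports the add-one-corrected estimate
(b+1)/(n+1) with its binomial standard error.

The null distribution is invariant under exchanging the up and down roles
((q₊, m₊) ↔ (q₋, m₋)); parameters are canonicalised before computing and the
MC stream is seeded from (base seed, entity, canonical parameters).  As a
consequence, negating every call in the profile swaps the results of (u, +)
and (u, −) bit-for-bit — including Monte Carlo p-values — which the test
suite asserts over random graph/profile pairs.

**Ranking and filter.** Rank is the 1-based position after sorting by score
descending, ties broken by smaller enrichment p, then smaller correctness p,
then label; fully deterministic because a rank cutoff otherwise depends on
unstated ordering.  The significance filter keeps hypotheses with
n_correct ≥ 3, both p-values < 0.01 and rank ≤ 35 (all overridable).
"Supporting genes" means correctly explained genes, not correct + incorrect.
No multiple-testing correction is applied across hypotheses — the filter is
deliberately the raw-p + rank rule; BH adjustment is available in
`de_profiles` for the gene-level statistics, where it belongs.

## Differential-expression input

DE tables carry signed linear fold changes (|fc| ≥ 1, negative = down, so
−4.92 means 4.92-fold down) and raw p-values; converters to and from log2 are
provided.  Probe-level rows collapse to one row per gene by largest |fc|,
ties by smaller p, then first occurrence.  Discretization calls sign(fc) when
|fc| ≥ 1.3 and the BH-adjusted p < 0.05 by default; the fold-change cutoff of
1.3 is the documented operating point of this kind of analysis, while the p
cutoff is configurable because no single value is canonical.  The universe is
always the full measured gene set — both null distributions condition on N,
so restricting it to called genes would bias the p-values.

## Network summarisation

Each significant hypothesis is reduced to its explanation vector: the ±1
signature over the genes it correctly explains (explained evidence is what
"redundant" and "surrogate" refer to, so vectors deliberately exclude
unconfirmed predictions).  Similarity is the cosine over the union of genes;
clustering is average-linkage agglomeration on 1 − cosine with the dendrogram
cut at 0.6 (members cohere at cosine ≳ 0.4), input order made irrelevant by
canonical label sorting.  A cluster is a *top network* when it has ≥ 3
members, one of which ranks in the top 25.

Elimination of redundant and surrogate hypotheses runs over the whole
significant set, best rank first: a hypothesis is removed when a better-ranked
kept hypothesis either (a) explains ≥ 75% of its correctly explained genes
with greater-or-equal score (surrogate), or (b) overlaps it with Jaccard
≥ 0.9 (redundant).  Two deliberate choices here: the containment threshold is
0.75 rather than exact set inclusion because under background differential
expression a surrogate picks up the odd coincidental gene outside its
parent's evidence, and an exact-subset rule then flickers between repeated
experiments; and elimination is global rather than per display cluster
because average-linkage clusters of mutually orthogonal evidence blocks are
often too small to contain the surrogate pairs they should resolve.  The
best-ranked hypothesis of any group is never removed.

Process calls aggregate the surviving hypotheses through a GMT annotation
table: members of a process are the significant survivors annotated to it,
net = Σ sign·score, dominance = |net| / Σ|score|, and the call is UP/DOWN when
the dominance reaches 0.33, MIXED otherwise.  The dominance rule is an
explicit codified stand-in for what is, in practice, expert curation of
direction arrows.

## Translatability

`build_matrix` stacks per-condition process calls into a process × condition
matrix with ABSENT for missing calls, optionally restricted to calls backed
by a top-ranking network.  "Translated" defaults to presence in both systems
regardless of direction, with same/opposite direction fractions reported
separately; MIXED agrees only with MIXED.  Concordance metrics are invariant
to row order and to processes absent everywhere.

## Synthetic data: what it emulates, and its design contracts

The generator produces a layered graph — regulators → intermediates →
transcript leaves (a three-hop variant splits the intermediate layer) — and
plants a small set of active (regulator, direction) mechanisms.  Intended
transcript signs propagate as signed walk counts summed over mechanisms;
conflicts resolve by the sign of the sum, exact zero meaning unchanged, with
conflicting transcripts counted and logged.  Observation noise follows the
ternary channel: a truly changed transcript is seen correctly with
probability (1−ε)(1−π), flipped with ε(1−π), dropped with π; unaffected
transcripts become background calls with probability β, split evenly between
directions unless the asymmetry knob is moved.  All draws descend from one
seed; outputs are byte-reproducible.

Identifiability of the planted mechanisms is a stated design contract, not an
accident of parameters:

- regulator out-degrees are Poisson draws truncated to
  [0.6·mean, 1.5·mean] — mean approximately preserved, variance bounded, so
  no planted mechanism is starved of downstream evidence;
- transcripts are partitioned near-evenly over intermediates (each gets one
  parent, plus a second parent at rate 0.05), so no single intermediate
  dominates the measurement layer;
- regulator → intermediate sets avoid repeating any intermediate *pair*
  across regulators (greedy, best effort, collisions logged).  This bounds
  the overlap of any two regulators' downstream programmes to about one
  intermediate block, which is what keeps decoy regulators from mimicking a
  planted mechanism wholesale.  The constraint needs head-room: keep
  n_regulators·C(d,2) well below C(n_intermediates, 2) (about one third is
  comfortable);
- planted mechanisms are drawn among regulators with at least the mean
  out-degree, preferring mutually disjoint intermediate sets, so mechanisms
  do not cancel each other at shared targets.

Under these conditions and zero noise, every planted regulator strictly
outscores every intermediate and every decoy, and recall at n_planted is 1
on every seed — the test suite asserts exactly that.  A further geometric
consideration matters for the paired-condition benchmark: planted mechanisms
should cover only a small fraction of the intermediate layer (≈ 7% in the
shipped benchmark).  Then a decoy that fully matches one intermediate block
is decisively significant (and is eliminated as a surrogate in both systems),
a decoy spanning blocks of two mechanisms is decisively significant in both
paired systems (and counts as genuinely shared), and nothing sits at the
significance cutoff where sampling noise would toggle it between systems.

What the generator does **not** emulate: probe-level intensities and array
normalisation artifacts, correlated noise across genes, realistic regulatory
dynamics (feedback, saturation), literature curation bias, or the scale-free
degree structure of real interactomes.  Passing the recovery benchmarks
therefore demonstrates the correctness and calibration of the inference
machinery under its own generative assumptions, not performance on real
knowledgebases, where redundancy and annotation bias are far harsher.

## Validation problem sizes

The shipped validation uses: oracle grids up to N = 200 (enrichment) and
N ≤ 8 (exhaustive correctness enumeration); 100 random graph/profile pairs
for the mirror suite; the recovery benchmark at 200 regulators / 100
intermediates / 2000 transcripts with 3 planted mechanisms (ε = π = 0.1,
β = 0.05, 100 seeds; zero-noise variant over 20 seeds); and paired conditions
at 60 / 200 / 3000 with overlap f ∈ {0, 0.5, 1}, 50 seeds each.  These sizes
are the package's own benchmark conditions and are re-run end-to-end by
`scripts/acceptance.py`.

## Numerical and degenerate-input choices

Log-space arithmetic throughout the exact tail computations; p-values clamped
to (0, 1]; hypotheses with no measured predictions are skipped; an empty
overlap between transcript nodes and the profile universe is an error; empty
explanation vectors are dropped with a warning; a reference condition with no
process calls yields explicit nulls rather than NaN arithmetic.  Monte Carlo
resolution is bounded below by 1/(n_perm+1) ≈ 5·10⁻⁴ at the default 1999
permutations — raise `n_perm` where correctness p-values near the 0.01
cutoff must be resolved more finely.

## Known limitations

Exact correctness computation is quartic in the smaller of the slot/margin
counts and falls back to sampling on large instances; walk semantics can
label a transcript ambiguous through long interference paths that simple-path
semantics would keep signed; the per-regulator process annotation used in the
synthetic benchmark makes process-level and hypothesis-level translatability
nearly equivalent, which real many-to-many annotations are not; and the
significance filter's rank cutoff makes borderline hypotheses sensitive to
the composition of the condition's full ranking, which is inherent to any
rank-based rule.
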