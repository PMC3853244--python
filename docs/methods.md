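# Methods

## Model

The predictor treats a chemical ontology as an undirected, unweighted graph
G = (V, E): one node per `[Term]` stanza of an OBO 1.2 file, one edge per
`is_a` or `relationship` assertion.  Three modeling choices are baked in:

* **Edges are undirected.**  The distance is used symmetrically (drug A to
  drug B and back), so the direction of `is_a` carries no information the
  method uses; it is discarded at parse time.
* **All relation types count equally.**  Any `relationship: <type> <id>`
  line becomes an edge, not only subsumption; parallel assertions between
  the same two terms collapse to a single edge (the edge remembers its
  relation labels, distances ignore them).  Self-referential assertions are
  dropped.
* **Obsolete terms are kept by default** (`keep_obsolete=False` drops them).
  Keeping them is the non-destructive choice: an obsolete term that still
  annotates a drug should still resolve.

The hop distance d(t, t′) is computed lazily by breadth-first search from
each needed source term and memoized per source — never as an all-pairs
matrix, which for a real ontology (tens of thousands of nodes) would be
wasteful when only the annotation terms of the drug table are ever queried.
An unreachable pair has no distance; it is represented by an explicit
sentinel (`None`), never by a large magic number.

The compound-pair score is the mean distance over the full Cartesian
product of the two term sets, **including repeated values** (multiset mean,
the standard semantic-similarity convention; set-mean semantics would
silently discount duplicated distances).  Q is held as an exact
`fractions.Fraction` — integer distance sum over integer pair count — so the
minimum-Q neighbor shell is determined by exact comparisons: two drugs tie
iff their Q values are identical as rationals, with no floating-point
epsilon policy.  If any cross pair is unreachable, Q is *undefined* for
that candidate pair of compounds; undefined candidates are skipped during
neighbor selection, and a query with no defined Q against any training drug
produces an explicit no-prediction outcome rather than a number.

Classification keeps **every** drug attaining the optimal score (minimum Q,
or maximum interaction score I with the constraint max I > 0), tallies
their group labels, and takes the mode.  Ties among top-voted groups are
broken uniformly at random from a seeded generator; the outcome records
whether randomness was used (`tie_broken`).  A query drug present in the
training set is *not* silently excluded by `predict` — exclusion is the
evaluation harness's job — which keeps prediction a pure function of its
arguments.

For the interaction backend, a maximum score of exactly 0 is a
no-prediction, not an all-drugs tie: a zero combined score encodes
non-interaction and carries no evidence about the target group.

## Evaluation protocols

Jackknife (leave-one-out) refits the classifier on the n−1 remaining drugs
for each of the n records; the held-out record's absence from its own
reference set is asserted inside the loop.  Independent test predicts a
disjoint held-out partition against a fixed training partition (overlap by
drug id is an error).  In both protocols:

* abstentions count as incorrect in accuracy and are additionally reported
  as a separate count, so they can never silently inflate accuracy;
* all accuracy arithmetic is on integer counts; percentages are computed at
  formatting time only, making the overall accuracy exactly the
  count-weighted mean of the per-group accuracies;
* one master seed spawns per-query tie-break seeds through
  `numpy.random.SeedSequence([master, query_index])`, so a full run is
  deterministic and any single prediction can be re-run in isolation.

Train/test splitting draws round-half-up(fraction × n) records uniformly
without replacement (876 drugs at 10% give exactly 88); sampling is
unstratified, so per-group test counts fluctuate around proportionality.

## Synthetic benchmark

The generator builds three coupled fixtures from one configuration and one
seed (regeneration is byte-identical):

* **Ontology** — a rooted tree with one branch per target group: a spine of
  `branch_depth − 1` intermediate terms, then `terms_per_branch` leaf terms
  under the deepest spine node.  Branches meet only at the root, so two
  leaves of the same branch are strictly closer (≤ 2 hops, given the
  shared parent) than leaves of different branches (2 × depth hops) whenever
  depth ≥ 2 — the class signal is structural, not tuned through distance
  thresholds.  One within-branch `related_to` shortcut edge per branch
  exercises the relationship-edge path without weakening branch separation.
* **Drugs** — `drugs_per_group` drugs per group (default 4 × 50), each
  annotated with `terms_per_drug` (default 2) distinct terms from its
  group's branch; a `cross_branch_noise` fraction (default 0.05) of drugs
  receives one additional off-branch term.
* **Interactions** — each unordered drug pair receives a positive combined
  score with probability 0.3 within a group and 0.005 across groups
  (interaction databases are sparse, and cross-class links are rare);
  scores are uniform integers in [150, 999], the familiar combined-score
  range.  Pairs without a row are non-interactive (I = 0).

Default sizes (4 groups × 50 drugs, a ~60-node ontology) were chosen so a
full leave-one-out evaluation of both backends runs in well under a minute;
they are the package's standard desk-scale benchmark.

**What passing tests show — and don't.**  The generator plants exactly the
structure the method assumes: within-class term sets closer on the graph
than cross-class ones, and interactions concentrated within classes.
Recovery of the planted classes (jackknife accuracy ≥ 0.90 at the default
noise level) therefore validates the machinery — parsing, distances, exact
tie handling, voting, protocol bookkeeping — not the biological claim that
real ontology annotations predict real target groups.  Real ontologies have
heavier-tailed degree distributions, cross-branch `relationship` edges, and
annotation sets of varying size; real interaction scores are not uniform.
None of that is emulated.

## Numerical and degenerate-input choices

* Q comparisons and tie detection: exact rationals, no tolerance.
* Interaction-score comparisons: raw float equality, appropriate for scores
  read verbatim from a file (no arithmetic is performed on them).
* Tie-breaks: uniform choice over the lexicographically sorted tied groups,
  from `numpy.random.default_rng(seed)`; sorting first makes the draw
  independent of tally-iteration order.
* Duplicate interaction rows that disagree keep the larger score with a
  warning (real interaction dumps contain both orientations of each pair);
  agreeing duplicates are silent.
* Empty OBO input is an empty graph, not an error; a `[Term]` stanza with
  no `id` is a parse error naming its line.
* A group with zero test samples renders "n/a" in reports instead of
  dividing by zero.

## Known limitations

* Single-label classification only; a drug acting on several target groups
  must be excluded upstream (the benchmark filters do this).
* No alternative set aggregations (min, max, best-match average), no
  edge-weighted or relation-typed distances, no information-content
  measures.
* The two backends are not ensembled; they are compared side by side.
* KEGG/ChEBI/STITCH identifier cross-mapping is out of scope; input tables
  must arrive pre-mapped.
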