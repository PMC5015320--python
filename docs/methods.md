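# Methods

This note records how `ontoeval` defines its evaluation machinery, the
defaults it ships, and the design decisions taken where the assessment
protocol it implements leaves room for choice.

## Ontology model

An ontology is a rooted DAG of terms connected by `is_a` and `part_of`
edges; all other OBO relationship types (`regulates`, `occurs_in`, …) are
ignored for ancestry, propagation, and information content. Annotation and
prediction sets are always handled in propagation-closed form (the
true-path rule), and the namespace root is excluded everywhere: a root-only
annotation carries no information, and scoring the root would inflate every
metric. Obsolete terms are dropped at parse time; records naming them are
skipped with a count rather than failing a whole input file. `alt_id`
accessions resolve to their canonical term. Cycles and references to
undeclared terms are hard errors — silently repairing either would corrupt
every downstream count.

Sub-ontologies are carved out either by namespace (the three GO branches)
or by root term (the phenotypic-abnormality subtree of HPO, HP:0000118);
edges leaving the extracted subtree are dropped. Two releases of the same
sub-ontology can be intersected (terms and edges present in both) to build
a drift-free common version for cross-assessment comparisons.

## Information content

ic(f) = −log₂( N(f) / N(parents(f)) ), where N(f) counts corpus proteins
annotated (after closure) with f and N(parents(f)) counts proteins carrying
*all* parents of f jointly — the conditional probability reading of a
multi-parent DAG. Roots get ic 0 by construction. Terms never observed in
the corpus, or whose parents never co-occur, cannot be estimated; they
receive the ceiling −log₂(1/(corpus_size+1)) and are flagged `capped` in
the serialized table. The cap keeps S_min finite when a method predicts (or
truth contains) a term absent from the training corpus; an alternative
would be to drop such terms, which silently under-penalizes
over-prediction. The estimator refuses corpora that are not
propagation-closed instead of closing them itself, so the caller's corpus
and the benchmark truth sets are guaranteed to be built by the same
closure.

## Benchmarks

Knowledge status is decided from the t0 snapshot: NK proteins had no
experimental annotation in any of the three GO namespaces; LK proteins in
one or two, excluding the namespace under evaluation. HPO benchmarks are
selected against HPO t0 annotations only — GO status neither qualifies nor
disqualifies a phenotype benchmark — and only the NK flavour exists there.
Truth sets are the t1 term sets as stored; curation retractions between
snapshots are ignored (a protein vanishing from t1 entirely is treated as
snapshot inconsistency and is an error). Accepted experimental evidence
codes default to EXP, IDA, IPI, IMP, IGI, IEP, TAS, IC.

Easy/difficult splitting uses maximal global sequence identity against the
training set with an inclusive 0.60 cutoff. The aligner is Needleman–Wunsch
(BLOSUM62, gap open 10, extend 0.5), identity = identical columns /
alignment length including gaps; a precomputed two-column identity table
bypasses alignment entirely. Species subsets require ≥ 15 proteins; coarser
groupings (e.g. eukarya/prokarya) are supplied as taxon collections.

## Predictions

Submission scores live in (0,1] with two significant figures, read here as
two decimal places to match the evaluation grid: validation rounds
half-up to the 0.01 grid, drops values that round to 0.00 (unexpressible),
and rejects out-of-range values (strict mode raises, lenient mode counts).
Duplicate (target, term) rows keep the maximum score, which is
order-independent. Because validated scores and the default
`ThresholdGrid` (0.01 … 1.00, step 0.01, K = 100) share the same float
representation of k/100, thresholding `score >= tau` is an exact
integer-cent comparison with no epsilon.

Before evaluation, score maps are made DAG-consistent by max-propagation
(every ancestor gets at least the best descendant score, root removed).
Without this, a thresholded prediction need not be a subgraph and the
ru/mi decomposition would double-penalize a method for each missing
ancestor of a correctly predicted leaf. Propagation is idempotent and
never lowers a score; a `--no-propagate` flag preserves raw submissions
for sensitivity analysis.

## Metric computation

Per protein, scores are sorted once and every per-threshold count (|P(τ)|,
|P(τ)∩T|, and their ic-weighted analogues) is obtained by binary search and
cumulative sums — O(K + k log k) per protein instead of materializing 100
explicit sets. The test suite checks this machinery against an independent
brute-force implementation that does materialize every set, at 1e−12 on
hundreds of seeded random instances. The per-protein ru(τ) is accumulated
directly as ic(T \ P(τ)) rather than as ic(T) − ic(T∩P(τ)), so a perfect
predictor's S_min is exactly 0.0 rather than a rounding residue.

Conventions at the edges: precision is undefined at thresholds where no
protein has a prediction (m(τ) = 0) and those points are skipped by F_max;
a method with no predictions at any threshold scores F_max = 0 in full
mode rather than "undefined". Arg-max/arg-min ties across the grid report
the smallest threshold. Benchmark proteins whose truth set is empty after
root exclusion are dropped from n with a warning. The normalized ru/mi
variant divides each protein's ru and mi by ic(T_i ∪ P_i(τ)) (a per-protein,
per-threshold total), which bounds both coordinates in [0,1]; proteins with
zero total information contribute 0 with a warning. Weighted
precision/recall replace set cardinalities with ic sums. These secondary
metrics follow the information-theoretic definitions of the ru/mi family.

Term-centric AUC ranks all benchmark proteins by the term's predicted
score, unpredicted proteins at 0, positives = proteins whose truth set
contains the term, everyone else negative. It is computed from midranks
(Mann–Whitney U / n₁n₂), so ties get half credit; averages cover terms with
at least 10 positives and at least one negative, with standard error
sd/√(#terms). The "top k independently well-predicted terms" report walks
the AUC ranking greedily, accepting a term only if its self-inclusive
ancestry (root excluded) is disjoint from the ancestries already accepted.

## Method comparison

Bootstrap resampling treats the benchmark proteins as the sampling unit.
Head-to-head comparisons draw one set of B index samples and score both
methods on each — paired sampling, matching the "compete on each benchmark
set" design and reducing variance of the difference. A method wins a sample
by a strictly larger F_max; exact floating-point equality is a tie and
awards no win. δ is the difference of bootstrap means (method 2 − method 1),
so it is antisymmetric under argument swap with a shared seed. Defaults:
B = 10 000, 95 % percentile intervals; the package's own tests and
acceptance script use B = 200–1000 on 50-protein benchmarks, which is
sufficient to resolve the quality orderings they assert.

Best-per-PI filtering keeps the highest-scoring method per principal
investigator, breaking ties by lexicographic method id. Similarity networks
use Pearson correlation on the (protein, term) pairs scored by both methods
of a pair (policies for union-with-zeros and globally-common pairs are
available behind a flag, since "common pairs" is genuinely ambiguous);
edges are emitted at r ≥ 0.75 by default, and pairs with fewer than two
common points or zero variance are recorded as missing rather than 0.

## Synthetic fixtures

The generators emulate the study design, not real biology: a full b-ary
tree ontology of configurable depth with a controlled fraction of two-parent
(diamond) nodes to exercise joint-parent conditioning; proteins annotated
by sampling leaves and closing upward; a growth phase in which NK/LK
cohorts gain their first annotations in designated namespaces; and
predictors parameterized by quality q (probability of recovering a truth
leaf) and noise rate (Poisson-mean spurious leaves). Kept-leaf scores are
drawn from Beta(5,1) and noise from Beta(1,5), mapped to the 0.01 grid, so
curves are threshold-sensitive and F_max does not degenerate to the value
at τ = 0.01. Defaults (depth 3, branching 2, 100 proteins, ~2 leaves per
protein, q = 0.8, noise 1.0) give benchmarks of a few dozen proteins —
large enough for the bootstrap orderings to be stable, small enough that
the whole suite runs in seconds.

What passing these tests shows: the arithmetic, the set/DAG logic, the
rule implementations, and the statistical machinery are correct. What it
does not show: performance numbers on real GO/HPO releases, whose term
counts (tens of thousands), annotation biases, and inter-term correlations
the toy generator makes no attempt to mimic. The fixtures have no real
sequences either; the identity-based splits are exercised with short
synthetic peptides and precomputed identity tables.

## Acceptance computation

`scripts/acceptance.py` reports the two analytic limit cases on a seeded
10-protein, 15-term fixture: a predictor whose propagated prediction set
equals the ground truth at score 1.00 must reach F_max = 1 exactly (at
some threshold its precision and recall are both 1 for every protein) and
S_min = 0 exactly (at τ = 1.00 both ru and mi vanish term-by-term). Both
values are recomputed through the full pipeline — fixture generation,
benchmark construction, information-content estimation, curve evaluation —
not asserted.

## Known limitations

- Only `is_a`/`part_of` edges propagate; ontologies that lean on
  `regulates` for semantics will look shallower here than in tools that
  include it.
- The GAF reader handles the common column layout and NOT qualifiers; it
  is not a full validator for every GAF 2.x corner (qualifier
  vocabularies, isoform columns).
- Partial-mode precision averages over all proteins with predictions at τ,
  which coincides with the self-selected subset whenever predictions exist
  only on chosen targets (always true after validation drops empty maps).
- Bootstrap win counting uses exact floating-point equality for ties;
  methods differing below float resolution are not collapsed into ties.
- `max_global_identity` is O(queries × training) full alignments; for
  realistically sized training sets, use the precomputed-table path.
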