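# Methods

## Ontology model and traversal

An ontology is a DAG of named concepts under one ID prefix, connected by
`is_a` edges only.  Other relationship types found in input documents are
counted and logged but never traversed: both alignment routes propagate
strictly taxonomically ("equivalent and super concepts"), so non-`is_a`
edges would change the semantics of the mapping.  Obsolete concepts are
parsed and retained for bookkeeping but isolated from traversal and
excluded from every matching, mapping and translation pool; coverage
percentages are therefore computed over active concepts.

Subsumption queries reduce to reflexive-transitive closure over `is_a`,
memoized per ontology.  Parsing is delegated to `obonet` with an additional
stanza validator (a `[Term]` without an `id` is reported by stanza ordinal)
and a cycle check that reports one offending cycle.  Synonym scope
annotations (EXACT/RELATED/…) are dropped by default — every synonym enters
the lexical pool — with an `exact_synonyms_only` switch for sensitivity
analysis.

EQ definitions are read from `intersection_of` stanzas in a fixed dialect:
a bare quality line opens a conjunct block, each following
`intersection_of: inheres_in ENTITY` line contributes one
(quality, entity) conjunct, and a new bare quality line opens the next
block.  Modifier constructs (e.g. relational qualities, nested entity
expressions) are not modelled; definitions are flat conjunctions of
(quality, entity) pairs over two shared support ontologies.

## Lexical alignment

Normalization lowercases, maps every Unicode punctuation character
(hyphens included) to a space, collapses whitespace and strips the ends.
Matching is exact on normalized strings — no stemming, no edit distance —
which makes the seed set reproducible and auditable; the cost is
sensitivity to wording, which is precisely the property under study.
Seeds are many-to-many; each ordered cross-ontology pair is emitted once
with the strongest evidence channel recorded
(name-name > name-synonym > synonym-name > synonym-synonym).

## Formal alignment

For flat conjunctions over shared support hierarchies, structural
subsumption is sound and complete: definition $d_1$ is subsumed by $d_2$
iff every conjunct of $d_2$ is generalized by some conjunct of $d_1$,
where conjunct generalization is coordinate-wise ancestor-or-self in the
quality and entity hierarchies.  This decision procedure replaces a
description-logic reasoner for the fragment the package models; it is
cross-checked in the test suite against brute-force enumeration over
conjunct assignments and path-enumerated ancestor closures.  Axioms are
emitted for every cross pair of defined concepts: subclass in either
direction, or a single equivalence when both hold.

## Mapping construction

Both routes produce axiom sets over the same merged structure: directed
edges child→parent for every `is_a` in both ontologies, sub→super for
every subclass axiom, both directions for every equivalence.  The mapping
entry of a source concept is the set of target-ontology concepts reachable
from it; concepts reaching none are "not mapped".  Equivalences introduce
two-cycles, so reachability is computed per node on the cyclic graph
rather than by DAG memoization.  Key consequences, all covered by tests:

* entries are closed under target-ontology ancestors;
* adding axioms never shrinks any entry (monotonicity);
* mappings are not symmetrical between directions;
* concepts without own seeds/definitions inherit mappings through their
  ancestors, so mapped counts can exceed seeded/defined counts.

Target-ontology roots are retained in entry sets by default (`drop_roots`
removes parentless targets), matching the convention of published mapping
records that include the root.

Summary statistics follow the conventions of published mapping-comparison
tables: "mapped" counts concepts with non-empty entries; the mean
mapped-set size averages over mapped concepts only; percentages are
rounded half-up to two decimals.

## Overlap comparison

Only concepts mapped by *both* methods are classified; concepts mapped by
one method are coverage-only statistics.  This intersection semantics is
forced by consistency: the five categories are defined on two non-empty
target sets, and published comparison totals sit well below each method's
individual mapped counts.  Subset categories mean proper subset; `exact`
is its own category.  The five-way classification is a partition,
verified exhaustively over all subset pairs of a small universe and on
every generated run.

## Prioritization benchmark

Annotation profiles are binary concept sets; the cosine similarity then
reduces to $|A\cap B|/\sqrt{|A||B|}$.  An empty translated profile scores
0 but stays in the ranking — dropping such pairs would silently change the
FPR denominator.  No ancestor closure is applied to the untranslated side
by default (a `close_annotations` option exists for sensitivity analysis):
the translated side acquires ancestors through mapping propagation, the
untranslated side is compared as annotated.  The pooled ROC ranks all
(disease, model) pairs together; tied scores advance as one threshold
block (the standard convention); AUC is trapezoidal and equals the
Mann–Whitney concordance statistic, which the tests assert on random and
pipeline-generated instances.  A model gene without a human ortholog makes
its pairs negatives by definition, and multiple models of one gene would
all inherit that gene's gold associations — the generator's presets use
one model per gene so that planted signal stays interpretable.

## Synthetic-data generator

The generator's purpose is an input bundle whose correct answers are known
by construction.

* **Support ontologies** are complete rooted trees (default depth 3,
  branching 3 → 40 nodes each), standing in for a cross-species anatomy
  ontology and a quality ontology.  Trees keep depth well-defined, which
  the coverage biases below use.
* **Species ontologies** sample one shared pool of distinct
  (quality, entity) pairs — default 199 pairs plus a species root, i.e.
  200 concepts per species.  Both species instantiate the *same* pool with
  parallel local IDs, so every concept has an identical-EQ partner in the
  other species.  `is_a` edges are asserted exactly where EQ subsumption
  holds between sampled pairs (plus the root), making the ontologies
  logically coherent and the formal aligner's output predictable.
  Distinctness of pairs within a species keeps the graph acyclic.
* **Definition coverage** (`frac_defined_1/2`, default 1.0/1.0) selects
  which concepts expose their definition.  The smaller defined set is
  nested inside the larger, emulating one cross-species definition effort
  consumed at different stages: every defined concept of the
  lower-coverage species then has a defined partner, which guarantees the
  formal route maps at least that species' defined fraction.  The
  higher-coverage species can have defined concepts with no defined
  subsumer on the other side, so its mapped fraction may fall below its
  defined fraction — the asymmetry real studies report.  Species roots are
  never defined; a defined root would make every concept inherit a mapping
  and force 100% coverage.
* **Label sharing** (`frac_shared_labels`, default 1.0) gives the chosen
  identical-EQ pairs an identical normalized label (mostly as primary
  names, a fraction through synonyms, exercising all evidence channels).
  Root labels are always species-specific for the same degeneracy reason.
* **Depth biases.**  `definition_depth_bias` > 0 concentrates definitions
  on shallow (general) concepts; `label_depth_bias` > 0 concentrates
  shared labels on deep (specific) concepts (weights
  $\propto e^{\mp b \cdot \mathrm{depth}}$).  This reproduces the
  documented asymmetry of the real methods — formal definitions are
  easiest to provide for general classes while disease vocabulary shares
  specific names — and with it the qualitative signature: the formal route
  maps more concepts (general definitions have many inheriting
  descendants) while the lexical route's entries are larger (deep partners
  carry long ancestor chains).
* **Annotation corpus.**  Models (species-2 space) draw 5–7 distinct
  non-root concepts; each model carries one gene; orthology is a complete
  1:1 map.  For each planted (gene, disease) association the disease's
  species-1 profile is the identical-EQ counterpart of the gene's model
  profile with `annotation_noise` of it resampled uniformly; unrelated
  diseases are annotated uniformly at random.  With zero noise and full
  sharing, a planted pair's translated similarity ($\approx\sqrt{m/|a|}$
  for $m$ annotations translating into $|a|$ concepts) exceeds any random
  pair's overlap score by a wide margin at the preset sizes, so both
  methods attain pooled AUC 1.0; at full noise the AUC is at chance.

Two presets fix the study conditions: `small` (full coverage, no noise,
200 concepts/species, 15 genes = models = diseases, 10 planted
associations) for planted-signal recovery, and `paper-shaped`
(300 concepts/species, definition coverage 0.48/0.63, label sharing 0.25,
depth biases 0.8, noise 0.2) for the qualitative coverage/specificity
contrast.  All randomness flows from a single seeded NumPy generator;
bundles are byte-identical across runs of the same config.

What the generator does **not** emulate: realistic vocabulary and synonym
skew, species-specific anatomy requiring bridging, multi-conjunct or
modifier-bearing definitions, differing ontology sizes, multi-gene
genotypes, and incomplete orthology.  Passing tests therefore demonstrate
correctness of the machinery and the direction of the method contrasts,
not quantitative agreement with any real HP/MP release.

## Numerical and reporting conventions

Percentages round half-up to two decimals.  Mapped-set averages are means
over mapped concepts only and render as "-" when nothing is mapped.
ROC requires at least one positive and one negative pair and raises
otherwise.  Report percentages and averages are always recomputable from
the report's own raw counts.  The test suite's statistical checks
(noise-degradation monotonicity over 20 seeds with 0.02 slack for sampling
error; permutation means within $3\,\mathrm{SE}$ of 0.5 over 200
permutations) use problem sizes of 60–300 concepts per species, chosen so
the full suite completes in seconds on one CPU.

## Known limitations

* The structural subsumption procedure covers only the flat
  (quality, entity) conjunction fragment; real definition files using
  modifiers or nested expressions would need skipping with counts.
* Lexical matching is strict; approximate matchers would find more seeds
  at the cost of auditability.
* The overlap category "nothing" is rare-to-absent on generated data
  because propagated entries share the target root whenever roots are
  retained; it occurs with `drop_roots` or on hand-built fixtures.
* Published headline counts and AUCs of real HP/MP alignments depend on
  specific ontology releases and annotation extracts and are out of scope
  at desk scale; the package targets the arithmetic of such summary
  tables and the qualitative relationships between the methods.
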