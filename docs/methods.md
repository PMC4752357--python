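# Methods

## Scope and design

The package implements the computational core of a logically defined
feeding-muscle anatomy ontology: a typed ontology model with an OBO-dialect
exchange format, an EL completion-rule reasoner with derivation traces, a
DL-query engine, a pre-reasoned-closure exporter, a programmatically built
fixture ontology with a per-axiom citation manifest, and an
ontology-expanded text search with a synthetic corpus generator. It is a
library first (`import muscle_logic`), with a thin `muscle-logic` CLI and
narrative scripts under `examples/`.

## The logic fragment

Class expressions are named classes, existential restrictions
(`property some filler`) and conjunctions — the EL fragment. There is no
negation, disjunction, cardinality or nominal support: muscle definitions
(attachments + innervation), grouping classes, and
innervation-implies-arch-origin GCIs all live inside EL, which keeps
classification polynomial. ⊤ is implicit (every class's subsumer); there is
no ⊥ and no disjointness. Cyclic subsumptions are legal and reported as
equivalence groups, per standard DL semantics.

Conjunctions are canonical at construction: flattened, deduplicated and
sorted by a structural key. This makes expression equality structural and
query conjunction trivially commutative.

## Normalization

Axioms are rewritten to the four normal forms NF1 `A ⊑ B`, NF2
`A₁ ⊓ A₂ ⊑ B`, NF3 `A ⊑ ∃r.B`, NF4 `∃r.A ⊑ B`. Equivalences split into both
inclusions first. Complex subexpressions are replaced by fresh names
`_:NF<n>` assigned in a fixed traversal order (FIFO over pending inclusion
pairs), and conjunctions are binarized left-to-right over the canonical
conjunct order, so normalization is deterministic for a given axiom list.
Fresh names are never serialized and are filtered from every reported
result. A definition with three existential conjuncts produces exactly
8 normal axioms (3 NF3, 3 NF4, 2 NF2); a GCI with existentials on both
sides produces an NF4/NF3 pair through one fresh intermediate. No
structural sharing is attempted — duplicate subexpressions get separate
fresh names; this costs a few extra axioms and keeps the rewriting a pure
function of the input order.

## Saturation

The reasoner computes the least fixpoint of:

* R1 `A'∈S(A), A'⊑B ⇒ B∈S(A)`
* R2 `A₁,A₂∈S(A), A₁⊓A₂⊑B ⇒ B∈S(A)`
* R3 `A'∈S(A), A'⊑∃r.B ⇒ (A,B)∈R(r)`
* R4 `(A,B)∈R(r), B'∈S(B), ∃r.B'⊑C ⇒ C∈S(A)`
* R5 `(A,B),(B,C)∈R(r), r transitive ⇒ (A,C)∈R(r)`
* R6 `(A,B)∈R(r), r⊑s ⇒ (A,B)∈R(s)`

The fixpoint is order-independent; the implementation uses a worklist keyed
by newly derived facts purely as a performance choice. Worst case is
polynomial: O(C²) subsumer entries and O(C²) role pairs per property, each
combined with each normal axiom a bounded number of times, i.e. roughly
O(C² · axioms) rule firings. R6 (property hierarchy) is included although
the fixture does not need it — imported relation sets routinely carry
sub-properties, and the rule is cheap.

Each fact records the rule and premises that first derived it; traces are
therefore well-founded by construction and replay bottom-up. The test suite
replays every reported subsumption of randomly generated ontologies through
an independent rule checker, and compares full subsumer sets against a
naive all-pairs fixpoint oracle that shares no code path or strategy with
the worklist reasoner. (An external reference reasoner is not part of the
test environment, so the oracle plus trace replay carry the soundness /
completeness evidence on their own.)

Query answering and complex-expression entailment both work by the standard
probe-class reduction: add `Q ≡ query` (or `Q_sub ⊑ sub`, `sup ⊑ Q_sup`)
and re-saturate the extended axiom set. Re-saturating from scratch (rather
than incrementally extending) keeps `answer` purely functional; at fixture
scale a full saturation is ~milliseconds, so the simplicity is free.

## The OBO dialect

Term and Typedef stanzas are standard OBO tags (`id`, `name`, `def`,
`synonym`, `xref`, `is_a`, `relationship`, `intersection_of`,
`is_transitive`). Two documented extensions carry the rest of EL:

* `[gci]` stanzas with `sub:`/`sup:` expression strings, because GCIs are
  not expressible in Term stanzas;
* an `equivalent_to: <expression>` Term tag for definitions that do not fit
  `intersection_of` lines — notably definitions that are bare conjunctions
  of existentials with no named genus, which is exactly the muscle
  template's shape.

Expression strings use the same grammar as DL queries (`and`, `some`,
quoted labels/synonyms/CURIEs; typographic quotes accepted; property names
match with spaces or underscores). One parser owns the grammar, so files
and queries round-trip identically. Output is deterministic — stanzas
sorted by CURIE, tags in fixed order — and `read ∘ write` is the structural
identity, property-tested over generated ontologies and cross-checked
against an independent OBO parser on the standard-tag subset.

Unknown Term tags are preserved as opaque annotations. Labels are unique
after case-folding (lowercase, whitespace collapse, typographic-quote
normalization); synonym lookup is the same fold, with ambiguity reported
rather than resolved silently.

## The fixture ontology and its two documented deltas

The fixture asserts only facts the published account states, each with a
citation tag in the manifest (`muscle_logic.fixture.manifest()`); widely
known anatomy that is not stated there is omitted (e.g. the facial-nerve
innervation of the buccinator — it carries an attachment axiom only).
Grouping classes carry full equivalence definitions
(`trigeminal muscle ≡ muscle organ ⊓ ∃innervated_by.'trigeminal nerve'`);
necessary-only axioms would not reproduce the automatic grouping, so
equivalence is the interpretation adopted. `mandible` and `mandible bone`
are one class with a synonym, as are the label variants of the masseter
pars reflexa and the zygomaticomandibularis infraorbital portion.

The three published competency tables are mutually inconsistent about two
classes: the conjunction table contains the transversus mandibulae (hence
it is a trigeminal muscle attached to the mandible) although the
attached-to-mandible table omits it, and the conjunction table omits the
mylohyoid although both single-feature tables contain it. Monotone
semantics cannot reproduce all three printed sets at once, so the fixture
encodes the logically consistent attachments: the mandible-attachment
answer is the printed 25 classes plus the transversus mandibulae (26), the
arch-1 answer is exactly the printed 20, and the conjunction answer is the
printed 16 plus the mylohyoid (17). The acceptance tests assert these sets
*and* the exact one-class deltas, rather than forcing either printed table.

Identifier scheme: the five published MFMO ids verbatim; stubs from
MFMO:0000400, muscles from MFMO:0000500 in table order, the detached
epiphysis/digit/hand demonstration from MFMO:0000600. Properties use their
conventional CURIEs (part_of BFO:0000050, attached_to RO:0002371,
innervated_by RO:0002005, develops_from RO:0002202); only part_of is
transitive.

## Closure export

`export_closure` classifies, then materializes the reflexive-transitive
subclass closure and, for each selected transitive property, **all**
entailed `A ⊑ ∃r.B` pairs over original classes — a superset of
asserted-plus-transitive-chains, since equivalence definitions also entail
role pairs. Selecting a non-transitive property is an explicit
configuration error (its closure semantics would differ). Reflexive pairs
are included by default (common for pre-reasoned database loaders) and
flagged inferred; every pair carries an asserted/inferred provenance flag.
TSV output is sorted `sub rel sup provenance`; OBO output materializes
pairs as direct tags and is a byte-level fixpoint of re-read + re-export.

## Semantic search and the synthetic corpus

Sentence splitting is a deterministic rule (sentence punctuation +
whitespace + uppercase/opening character); tokenization case-folds and
keeps intra-word hyphens; phrases match over token n-grams, longest match
wins, no overlapping tags; no stemming — synonyms must be explicit in the
ontology, keeping the lexicon an ontology artifact. Ranking is match count
with doc_id tie-break (determinism over relevance tuning). In keyword mode
a queried category degrades to its bare label phrase — exactly what a
literal engine would do with the same question — which makes the
semantic ⊇ keyword containment property well-defined. Both sentence and
document scopes are provided; tests fix the scope explicitly.

The generator emulates two document populations: relevant abstracts that
name a member of the target category through a template sentence (synonym
with probability `synonym_probability`, label otherwise, drawn with a
seeded RNG) plus a topical keyword, and distractors that contain the
query's individual words (muscle, nerve, trigeminal, mandible, attached,
mastication) scattered across sentences without forming any lexicon
phrase — the generator verifies this by scanning its own output and fails
rather than mislabel. Defaults are 50 relevant + 50 distractor documents
with `synonym_probability = 0.5`, a size at which binomial noise in the
literal-phrase fraction is visible but recall arithmetic stays exact.
What the generator does **not** emulate: real abstracts' vocabulary
breadth, inflection and typos, OCR noise, or multi-category documents —
so passing tests show that ontology expansion recovers every synonym
mention on clean text, not that the tagger is robust to noisy text.

## Numerical and procedural choices

* All randomness (generators, acceptance sweeps) flows from explicit seeds;
  hypothesis suites are derandomized.
* The acceptance script's sweep sizes — 200 random ontologies (≤30 classes,
  ≤60 axioms) against the naive oracle, 25 random DAGs (≤50 nodes) for the
  closure check, 100 round-trip ontologies, 100-document corpora — are the
  package's test conditions; each completes in seconds.
* Degenerate inputs: an empty ontology serializes to a header-only file; an
  empty corpus indexes to an empty index; a query for a childless class
  returns an empty descendant set; `conjunction_of` collapses a singleton.

## Known limitations

* No role chains beyond transitivity, no nominals, no datatype properties,
  no incremental reclassification.
* No OWL/RDF-XML parsing; the OBO dialect is the only exchange format.
* DL queries support conjunction and existentials only (no negation,
  disjunction or cardinality).
* The fixture is the published subset, not the full released ontology;
  classes not mentioned in the published account are absent.
* Search has no stemming or approximate matching by design; a synonym the
  ontology lacks is a synonym the search cannot expand.
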