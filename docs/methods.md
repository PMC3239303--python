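# Methods

This note documents the model implemented by `regevents`, the semantics
of its matching and inference steps, the design choices made where the
design was genuinely open, and what the synthetic corpora do and do not
demonstrate.

## Representation

Everything semantic is a **concept-rooted attribute structure**: a Gene
Regulation Ontology (GRO) concept plus a slot map over a fixed property
vocabulary (`hasAgent`, `hasPatient`, `hasPolarity`,
`hasPhysicalContact`, `hasPart`).  Slot values are entity references
(grounded mentions), string literals, or further structures — an event
participant may itself be an event, which is what "compositional event"
means here.  The same shape serves as pattern semantics, rule
condition/conclusion, extraction template and ground event; only which
value kinds are allowed differs (variables in patterns/rules/templates,
`polarity_sum` calls in rule conclusions).

The ontology is an is-a DAG (multiple parents allowed).  Subsumption is
the reflexive–transitive closure of the is-a relation; it backs every
"is-a-kind-of" decision in matching, inference and template selection.
The shipped miniature hierarchy places
`TranscriptionFactor ⊑ Protein ⊑ MolecularEntity`,
`RegulationOfTranscription ⊑ RegulationOfGeneExpression ⊑
RegulatoryProcess`, `Transcription ⊑ GeneExpression` and
`TranscriptionFactorBindingSiteOfDNA ⊑ RegulatoryDNARegion`.  The last
placement, and the position of `BindingOfTFToTFBindingSiteOfDNA`, are
declared defaults: a full GRO release would settle them, the miniature
file simply has to pick something consistent with the templates.

Ground structures have a canonical form — nested sorted tuples in which
an entity reference collapses to its grounding ID.  Canonical equality is
the event identity used for deduplication and for fixpoint detection;
using grounding IDs (not mention objects) is what lets two sentences
mentioning the same gene unify during cross-sentence inference.

## Named-entity recognition

Dictionary lookup, left-to-right longest match over contiguous tokens,
case-sensitive by default (bacterial gene vs protein symbols differ only
in case: *fimA*/FimA).  One surface form may carry several concept
labels — *himA* names both the gene and the DNA-binding protein it
encodes — and every downstream concept constraint accepts a mention if
*any* of its labels satisfies the constraint.  This metonymy convention
is what allows a `?Protein` template slot to bind a mention of a gene
name used for its product.  No fuzzy matching, abbreviation expansion or
species disambiguation is attempted.

## Loose pattern matching

A pattern pairs a syntactic tree fragment with a semantic structure over
shared variables.  The head item must match a token by lemma and coarse
POS.  Dependent items match **descendants** of the head-matched node
rather than only children — the point being that unmatched intervening
material (`sevenfold`, `fusion`, determiners) should not block an
otherwise clear event description — under three restrictive conditions:

1. **Role confinement.**  An item marked `Subject:`/`Object:` may bind a
   node only if some node on the path from the head down to it bears that
   syntactic role.  A `PrepObject` satisfies an `Object` requirement: in
   the Stanford-style representation used here the preposition heads its
   object, and "object of a preposition below the head" is exactly the
   configuration nominal patterns like `(lesion_Noun Object:Patient)`
   must reach through.
2. **Branch disjointness.**  Distinct branches of one pattern instance
   claim mutually non-dominating subtrees.  An item's *own* nested
   sub-items of course match inside its subtree; what is forbidden is two
   sibling branches consuming overlapping material.
3. **Clause boundaries.**  The head-to-candidate path may not cross a
   node whose lemma is a relative pronoun/complementizer (`which`,
   `that`, `because`, ...), a node having such a word as a direct child
   (the head of a relative clause), or an exception word (`except`,
   `unless`, `without`).  Both lists are configurable
   (`MatchConfig`); the defaults are a deliberately small, conservative
   set.

When several candidates satisfy an item, all assignments binding
*different* entities are kept — this is precisely how coordination
distributes ("himA or himD" yields one structure per conjunct, the
conjunct being a tree descendant of the first conjunct and inheriting its
role through condition 1).  Assignments binding the *same* entities
collapse onto the structurally preferred one (minimal depth, then
leftmost surface position), which prevents the ambiguity explosion where
a variable could bind a composed structure, the structure's head, or the
bare mention inside it — all denoting the same participant.

Composition is a post-order traversal.  Entity mentions seed their head
token with atomic semantics; each match instantiates its semantic
pattern with the semantics of the bound nodes and stacks the result on
the matched node, so later (higher) patterns can consume it.  All
matches accumulate — a node may carry several structures.  A structure
consumed as a slot filler is not emitted separately: the sentence's
explicit events are its *maximal* structures.  Negation is detected only
as a cue flag in provenance (`not`, `no`, `never` among the trigger's
children) and deliberately not interpreted.

## Inference

Rules are `P → Q` implications over the same structures, applied by
modus ponens: whenever every condition matches some event of the
document (conditions share variables, unified by canonical equality),
the instantiated conclusion is added as an inferred event.  Matching is
one-way and subsumptive — the event's concept must be at or below the
condition's concept, condition slots must be present with recursively
matching values, extra event slots are ignored.  Application repeats
until no new canonical event appears.

Two semantic choices deserve emphasis:

* **Missing polarity binds the default `positive`.**  Regulation verbs
  like *cause* or *regulate* carry no polarity of their own, yet the
  flattening rules must fire through them.  `positive` is the NXOR
  identity, so the default is inert: `polarity_sum(p, positive) = p`.
  `polarity_sum` itself is NXOR over {positive ↦ ⊤, negative ↦ ⊥}, with
  `unknown` absorbing; restricted to {positive, negative} it is a
  commutative group in which every element is its own inverse.
* **Conclusions inherit.**  A conclusion starts from the top-level slots
  of the event matched by the rule's *first* condition and then applies
  its explicit overrides.  A flattening rule thus rewrites one
  participant and the polarity while carrying the rest of the event
  forward; for fully-specified conclusions (the evidence-combination
  rule) inheritance is a no-op.  Without inheritance the flattening
  chain would discard the regulated patient at the first step and no
  database-shaped event could ever be derived from a cascade.

Closure scope is the document: a multi-condition rule may take its
supports from different sentences (binding-site evidence plus an
expression-regulation statement), which is the mechanism for
evidence combination without anaphora resolution.  Termination holds for
the shipped rules because no conclusion nests deeper than its
conditions; a configurable pass cap (default 100) guards user-supplied
rule files and raises rather than looping.  Inferred events carry the
rule ID and their supporting events, so every provenance chain bottoms
out in explicit events — the closure can add no fact that is not
grounded in text.

## Extraction, outputs and scoring

Templates are structures whose `?Concept` positions must bind entities
(label subsumption applies) and whose fixed parts restrict the event
under concept subsumption; explicit and inferred events are equally
eligible, and records deduplicate on (template, participants, polarity,
contact).  Records ground participants by dictionary ID, since database
comparison is ID-level.  Writers: nested JSON with provenance (the
round-trippable interchange format), BioNLP-style standoff (`.a1` entity
T-lines with 0-based half-open character offsets over
space-joined/newline-joined token text; `.a2` trigger T-lines, E-lines
and Polarity/PhysicalContact A-lines), and a flat edge TSV.

The scorer counts a prediction correct when document, agent ID and
patient ID agree with a gold record and the predicted event type is the
gold type or a sub-concept (a more specific prediction satisfies a more
general gold, not vice versa); polarity and contact are excluded from
correctness, following the standard two-participant criterion.  Credit
is assigned by maximum bipartite matching so a gold record is never
counted twice.  `unique` mode collapses per-document duplicates on
(document, agent, patient, type) before counting — the protocol for
database comparison, and the mode used by the corpus-level tests, where
one underlying fact may legitimately surface as several records (e.g. a
`RegulationOfTranscription` event also satisfies the more general
expression-regulation template).

## Synthetic corpora

The generator emits pre-parsed documents from five hand-written tree
skeletons (direct regulation, nominalized cascade, coordination,
cross-sentence binding pair, distractors), with synthetic name
inventories (`TF01`…, `g0001`…; the worked examples reserve himA, himD,
fimA) and per-record `requires_inference` flags.  Defaults: 20
documents, frame weights 0.25/0.2/0.15/0.2/0.2, 12 TFs, 30 genes; the
property tests and the acceptance script use 25–40 documents, sizes at
which every code path is exercised many times while the whole suite runs
in seconds.  Because trees are skeletons and the resources are
co-designed with the frames, the full pipeline recovers 100% of gold
records with zero false positives, and the no-inference run recovers
exactly the `requires_inference=false` subset.  That is a *consistency*
statement, not a corpus-performance claim: real abstracts bring parser
errors, anaphora, negation, dictionary gaps and vocabulary far beyond
the shipped nine patterns and four rules, none of which the generator
emulates.  What the synthetic ablation does demonstrate is the
qualitative direction — recall depends heavily on inference, precision
does not — and that the machinery (composition, NXOR polarity,
cross-sentence unification, subsumption scoring) behaves exactly as
specified.

## Numerical and degenerate-input choices

* Ontology files are validated on load: undeclared edge endpoints,
  unresolvable aliases, empty concept sets and is-a cycles are errors
  (the cycle is named).
* CoNLL input must be a tree: exactly one root, contiguous 1-based
  indices, no head cycles; multiword-token and empty-node lines are
  skipped.  Unknown POS tags and relations normalize to `Other`.
* Candidate ordering (depth, then surface position) makes matching
  deterministic for a fixed input; rule application order does not
  affect the closure because events are a canonical set.
* `evaluate` returns precision 0 (not NaN) when nothing was predicted.
* Matching is lemma-based and case-insensitive at the lemma level
  ("cause" matches "caused"); NER stays case-sensitive unless configured
  otherwise.

## Known limitations

No parsing (pre-parsed input only), no anaphora resolution, no negation
semantics, no pattern learning, and only the four published-style
inference rules plus a DSL for adding more.  The clause-boundary and
exception word lists are small defaults, not a linguistic inventory.
Standoff sub-events reuse their parent's trigger span, since composed
sub-structures do not retain their own trigger token.
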