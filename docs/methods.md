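# Methods

## The curation model

`biomap` treats a cross-resource mapping as a triple *(subject, predicate,
object)* over CURIE-identified entities, with `skos:exactMatch` (terms usable
interchangeably), `skos:broadMatch`, and `skos:narrowMatch` built in and
arbitrary CURIE predicates permitted. Entity identity is `(prefix,
identifier)`; names are display metadata only, so renaming a term never
changes what is asserted. Prefixes are lowercased on ingest.

Every stored mapping is canonical: for symmetric predicates the endpoints are
ordered lexicographically by `(prefix, identifier)`; for the broad/narrow
pair, reordering swaps the predicate for its inverse; an unknown asymmetric
predicate whose endpoints would need reordering is an error, because its
inverse is not known. The symmetric set defaults to `{skos:exactMatch}` and
can be extended (e.g. with a homology relation) through a small YAML config.
Canonical form makes a mapping and its mirror one assertion, which is what
the ledger keys on. Self-mappings are rejected at construction: nothing in
the pipeline produces them, and they would corrupt the graph checks.

Provenance is exactly one of: a curation record (curator ORCID matching
`dddd-dddd-dddd-ddd[dX]`, verdict in {positive, negative, unsure}) or a
prediction record (tool, method in {lexical, inferred-transitivity, other},
confidence in [0, 1], and, for multi-hop inferences, the intermediate CURIEs
of each path).

The ledger holds four insertion-ordered, duplicate-free collections —
positive, negative, unsure, predicted. Curation operations enforce pairwise
disjointness across collections; the file reader deliberately does not, so
that files containing a cross-file duplicate can still be loaded and the
duplicate reported by lint rather than crashing the load. Negative verdicts
are first-class data: they block re-prediction and drive the unstable-clique
check, and the SSSOM export keeps them flagged (`predicate_modifier=Not`)
instead of dropping them. A verdict on an already-curated key is rejected;
reversing a curation requires explicit deletion first, which keeps replay
semantics unambiguous.

## Lexical matching

Matching is exact string lookup under three transformations, not fuzzy
search. `normalize_string` applies Unicode NFKC, spells out the 24 Greek
letters (both cases, plus the micro sign) as lowercase English names,
lowercases, and collapses whitespace; hyphens survive. The dash-stripped form
additionally removes hyphen/dash characters. An index registers every label
and synonym under all three forms; a query is tried raw first, then
normalized, then dash-stripped, and candidates are taken from the strongest
form that hits.

Scores come from a fixed table — raw/label 1.00, raw/synonym 0.95,
normalized/label 0.90, normalized/synonym 0.85, dash-stripped/label 0.80,
dash-stripped/synonym 0.75 — evaluated at the *weaker* of the transformation
the query needed and the transformation that produced the index key. The
table is this package's own definition: it is deterministic, explainable,
and ordered by the string-variation classes that dominate vocabulary
mismatches (case, Greek spelling, dashes), in place of a trained scoring
model. Ties are broken by ascending CURIE, so grounding is reproducible.

Cross-vocabulary prediction grounds every lexicalization of every source
term against the target index, keeps the best score per (source term, target
term) pair, and emits canonical `skos:exactMatch` predictions at or above
the threshold. The default threshold 0.70 admits all tiers; raising it can
only remove predictions. A source term may map to several targets — the
duplicate-prefix motif, not the matcher, is where competing candidates are
resolved, by a curator. Aligning a vocabulary against itself is rejected as
a different task.

`derive_cell_line_label` implements the naming convention of cell-line
catalogs that postpend a tissue of origin after an underscore
(`CL14_LARGE_INTESTINE` → `CL14`); it simply takes the part before the first
underscore and passes underscore-free names through.

## Consistency checking

The positive and negative `skos:exactMatch` curations form a labeled
undirected graph (other predicates are ignored; predicted edges join the
positive side only on request, since it is a policy question whether
unreviewed predictions should participate). Because equivalence is
transitive, a connected component of the positive subgraph — not just a
triangle — is the semantic unit; the three motifs are evaluated per
component:

* **duplicate prefix**: ≥ 2 nodes of one component share a prefix → one of
  them is mapped incorrectly; one report per (component, prefix).
* **incomplete clique**: every unordered pair of component members with
  distinct prefixes, no existing positive edge, and no negative edge is
  proposed as an inferred `exactMatch` with fixed confidence 0.95 ("high
  confidence" made concrete; the value is a label for inferred provenance,
  not a calibrated probability). Same-prefix pairs are never proposed — they
  are the duplicate-prefix motif's business.
* **unstable clique**: every negative edge whose endpoints are positively
  connected is reported with one shortest positive path as the witness.

These detectors are pure and deterministic, with report order keyed on the
component's minimum CURIE. The test suite checks them against hand-rolled
brute-force oracles (union-find over exhaustive pair enumeration) on
hundreds of random graphs.

Multi-hop inference composes chains through an explicit *ordered* list of
mapping collections (hop 1 from the first, hop 2 from the second, …), rather
than searching an arbitrary graph: this mirrors how release-to-release
alignments are actually chained (e.g. CCLE→Cellosaurus→EFO) and keeps the
path provenance legible. Edges are undirected within a hop, chains never
revisit a node, endpoint pairs reachable by several paths are emitted once
with all paths recorded, and `max_hops` greater than the number of supplied
collections is an error.

## Prioritization and evaluation

`prioritize_by_frequency` sorts unmapped terms by usage count (ties by
ascending CURIE, for reproducible queues) and returns the shortest prefix of
that order whose cumulative count reaches the coverage target — the "terms
worth curating first" set. Coverage 0 selects nothing; a zero total with a
positive target is an error rather than a silent empty answer.
`sample_for_evaluation` draws a uniform, seed-determined sample without
replacement for unbiased precision estimation. `score_predictions` reports
precision/recall/F1 against a truth key set, with empty denominators
reported as null, never as 0/0.

## The synthetic generator

`generate_vocabulary_pair` builds two vocabularies over pronounceable
CV-syllable nonsense tokens (globally unique within a run), one variant
operation sampled per shared concept:

| op | A side | B side | expected match |
|---|---|---|---|
| identity | `doma duma` | same | raw, 1.00 |
| case | `vife modeno` | `VIFE MODENO` | normalized, 0.90 |
| greek | `gri-β zam` | `gri-beta zam` | normalized, 0.90 |
| dash | `madu-lubu` | `madulubu` | dash-stripped, 0.80 |
| synonym_only | label | unrelated label, A's label as synonym | synonym tier ≤ 0.95 |
| pluralize | `foo bar` | `foo bars` | deliberate miss |

`pluralize` is intentionally not normalization-invariant: it generates
realistic misses and feeds the negative-curation path. Decoys copy an A
label and replace its final token with a numeral — near misses that share a
stem without being equal, so they can never shadow a true match. Everything
is determined by the spec's seed.

What the generator does *not* emulate: real synonym breadth and ambiguity
(one string naming several entities across resources), hierarchical
broad/narrow structure, abbreviations and word-order variation, or term
obsolescence across releases. Perfect synthetic precision/recall therefore
demonstrates that the machinery is correct under the declared variation
classes, not that real vocabulary alignment is this clean — on real data the
matcher surfaces candidates whose final status is the curator's call.

## File formats and determinism

The four ledger files are UTF-8, tab-separated, single-header TSV. The
writer emits a fixed header (`subject_prefix … type, source`, plus
`confidence` in the predicted file), rows sorted bytewise on (subject CURIE,
predicate, object CURIE), LF endings — so `write∘read∘write = write` holds
at the byte level and diffs under version control are minimal. The reader
matches headers by normalized name and accepts the common
`source_*/target_*/relation` dialect. Confidences are serialized via `repr`
after rounding to 10 decimal places, which round-trips floats exactly.

SSSOM export collates all four collections into one TSV with a YAML-style
`#` header block (CURIE map, license, set id) and the standard columns;
curated rows carry `semapv:ManualMappingCuration` and the curator ORCID,
lexical predictions `semapv:LexicalMatching` with tool and confidence,
inferred ones `semapv:ChainedMapping`. A minimal generic SSSOM reader is
included for round-trip verification only; the four-file ledger remains the
primary store.

Lint checks prefixes and identifiers against a local prefix→regex registry
(unknown prefixes are themselves violations), canonical orientation, and
cross-file duplicates. Ledger summaries count per collection, predicate,
unordered prefix pair, and curator; curated and predicted scopes are
reported separately rather than folded into one number.

## Problem sizes and verification

The acceptance script exercises: ten 200-concept vocabulary pairs (plus one
with 20 decoys) for lexical recovery; 200 random graphs of ≤ 50 nodes for
motif/oracle agreement; one 10,000-mapping ledger for byte-level round-trip
and SSSOM re-import; 100 random weight tables for prioritizer minimality; a
600-concept pair with decoys and synonym-only variants for the seeded
100-prediction evaluation sample; and a 60-verdict replay for conservation
and determinism. These sizes give stable, fast, fully offline checks; all
randomness derives from the script's `--seed`.

The loader is additionally validated against a pinned public release of a
real curated ledger (four files, ~51k mappings); that check needs the
archive downloaded locally and fails where it is absent.

## Known limitations

* Exact-lookup retrieval: no edit-distance or abbreviation matching, and no
  organism- or context-aware disambiguation.
* Broad/narrow semantics extend only to predicate inversion; no reasoning
  over hierarchies.
* The unstable-clique check reports conflicts but does not decide which edge
  is wrong; repair is the curator's job.
* Inferred confidence is a constant, not a function of path length or edge
  confidences.
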