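# biomap

Identifier resources — ontologies, taxonomies, and controlled vocabularies
such as ChEBI, MeSH, HGNC, EFO, or Cellosaurus — overlap in scope, and the
same biomedical entity (a chemical, a gene, a disease, a cell line) often
carries a different identifier in each. `biomap` is a toolkit for predicting
the missing equivalences between such resources, reviewing them with full
provenance, and keeping the result consistent. It is aimed at ontology and
knowledge-graph curators who need cross-references that are versionable,
auditable, and exportable in the community-standard SSSOM format.

The package provides:

* **a self-contained lexical matcher** — labels and synonyms of one
  vocabulary are indexed under their raw, normalized (Unicode-folded,
  Greek letters spelled out, lowercased), and dash-stripped forms; strings
  from a second vocabulary are grounded against the index and scored by a
  fixed tier table (exact label 1.00 down to dash-stripped synonym 0.75),
  yielding `skos:exactMatch` predictions with confidences;
* **a four-collection ledger** — positive, negative, and unsure human
  curations plus machine predictions, stored in four TSV files with
  deterministic, diff-friendly byte layout; every mapping is canonicalized
  (mirror orientations collapse, `skos:broadMatch`/`narrowMatch` invert) and
  carries either a curator ORCID or a tool/confidence record;
* **graph-motif consistency checks** — the positive/negative exactMatch
  graph is scanned for duplicate-prefix components (one node is mapped
  wrongly), incomplete cliques (a missing mapping is proposable by
  transitivity of equivalence), and unstable cliques (a negative edge inside
  a positively connected component);
* **multi-hop inference** — composing exactMatch chains across an ordered
  list of mapping sets (e.g. CCLE→Cellosaurus→EFO) with per-path provenance;
* **curation-effort tools** — novelty filtering against existing and primary
  mappings, scope filters, a frequency-weighted prioritizer (smallest set of
  terms covering e.g. 80% of unmapped instances), and seeded sampling for
  unbiased precision estimates;
* **a synthetic benchmark generator** — vocabulary pairs with a known answer
  key and controllable lexical variation (case, Greek letters, dashes,
  synonym-only overlap, pluralization, near-miss decoys), so the entire
  pipeline is testable offline.

## Worked example

Generate a synthetic vocabulary pair whose B side varies by capitalization,
Greek spelling, and dashes, then predict mappings:

```console
$ biomap simulate --n-shared 100 --decoys 10 --ops case,greek,dash --seed 7 -o simdir/
wrote 100 + 110 terms, 100 truth mappings
$ biomap predict --source simdir/vocabulary_a.tsv --target simdir/vocabulary_b.tsv \
      --threshold 0.7 -o predicted.tsv
wrote 100 predictions to predicted.tsv
$ head -3 predicted.tsv
subject_prefix	subject_identifier	subject_name	predicate	object_prefix	object_identifier	object_name	type	source	confidence
mocka	1	madu-lubu	skos:exactMatch	mockb	1	madulubu	semapv:LexicalMatching	biomap-lexical	0.8
mocka	10	vife modeno	skos:exactMatch	mockb	10	VIFE MODENO	semapv:LexicalMatching	biomap-lexical	0.9
```

All 100 true pairs are recovered and none of the 10 decoys produce a false
positive: the dash variant (`madu-lubu` ↔ `madulubu`) matches at the
dash-stripped tier (confidence 0.8), the case variant at the normalized tier
(0.9). The same machinery grounds free text:

```pycon
>>> from biomap import EntityReference, Term, Vocabulary, build_index, ground
>>> kras = Term(reference=EntityReference(prefix="hgnc", identifier="6407", name="KRAS"),
...             label="KRAS", synonyms=("K-Ras", "KRAS2"))
>>> (match,) = ground("k-ras", build_index(Vocabulary(prefix="hgnc", terms=(kras,))))
>>> match.reference.curie, match.score, match.lexical_status
('hgnc:6407', 0.85, 'synonym')
```

The query needed normalization and hit a synonym, so it scores at the
normalized/synonym tier (0.85). Verdicts are applied non-interactively from
a TSV log (`biomap curate apply verdicts.tsv --ledger ledger/`), moving each
prediction into the positive, negative, or unsure collection with the
curator's ORCID attached; `biomap check` writes the motif report and
`biomap export-sssom` collates all four collections into one SSSOM document
in which negative curations are flagged with `predicate_modifier=Not` rather
than dropped.

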