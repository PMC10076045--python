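"""Self-contained lexical matcher: normalization, indexing, grounding, prediction.

Retrieval works on three progressively looser string transformations ("tiers"):
the raw string, a normalized form (Unicode compatibility normalization, Greek
letters spelled out, lowercased, whitespace collapsed), and a dash-stripped
normalized form.  Matches are scored from a fixed table ordered by tier and by
whether the matched lexicalization is the term's preferred label or a synonym:

======================  =====
raw / label              1.00
raw / synonym            0.95
normalized / label       0.90
normalized / synonym     0.85
dash-stripped / label    0.80
dash-stripped / synonym  0.75
======================  =====

The score of a hit is taken at the weaker of the transformation that the query
needed and the transformation that produced the index key, so e.g. the query
"k-ras" against a synonym "K-Ras" scores as a normalized/synonym match (0.85).
"""

from __future__ import annotations

import csv
import json
import re
import unicodedata
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Literal, Optional, Tuple

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .core import EXACT_MATCH, EntityReference, PredictionMetadata, SemanticMapping, canonicalize

__all__ = [
    "Term",
    "Vocabulary",
    "LexicalIndex",
    "Match",
    "TIER_SCORES",
    "DEFAULT_THRESHOLD",
    "normalize_string",
    "dash_strip",
    "build_index",
    "ground",
    "predict_mappings",
    "derive_cell_line_label",
    "read_vocabulary",
    "write_vocabulary",
]

# Greek codepoints (both cases, plus final sigma and the micro sign) to their
# spelled-out lowercase English names.
_GREEK_NAMES = {
    "α": "alpha", "β": "beta", "γ": "gamma", "δ": "delta", "ε": "epsilon",
    "ζ": "zeta", "η": "eta", "θ": "theta", "ι": "iota", "κ": "kappa",
    "λ": "lambda", "μ": "mu", "ν": "nu", "ξ": "xi", "ο": "omicron",
    "π": "pi", "ρ": "rho", "σ": "sigma", "ς": "sigma", "τ": "tau",
    "υ": "upsilon", "φ": "phi", "χ": "chi", "ψ": "psi", "ω": "omega",
}
_GREEK_TABLE = {}
for _ch, _name in _GREEK_NAMES.items():
    _GREEK_TABLE[ord(_ch)] = _name
    _GREEK_TABLE[ord(_ch.upper())] = _name
_GREEK_TABLE[0x00B5] = "mu"  # micro sign; NFKC folds it to U+03BC anyway

_WS_RE = re.compile(r"\s+")
_DASHES = "-‐‑‒–—"

Tier = Literal["raw", "normalized", "dash-stripped"]
_TIER_RANK: Dict[str, int] = {"raw": 0, "normalized": 1, "dash-stripped": 2}
_TIERS: Tuple[Tier, ...] = ("raw", "normalized", "dash-stripped")

#: Fixed deterministic score table, keyed by (tier, lexical status).
TIER_SCORES: Dict[Tuple[str, str], float] = {
    ("raw", "label"): 1.00,
    ("raw", "synonym"): 0.95,
    ("normalized", "label"): 0.90,
    ("normalized", "synonym"): 0.85,
    ("dash-stripped", "label"): 0.80,
    ("dash-stripped", "synonym"): 0.75,
}

#: Default prediction threshold; admits every tier of the score table.
DEFAULT_THRESHOLD = 0.70


def normalize_string(s: str) -> str:
    """Normalize a lexicalization for matching; idempotent.

    Applies Unicode NFKC, spells out Greek letters ("Amyloid-β" becomes
    "amyloid-beta"), lowercases, collapses internal whitespace and strips the
    ends.  Hyphens are preserved (the dash-stripped tier removes them).
    """
    s = unicodedata.normalize("NFKC", s)
    s = s.translate(_GREEK_TABLE)
    s = s.lower()
    s = _WS_RE.sub(" ", s).strip()
    return s


def dash_strip(s: str) -> str:
    """Remove hyphen/dash characters (applied after :func:`normalize_string`)."""
    return s.translate({ord(c): None for c in _DASHES})


class Term(BaseModel):
    """A vocabulary entry: an entity reference with its label and synonyms."""

    model_config = ConfigDict(frozen=True)

    reference: EntityReference
    label: str
    synonyms: Tuple[str, ...] = ()

    @field_validator("label")
    @classmethod
    def _label_nonempty(cls, v: str) -> str:
        if not v:
            raise ValueError("label must be non-empty")
        return v

    def lexicalizations(self) -> Iterable[Tuple[str, str]]:
        """Yield (text, status) pairs; status is 'label' or 'synonym'."""
        yield self.label, "label"
        for synonym in self.synonyms:
            yield synonym, "synonym"


class Vocabulary(BaseModel):
    """All terms of one identifier resource."""

    model_config = ConfigDict(frozen=True)

    prefix: str
    terms: Tuple[Term, ...]

    @model_validator(mode="after")
    def _check_terms(self) -> "Vocabulary":
        seen = set()
        for term in self.terms:
            if term.reference.prefix != self.prefix:
                raise ValueError(
                    f"term {term.reference.curie} does not share vocabulary prefix {self.prefix!r}"
                )
            if term.reference.identifier in seen:
                raise ValueError(f"duplicate identifier {term.reference.identifier!r}")
            seen.add(term.reference.identifier)
        return self

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class IndexEntry:
    reference: EntityReference
    lexical_status: str  # label | synonym
    tier: str  # raw | normalized | dash-stripped
    source_text: str  # the original label/synonym string


@dataclass
class LexicalIndex:
    """Lookup from transformed lexicalization strings to the terms bearing them."""

    prefix: str
    entries: Dict[str, List[IndexEntry]] = field(default_factory=dict)

    def _register(self, key: str, entry: IndexEntry) -> None:
        if not key:
            return
        bucket = self.entries.setdefault(key, [])
        if entry not in bucket:
            bucket.append(entry)

    def lookup(self, key: str) -> List[IndexEntry]:
        return self.entries.get(key, [])


def build_index(vocab: Vocabulary) -> LexicalIndex:
    """Index every label and synonym under its raw, normalized, and
    dash-stripped-normalized forms."""
    index = LexicalIndex(prefix=vocab.prefix)
    for term in vocab.terms:
        for text, status in term.lexicalizations():
            norm = normalize_string(text)
            stripped = dash_strip(norm)
            ref = term.reference
            index._register(text, IndexEntry(ref, status, "raw", text))
            index._register(norm, IndexEntry(ref, status, "normalized", text))
            index._register(stripped, IndexEntry(ref, status, "dash-stripped", text))
    return index


class Match(BaseModel):
    """One scored grounding candidate."""

    model_config = ConfigDict(frozen=True)

    reference: EntityReference
    score: float
    matched_text: str
    lexical_status: str


def ground(s: str, index: LexicalIndex) -> List[Match]:
    """Ground a free-text string against an index; ranked, deterministic.

    Candidates are retrieved at the strongest query transformation that hits
    the index; each hit is scored at the weaker of the query tier and the tier
    that created the index key, then sorted by (score desc, CURIE asc).
    """
    forms = {"raw": s, "normalized": normalize_string(s)}
    forms["dash-stripped"] = dash_strip(forms["normalized"])
    for query_tier in _TIERS:
        entries = index.lookup(forms[query_tier])
        if not entries:
            continue
        best: Dict[Tuple[str, str], Match] = {}
        for entry in entries:
            effective = max(_TIER_RANK[query_tier], _TIER_RANK[entry.tier])
            score = TIER_SCORES[(_TIERS[effective], entry.lexical_status)]
            key = (entry.reference.prefix, entry.reference.identifier)
            prev = best.get(key)
            if prev is None or score > prev.score:
                best[key] = Match(
                    reference=entry.reference,
                    score=score,
                    matched_text=entry.source_text,
                    lexical_status=entry.lexical_status,
                )
        return sorted(best.values(), key=lambda m: (-m.score, m.reference.curie))
    return []


def predict_mappings(
    source: Vocabulary,
    target: Vocabulary,
    threshold: float = DEFAULT_THRESHOLD,
    tool: str = "biomap-lexical",
) -> List[SemanticMapping]:
    """Predict skos:exactMatch mappings from ``source`` terms into ``target``.

    Every lexicalization of every source term is grounded against the target
    index; the best score per (source term, target term) pair is kept, and
    pairs at or above ``threshold`` become canonical predictions with the
    score as confidence.
    """
    if source.prefix == target.prefix:
        raise ValueError(
            f"source and target share prefix {source.prefix!r}; self-alignment is a different task"
        )
    index = build_index(target)
    best: Dict[Tuple[EntityReference, EntityReference], float] = {}
    for term in source.terms:
        for text, _status in term.lexicalizations():
            for match in ground(text, index):
                pair = (term.reference, match.reference)
                if best.get(pair, -1.0) < match.score:
                    best[pair] = match.score
    predictions = [
        canonicalize(
            SemanticMapping(
                subject=subject,
                predicate=EXACT_MATCH,
                object=obj,
                provenance=PredictionMetadata(tool=tool, method="lexical", confidence=score),
            )
        )
        for (subject, obj), score in best.items()
        if score >= threshold
    ]
    return sorted(predictions, key=lambda m: m.key)


def derive_cell_line_label(raw_name: str) -> str:
    """Strip a tissue-of-origin suffix from a cell-line name.

    Cell-line catalogs often postpend the tissue of origin after an underscore
    (e.g. ``CL14_LARGE_INTESTINE``); the cell line name is the part before the
    first underscore.  Names without an underscore pass through unchanged.
    """
    return raw_name.split("_", 1)[0]


# -- vocabulary files ------------------------------------------------------

_VOCAB_HEADER = ["prefix", "identifier", "label", "synonyms"]


def read_vocabulary(path) -> Vocabulary:
    """Read a vocabulary from TSV (header: prefix, identifier, label, synonyms
    pipe-delimited) or from the JSON equivalent."""
    path = str(path)
    if path.endswith(".json"):
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        terms = tuple(
            Term(
                reference=EntityReference(
                    prefix=data["prefix"], identifier=t["identifier"], name=t["label"]
                ),
                label=t["label"],
                synonyms=tuple(t.get("synonyms", [])),
            )
            for t in data["terms"]
        )
        return Vocabulary(prefix=data["prefix"], terms=terms)
    terms_list: List[Term] = []
    prefix: Optional[str] = None
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            prefix = prefix or row["prefix"]
            synonyms = tuple(s for s in (row.get("synonyms") or "").split("|") if s)
            terms_list.append(
                Term(
                    reference=EntityReference(
                        prefix=row["prefix"], identifier=row["identifier"], name=row["label"]
                    ),
                    label=row["label"],
                    synonyms=synonyms,
                )
            )
    if prefix is None:
        raise ValueError(f"empty vocabulary file: {path}")
    return Vocabulary(prefix=prefix, terms=tuple(terms_list))


def write_vocabulary(vocab: Vocabulary, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_VOCAB_HEADER)
        for term in vocab.terms:
            writer.writerow(
                [vocab.prefix, term.reference.identifier, term.label, "|".join(term.synonyms)]
            )
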