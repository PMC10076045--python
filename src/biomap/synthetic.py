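"""Synthetic vocabulary pairs with known ground truth, plus precision/recall scoring.

The generator emulates the lexical variation found between real biomedical
vocabularies — capitalization differences, Greek letters versus their
spelled-out forms, dashes, synonym-only overlap, and pluralization — over
pronounceable nonsense tokens, so the full predict-filter-curate pipeline can
be exercised with no downloads and an exactly known answer key.

Variant semantics (applied to the B-side surface form of a shared concept):

* ``identity``   — same string on both sides (raw-tier match);
* ``case``       — upper-cased (normalized-tier match);
* ``greek``      — a Greek letter on side A is spelled out on side B
  (normalized-tier match);
* ``dash``       — the hyphen of a hyphenated A label is dropped
  (dash-stripped-tier match);
* ``synonym_only`` — B's label is unrelated but A's label appears among B's
  synonyms (synonym-status match);
* ``pluralize``  — B appends an "s"; deliberately NOT normalization-invariant,
  producing a realistic miss that exercises the negative-curation path.

Decoys are B-side near-miss traps: an A label with its final token replaced
by a numeral, risking a collision without equality.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .core import (
    EXACT_MATCH,
    CurationMetadata,
    EntityReference,
    MappingKey,
    MappingLedger,
    PredictionMetadata,
    SemanticMapping,
    canonicalize,
    mapping_key,
)
from .lexical import Term, Vocabulary

__all__ = [
    "VARIANT_OPS",
    "SyntheticSpec",
    "EvaluationResult",
    "generate_vocabulary_pair",
    "score_predictions",
    "generate_ledger",
]

VARIANT_OPS = frozenset({"identity", "case", "greek", "dash", "synonym_only", "pluralize"})

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"
_GREEK_CHOICES = [("α", "alpha"), ("β", "beta"), ("γ", "gamma"), ("κ", "kappa")]


class SyntheticSpec(BaseModel):
    """Parameters of one synthetic vocabulary pair."""

    model_config = ConfigDict(frozen=True)

    n_shared: int = Field(ge=0, description="true-equivalent concept pairs")
    n_unique_a: int = Field(default=0, ge=0)
    n_unique_b: int = Field(default=0, ge=0)
    n_decoys: int = Field(default=0, ge=0, description="near-miss traps on side B")
    variant_ops: FrozenSet[str] = frozenset({"identity"})
    seed: int = 0
    prefix_a: str = "mocka"
    prefix_b: str = "mockb"

    @model_validator(mode="after")
    def _check(self) -> "SyntheticSpec":
        unknown = self.variant_ops - VARIANT_OPS
        if unknown:
            raise ValueError(f"unknown variant ops: {sorted(unknown)}")
        if self.n_shared > 0 and not self.variant_ops:
            raise ValueError("variant_ops must be non-empty when n_shared > 0")
        return self


def _token(rng: random.Random, used: Set[str]) -> str:
    """A unique pronounceable CV-syllable token."""
    while True:
        n = rng.randint(2, 4)
        tok = "".join(rng.choice(_CONSONANTS) + rng.choice(_VOWELS) for _ in range(n))
        if tok not in used:
            used.add(tok)
            return tok


@dataclass(frozen=True)
class _Concept:
    label_a: str
    label_b: str
    synonyms_b: Tuple[str, ...]
    op: str


def _make_concept(op: str, rng: random.Random, used: Set[str]) -> _Concept:
    t1, t2 = _token(rng, used), _token(rng, used)
    if op == "dash":
        label_a = f"{t1}-{t2}"
        return _Concept(label_a, f"{t1}{t2}", (), op)
    if op == "greek":
        char, name = rng.choice(_GREEK_CHOICES)
        label_a = f"{t1}-{char} {t2}"
        return _Concept(label_a, f"{t1}-{name} {t2}", (), op)
    label_a = f"{t1} {t2}"
    if op == "identity":
        return _Concept(label_a, label_a, (), op)
    if op == "case":
        return _Concept(label_a, label_a.upper(), (), op)
    if op == "pluralize":
        return _Concept(label_a, label_a + "s", (), op)
    if op == "synonym_only":
        label_b = f"{_token(rng, used)} {_token(rng, used)}"
        return _Concept(label_a, label_b, (label_a,), op)
    raise ValueError(op)  # pragma: no cover


def generate_vocabulary_pair(
    spec: SyntheticSpec,
) -> Tuple[Vocabulary, Vocabulary, Set[MappingKey]]:
    """Two vocabularies with a known truth set of exactMatch mapping keys.

    Fully determined by ``spec.seed``; ``len(truth) == spec.n_shared``.
    Truth keys are canonical, so they compare directly against the keys of
    :func:`biomap.lexical.predict_mappings` output.
    """
    rng = random.Random(spec.seed)
    used: Set[str] = set()
    ops = sorted(spec.variant_ops)

    terms_a: List[Term] = []
    terms_b: List[Term] = []
    truth: Set[MappingKey] = set()

    def ref(prefix: str, i: int, name: str) -> EntityReference:
        return EntityReference(prefix=prefix, identifier=str(i), name=name)

    next_a = next_b = 1
    shared_a_labels: List[str] = []
    for _ in range(spec.n_shared):
        concept = _make_concept(rng.choice(ops), rng, used)
        ref_a = ref(spec.prefix_a, next_a, concept.label_a)
        ref_b = ref(spec.prefix_b, next_b, concept.label_b)
        next_a += 1
        next_b += 1
        terms_a.append(Term(reference=ref_a, label=concept.label_a))
        terms_b.append(
            Term(reference=ref_b, label=concept.label_b, synonyms=concept.synonyms_b)
        )
        shared_a_labels.append(concept.label_a)
        truth.add(
            mapping_key(
                canonicalize(
                    SemanticMapping(
                        subject=ref_a,
                        predicate=EXACT_MATCH,
                        object=ref_b,
                        provenance=PredictionMetadata(tool="truth", confidence=1.0),
                    )
                )
            )
        )

    for _ in range(spec.n_unique_a):
        label = f"{_token(rng, used)} {_token(rng, used)}"
        terms_a.append(Term(reference=ref(spec.prefix_a, next_a, label), label=label))
        next_a += 1
    for _ in range(spec.n_unique_b):
        label = f"{_token(rng, used)} {_token(rng, used)}"
        terms_b.append(Term(reference=ref(spec.prefix_b, next_b, label), label=label))
        next_b += 1

    decoy_labels: Set[str] = set()
    for _ in range(spec.n_decoys):
        source = rng.choice(shared_a_labels) if shared_a_labels else _token(rng, used)
        tokens = source.split(" ")
        while True:
            numeral = str(rng.randint(10, 999))
            label = " ".join(tokens[:-1] + [numeral]) if len(tokens) > 1 else f"{source} {numeral}"
            if label not in decoy_labels:
                decoy_labels.add(label)
                break
        terms_b.append(Term(reference=ref(spec.prefix_b, next_b, label), label=label))
        next_b += 1

    vocab_a = Vocabulary(prefix=spec.prefix_a, terms=tuple(terms_a))
    vocab_b = Vocabulary(prefix=spec.prefix_b, terms=tuple(terms_b))
    return vocab_a, vocab_b, truth


@dataclass(frozen=True)
class EvaluationResult:
    """Precision/recall of predictions against a truth key set.

    Undefined ratios (empty denominator) are None, never silently 0/0.
    """

    tp: int
    fp: int
    fn: int
    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]


def score_predictions(
    predictions: Sequence[SemanticMapping],
    truth: Set[MappingKey],
) -> EvaluationResult:
    predicted_keys = {mapping_key(m) for m in predictions}
    tp = len(predicted_keys & truth)
    fp = len(predicted_keys - truth)
    fn = len(truth - predicted_keys)
    precision = tp / (tp + fp) if (tp + fp) else None
    recall = tp / (tp + fn) if (tp + fn) else None
    if precision and recall:
        f1 = 2 * precision * recall / (precision + recall)
    elif precision is None or recall is None:
        f1 = None
    else:
        f1 = 0.0
    return EvaluationResult(tp=tp, fp=fp, fn=fn, precision=precision, recall=recall, f1=f1)


_FAKE_PREFIXES = ("alpha", "bravo", "chem", "dis", "enz")
_FAKE_ORCIDS = ("0000-0001-0000-0001", "0000-0002-0000-0002", "0000-0003-0000-000X")


def generate_ledger(
    n_positive: int = 10,
    n_negative: int = 3,
    n_unsure: int = 1,
    n_predicted: int = 20,
    seed: int = 0,
) -> MappingLedger:
    """A random but valid ledger over a handful of fake prefixes.

    Used for round-trip, lint, and curation-replay testing; every mapping is
    exactMatch with plausible provenance, and keys never collide across the
    four collections.
    """
    rng = random.Random(seed)
    ledger = MappingLedger()
    counts = {
        "positive": n_positive,
        "negative": n_negative,
        "unsure": n_unsure,
        "predicted": n_predicted,
    }
    for collection, count in counts.items():
        made = 0
        while made < count:
            p1, p2 = rng.sample(_FAKE_PREFIXES, 2)
            subject = EntityReference(
                prefix=p1, identifier=str(rng.randint(1, 10 * (sum(counts.values()) + 1))),
                name=f"{p1} term",
            )
            obj = EntityReference(
                prefix=p2, identifier=str(rng.randint(1, 10 * (sum(counts.values()) + 1))),
                name=f"{p2} term",
            )
            if subject.pair() == obj.pair():
                continue
            if collection == "predicted":
                provenance = PredictionMetadata(
                    tool="biomap-lexical", method="lexical",
                    confidence=round(rng.uniform(0.7, 1.0), 4),
                )
            else:
                provenance = CurationMetadata(
                    curator_orcid=rng.choice(_FAKE_ORCIDS), verdict=collection
                )
            mapping = SemanticMapping(
                subject=subject, predicate=EXACT_MATCH, object=obj, provenance=provenance
            )
            if ledger.find(mapping_key(canonicalize(mapping))) is not None:
                continue
            ledger.add(mapping, collection)
            made += 1
    return ledger
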