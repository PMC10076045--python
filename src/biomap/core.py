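"""Core data model: entities, semantic mappings, provenance, and the four-collection ledger.

Identity of an entity is its CURIE (``prefix:identifier``); names are display
metadata only.  A mapping is a subject-predicate-object triple whose provenance
is either a human curation (ORCID + verdict) or a prediction (tool, method,
confidence).  Mappings are stored in *canonical* form so that a mapping and its
mirror count as one assertion.
"""

from __future__ import annotations

import re
from typing import Iterable, Iterator, Literal, Optional, Tuple, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "EXACT_MATCH",
    "BROAD_MATCH",
    "NARROW_MATCH",
    "DEFAULT_SYMMETRIC",
    "INVERSE_PREDICATES",
    "EntityReference",
    "CurationMetadata",
    "PredictionMetadata",
    "SemanticMapping",
    "MappingKey",
    "MappingLedger",
    "BiomapError",
    "DuplicateMappingError",
    "UnknownPredicateError",
    "canonicalize",
    "mapping_key",
    "mirror",
    "load_predicate_config",
]

EXACT_MATCH = "skos:exactMatch"
BROAD_MATCH = "skos:broadMatch"
NARROW_MATCH = "skos:narrowMatch"

#: Directional predicates whose orientation can be flipped by swapping to the inverse.
INVERSE_PREDICATES = {BROAD_MATCH: NARROW_MATCH, NARROW_MATCH: BROAD_MATCH}

#: Predicates treated as symmetric by default; extendable via ``load_predicate_config``.
DEFAULT_SYMMETRIC = frozenset({EXACT_MATCH})

#: (subject CURIE, predicate CURIE, object CURIE) of a canonical mapping.
MappingKey = Tuple[str, str, str]

_ORCID_RE = re.compile(r"^\d{4}-\d{4}-\d{4}-\d{3}[\dX]$")
_CURIE_RE = re.compile(r"^[^\s:]+:[^\s:]+$")

Verdict = Literal["positive", "negative", "unsure"]
PredictionMethod = Literal["lexical", "inferred-transitivity", "other"]


class BiomapError(Exception):
    """Base class for errors raised by this package."""


class DuplicateMappingError(BiomapError):
    """A mapping with the same canonical key is already present."""

    def __init__(self, key: MappingKey, collection: str):
        self.key = key
        self.collection = collection
        super().__init__(f"mapping {key} already present in collection {collection!r}")


class UnknownPredicateError(BiomapError):
    """Canonicalization asked to reorient a predicate it does not know how to invert."""


class EntityReference(BaseModel):
    """A prefixed identifier plus a human-readable name.

    ``prefix`` is a lowercase identifier-resource key (e.g. ``chebi``) and
    ``identifier`` the local unique identifier within that resource.  ``name``
    may be empty (predictions sometimes lack one).
    """

    model_config = ConfigDict(frozen=True)

    prefix: str
    identifier: str
    name: str = ""

    @field_validator("prefix")
    @classmethod
    def _normalize_prefix(cls, v: str) -> str:
        v = v.strip().lower()
        if not v or "\t" in v or "\n" in v:
            raise ValueError("prefix must be non-empty and contain no tab/newline")
        return v

    @field_validator("identifier")
    @classmethod
    def _check_identifier(cls, v: str) -> str:
        if not v or "\t" in v or "\n" in v:
            raise ValueError("identifier must be non-empty and contain no tab/newline")
        return v

    @property
    def curie(self) -> str:
        return f"{self.prefix}:{self.identifier}"

    @classmethod
    def from_curie(cls, curie: str, name: str = "") -> "EntityReference":
        prefix, _, identifier = curie.partition(":")
        if not identifier:
            raise ValueError(f"not a CURIE: {curie!r}")
        return cls(prefix=prefix, identifier=identifier, name=name)

    def pair(self) -> Tuple[str, str]:
        """Sort key for canonical endpoint ordering."""
        return (self.prefix, self.identifier)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.curie


class CurationMetadata(BaseModel):
    """Provenance of a human curation: who decided, and what the verdict was."""

    model_config = ConfigDict(frozen=True)

    curator_orcid: str
    verdict: Verdict

    @field_validator("curator_orcid")
    @classmethod
    def _check_orcid(cls, v: str) -> str:
        if not _ORCID_RE.match(v):
            raise ValueError(f"malformed ORCID: {v!r}")
        return v


class PredictionMetadata(BaseModel):
    """Provenance of an automatic prediction.

    ``paths`` optionally records, for multi-hop inferred mappings, the chains of
    intermediate CURIEs through which the mapping was composed.
    """

    model_config = ConfigDict(frozen=True)

    tool: str
    method: PredictionMethod = "lexical"
    confidence: float = Field(ge=0.0, le=1.0)
    paths: Optional[Tuple[Tuple[str, ...], ...]] = None


Provenance = Union[CurationMetadata, PredictionMetadata]


class SemanticMapping(BaseModel):
    """A subject-predicate-object assertion relating entities across resources."""

    model_config = ConfigDict(frozen=True)

    subject: EntityReference
    predicate: str
    object: EntityReference
    provenance: Provenance

    @field_validator("predicate")
    @classmethod
    def _check_predicate(cls, v: str) -> str:
        if not _CURIE_RE.match(v):
            raise ValueError(f"predicate must be a CURIE: {v!r}")
        return v

    @model_validator(mode="after")
    def _no_self_mapping(self) -> "SemanticMapping":
        if self.subject.pair() == self.object.pair():
            raise ValueError(f"self-mapping rejected: {self.subject.curie}")
        return self

    @property
    def key(self) -> MappingKey:
        return mapping_key(self)

    @property
    def confidence(self) -> Optional[float]:
        if isinstance(self.provenance, PredictionMetadata):
            return self.provenance.confidence
        return None


def mirror(mapping: SemanticMapping) -> SemanticMapping:
    """Swap the endpoints, inverting directional predicates where defined."""
    predicate = INVERSE_PREDICATES.get(mapping.predicate, mapping.predicate)
    return SemanticMapping(
        subject=mapping.object,
        predicate=predicate,
        object=mapping.subject,
        provenance=mapping.provenance,
    )


def canonicalize(
    mapping: SemanticMapping,
    symmetric: frozenset = DEFAULT_SYMMETRIC,
) -> SemanticMapping:
    """Return the canonical orientation of a mapping; idempotent.

    For symmetric predicates the endpoints are ordered so that
    ``(subject.prefix, subject.identifier)`` sorts before the object's pair.
    For skos:broadMatch / skos:narrowMatch, reordering replaces the predicate
    by its inverse.  Any other predicate with out-of-order endpoints raises
    :class:`UnknownPredicateError`, since its inverse is not known.
    """
    if mapping.subject.pair() <= mapping.object.pair():
        return mapping
    if mapping.predicate in symmetric:
        return SemanticMapping(
            subject=mapping.object,
            predicate=mapping.predicate,
            object=mapping.subject,
            provenance=mapping.provenance,
        )
    if mapping.predicate in INVERSE_PREDICATES:
        return mirror(mapping)
    raise UnknownPredicateError(
        f"cannot reorient endpoints of asymmetric predicate {mapping.predicate!r}"
    )


def mapping_key(mapping: SemanticMapping) -> MappingKey:
    """Key identifying the semantic assertion: (subject CURIE, predicate, object CURIE)."""
    return (mapping.subject.curie, mapping.predicate, mapping.object.curie)


def load_predicate_config(path) -> frozenset:
    """Read the set of symmetric predicates from a small YAML config.

    The file holds ``symmetric: [skos:exactMatch, ...]``; skos:exactMatch is
    always included.
    """
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    extra = data.get("symmetric", [])
    return DEFAULT_SYMMETRIC | frozenset(extra)


COLLECTIONS = ("positive", "negative", "unsure", "predicted")


class MappingLedger:
    """The four-collection mapping store: positive, negative, unsure, predicted.

    Collections are insertion-ordered and duplicate-free under
    :func:`mapping_key`.  :meth:`add` enforces disjointness across collections
    (the curation invariant); :meth:`add_to_collection` checks only the target
    collection, which lets the file reader represent cross-file duplicates so
    lint can report them.
    """

    def __init__(self, symmetric: frozenset = DEFAULT_SYMMETRIC):
        self.symmetric = symmetric
        self._collections: dict = {name: {} for name in COLLECTIONS}

    # -- access ------------------------------------------------------------

    @property
    def positive(self) -> dict:
        return self._collections["positive"]

    @property
    def negative(self) -> dict:
        return self._collections["negative"]

    @property
    def unsure(self) -> dict:
        return self._collections["unsure"]

    @property
    def predicted(self) -> dict:
        return self._collections["predicted"]

    def collection(self, name: str) -> dict:
        if name not in COLLECTIONS:
            raise KeyError(name)
        return self._collections[name]

    def __iter__(self) -> Iterator[Tuple[str, SemanticMapping]]:
        for name in COLLECTIONS:
            for mapping in self._collections[name].values():
                yield name, mapping

    def __len__(self) -> int:
        return sum(len(c) for c in self._collections.values())

    def sizes(self) -> dict:
        return {name: len(self._collections[name]) for name in COLLECTIONS}

    def all_keys(self) -> set:
        keys: set = set()
        for c in self._collections.values():
            keys.update(c.keys())
        return keys

    def find(self, key: MappingKey) -> Optional[str]:
        """Name of the collection holding ``key``, or None."""
        for name in COLLECTIONS:
            if key in self._collections[name]:
                return name
        return None

    # -- mutation ----------------------------------------------------------

    def add(self, mapping: SemanticMapping, collection: str) -> SemanticMapping:
        """Canonicalize and insert, rejecting a key present in *any* collection."""
        mapping = canonicalize(mapping, self.symmetric)
        key = mapping_key(mapping)
        existing = self.find(key)
        if existing is not None:
            raise DuplicateMappingError(key, existing)
        self._collections[collection][key] = mapping
        return mapping

    def add_to_collection(self, mapping: SemanticMapping, collection: str) -> SemanticMapping:
        """Canonicalize and insert, checking duplicates only within ``collection``."""
        mapping = canonicalize(mapping, self.symmetric)
        key = mapping_key(mapping)
        if key in self._collections[collection]:
            raise DuplicateMappingError(key, collection)
        self._collections[collection][key] = mapping
        return mapping

    def remove(self, key: MappingKey, collection: str) -> SemanticMapping:
        try:
            return self._collections[collection].pop(key)
        except KeyError:
            raise KeyError(f"mapping {key} not in collection {collection!r}") from None

    def add_all(self, mappings: Iterable[SemanticMapping], collection: str) -> None:
        for mapping in mappings:
            self.add(mapping, collection)

    def cross_collection_duplicates(self) -> list:
        """Keys present in more than one collection, with the collection names."""
        seen: dict = {}
        out = []
        for name in COLLECTIONS:
            for key in self._collections[name]:
                if key in seen:
                    out.append((key, seen[key], name))
                else:
                    seen[key] = name
        return out
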