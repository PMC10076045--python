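"""Reading/writing the four-file TSV ledger dialect, SSSOM export, lint, and summaries.

The writer emits a single fixed header per file::

    subject_prefix  subject_identifier  subject_name  predicate
    object_prefix   object_identifier   object_name   type  source  [confidence]

with rows sorted by mapping key, UTF-8 and LF line endings, so output is
byte-deterministic and stable under version control.  The reader is tolerant:
headers are matched by normalized name with aliases for the common dialect
that uses ``source */target *`` column prefixes and ``relation`` for the
predicate.
"""

from __future__ import annotations

import csv
import io
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import yaml

from .core import (
    COLLECTIONS,
    DEFAULT_SYMMETRIC,
    CurationMetadata,
    EntityReference,
    MappingKey,
    MappingLedger,
    PredictionMetadata,
    SemanticMapping,
    canonicalize,
    mapping_key,
)

__all__ = [
    "LEDGER_FILENAMES",
    "LedgerParseError",
    "LintViolation",
    "LedgerSummary",
    "read_ledger",
    "read_ledger_dir",
    "write_ledger",
    "write_ledger_dir",
    "export_sssom",
    "parse_sssom",
    "lint_ledger",
    "summarize_ledger",
    "load_registry",
]

#: Conventional file names when a ledger lives in a directory.
LEDGER_FILENAMES = {
    "positive": "positive.tsv",
    "negative": "negative.tsv",
    "unsure": "unsure.tsv",
    "predicted": "predictions.tsv",
}

_CURATED_TYPE = "semapv:ManualMappingCuration"
_METHOD_TO_TYPE = {
    "lexical": "semapv:LexicalMatching",
    "inferred-transitivity": "semapv:ChainedMapping",
    "other": "semapv:UnspecifiedMatching",
}
_TYPE_TO_METHOD = {v: k for k, v in _METHOD_TO_TYPE.items()}


class LedgerParseError(Exception):
    """A ledger file violates the dialect; message carries file and line."""


def _norm_header(name: str) -> str:
    """lowercase and collapse runs of non-alphanumerics to single underscores."""
    return re.sub(r"[^a-z0-9]+", "_", name.strip().lower()).strip("_")


# canonical column -> accepted normalized header names
_HEADER_ALIASES = {
    "subject_prefix": {"subject_prefix", "source_prefix"},
    "subject_identifier": {"subject_identifier", "subject_id", "source_identifier", "source_id"},
    "subject_name": {"subject_name", "subject_label", "source_name", "source_label"},
    "predicate": {"predicate", "relation", "predicate_id"},
    "object_prefix": {"object_prefix", "target_prefix"},
    "object_identifier": {"object_identifier", "object_id", "target_identifier", "target_id"},
    "object_name": {"object_name", "object_label", "target_name", "target_label"},
    "type": {"type", "curation_type", "prediction_type", "mapping_justification"},
    "source": {"source", "contributor", "author", "author_id", "prediction_source", "mapping_tool"},
    "confidence": {"confidence", "prediction_confidence"},
}


def _resolve_header(header: List[str], path: str) -> Dict[str, int]:
    columns: Dict[str, int] = {}
    for i, raw in enumerate(header):
        norm = _norm_header(raw)
        for canonical, aliases in _HEADER_ALIASES.items():
            if norm in aliases and canonical not in columns:
                columns[canonical] = i
                break
    required = (
        "subject_prefix",
        "subject_identifier",
        "predicate",
        "object_prefix",
        "object_identifier",
    )
    missing = [c for c in required if c not in columns]
    if missing:
        raise LedgerParseError(f"{path}: header missing required columns {missing}")
    return columns


def _parse_file(
    path,
    collection: str,
    ledger: MappingLedger,
) -> None:
    path = str(path)
    seen_lines: Dict[MappingKey, int] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise LedgerParseError(f"{path}: empty file (header required)") from None
        columns = _resolve_header(header, path)
        n_fields = len(header)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != n_fields:
                raise LedgerParseError(
                    f"{path}:{lineno}: expected {n_fields} fields, found {len(row)}"
                )

            def get(col: str, default: str = "") -> str:
                idx = columns.get(col)
                return row[idx] if idx is not None else default

            try:
                subject = EntityReference(
                    prefix=get("subject_prefix"),
                    identifier=get("subject_identifier"),
                    name=get("subject_name"),
                )
                obj = EntityReference(
                    prefix=get("object_prefix"),
                    identifier=get("object_identifier"),
                    name=get("object_name"),
                )
                provenance = _parse_provenance(
                    collection, get("type"), get("source"), get("confidence"), path, lineno
                )
                mapping = SemanticMapping(
                    subject=subject, predicate=get("predicate"), object=obj, provenance=provenance
                )
            except LedgerParseError:
                raise
            except ValueError as exc:
                raise LedgerParseError(f"{path}:{lineno}: {exc}") from exc
            mapping = canonicalize(mapping, ledger.symmetric)
            key = mapping_key(mapping)
            if key in seen_lines:
                raise LedgerParseError(
                    f"{path}:{lineno}: duplicate mapping {key} (first at line {seen_lines[key]})"
                )
            seen_lines[key] = lineno
            ledger.collection(collection)[key] = mapping


def _parse_provenance(collection, type_str, source, confidence, path, lineno):
    if collection == "predicted":
        if confidence == "":
            raise LedgerParseError(f"{path}:{lineno}: predicted mapping lacks confidence")
        try:
            value = float(confidence)
        except ValueError:
            raise LedgerParseError(f"{path}:{lineno}: bad confidence {confidence!r}") from None
        if not 0.0 <= value <= 1.0:
            raise LedgerParseError(f"{path}:{lineno}: confidence {value} outside [0, 1]")
        method = _TYPE_TO_METHOD.get(type_str, "other")
        return PredictionMetadata(tool=source or "unknown", method=method, confidence=value)
    verdict = collection
    orcid = source.removeprefix("orcid:")
    try:
        return CurationMetadata(curator_orcid=orcid, verdict=verdict)
    except ValueError as exc:
        raise LedgerParseError(f"{path}:{lineno}: {exc}") from exc


def read_ledger(
    positive,
    negative,
    unsure,
    predicted,
    symmetric: frozenset = DEFAULT_SYMMETRIC,
) -> MappingLedger:
    """Read the four TSV files into a ledger.

    Within-file duplicate keys are an error; a key present in two different
    files is preserved so that :func:`lint_ledger` can report it.
    """
    ledger = MappingLedger(symmetric=symmetric)
    for collection, path in zip(COLLECTIONS, (positive, negative, unsure, predicted)):
        _parse_file(path, collection, ledger)
    return ledger


def read_ledger_dir(directory, symmetric: frozenset = DEFAULT_SYMMETRIC) -> MappingLedger:
    directory = Path(directory)
    return read_ledger(
        *(directory / LEDGER_FILENAMES[c] for c in COLLECTIONS), symmetric=symmetric
    )


_BASE_HEADER = [
    "subject_prefix",
    "subject_identifier",
    "subject_name",
    "predicate",
    "object_prefix",
    "object_identifier",
    "object_name",
    "type",
    "source",
]


def _format_row(mapping: SemanticMapping) -> List[str]:
    prov = mapping.provenance
    if isinstance(prov, CurationMetadata):
        type_str = _CURATED_TYPE
        source = f"orcid:{prov.curator_orcid}"
        confidence = None
    else:
        type_str = _METHOD_TO_TYPE[prov.method]
        source = prov.tool
        confidence = prov.confidence
    row = [
        mapping.subject.prefix,
        mapping.subject.identifier,
        mapping.subject.name,
        mapping.predicate,
        mapping.object.prefix,
        mapping.object.identifier,
        mapping.object.name,
        type_str,
        source,
    ]
    return row, confidence


def write_ledger(ledger: MappingLedger, positive, negative, unsure, predicted) -> None:
    """Write the four files deterministically: sorted rows, LF, fixed header."""
    for collection, path in zip(COLLECTIONS, (positive, negative, unsure, predicted)):
        with_confidence = collection == "predicted"
        header = _BASE_HEADER + (["confidence"] if with_confidence else [])
        rows = sorted(ledger.collection(collection).items())
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(header)
            for _key, mapping in rows:
                row, confidence = _format_row(mapping)
                if with_confidence:
                    row.append(_format_confidence(confidence))
                writer.writerow(row)


def _format_confidence(value: Optional[float]) -> str:
    if value is None:
        return ""
    return repr(round(float(value), 10))


def write_ledger_dir(ledger: MappingLedger, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_ledger(ledger, *(directory / LEDGER_FILENAMES[c] for c in COLLECTIONS))


# -- SSSOM -----------------------------------------------------------------

_SSSOM_COLUMNS = [
    "subject_id",
    "subject_label",
    "predicate_id",
    "predicate_modifier",
    "object_id",
    "object_label",
    "mapping_justification",
    "author_id",
    "mapping_tool",
    "confidence",
]

_BUILTIN_CURIE_MAP = {
    "skos": "http://www.w3.org/2004/02/skos/core#",
    "semapv": "https://w3id.org/semapv/vocab/",
    "orcid": "https://orcid.org/",
}


def export_sssom(
    ledger: MappingLedger,
    curie_map: Mapping[str, str],
    license: str = "https://creativecommons.org/publicdomain/zero/1.0/",
    mapping_set_id: str = "https://example.org/biomap/mappings.sssom.tsv",
) -> str:
    """Collate all four collections into one SSSOM TSV document (as a string).

    Curated rows carry a manual-curation justification and the curator ORCID;
    predicted rows carry the matching justification, tool, and confidence.
    Negative curations are kept, flagged with predicate_modifier ``Not``.
    Every ledger prefix must appear in ``curie_map``.
    """
    prefixes = set()
    for _collection, mapping in ledger:
        prefixes.add(mapping.subject.prefix)
        prefixes.add(mapping.object.prefix)
    missing = sorted(p for p in prefixes if p not in curie_map)
    if missing:
        raise KeyError(f"prefixes missing from curie_map: {missing}")

    full_map = dict(_BUILTIN_CURIE_MAP)
    full_map.update({p: curie_map[p] for p in sorted(prefixes)})

    buf = io.StringIO()
    buf.write("# curie_map:\n")
    for prefix in sorted(full_map):
        buf.write(f"#   {prefix}: {full_map[prefix]}\n")
    buf.write(f"# license: {license}\n")
    buf.write(f"# mapping_set_id: {mapping_set_id}\n")
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow(_SSSOM_COLUMNS)

    rows = []
    for collection, mapping in ledger:
        prov = mapping.provenance
        if isinstance(prov, CurationMetadata):
            justification = "semapv:ManualMappingCuration"
            author = f"orcid:{prov.curator_orcid}"
            tool = ""
            confidence = ""
        else:
            justification = _METHOD_TO_TYPE[prov.method]
            author = ""
            tool = prov.tool
            confidence = _format_confidence(prov.confidence)
        modifier = "Not" if collection == "negative" else ""
        rows.append(
            [
                mapping.subject.curie,
                mapping.subject.name,
                mapping.predicate,
                modifier,
                mapping.object.curie,
                mapping.object.name,
                justification,
                author,
                tool,
                confidence,
            ]
        )
    rows.sort()
    writer.writerows(rows)
    return buf.getvalue()


def parse_sssom(text: str) -> List[dict]:
    """Minimal generic SSSOM TSV reader: skips the ``#`` metadata block and
    returns the data rows as dicts.  Used for round-trip checks, not as a
    primary store."""
    lines = [line for line in text.splitlines() if not line.startswith("#")]
    reader = csv.DictReader(lines, delimiter="\t")
    return list(reader)


# -- lint ------------------------------------------------------------------


@dataclass(frozen=True)
class LintViolation:
    kind: str  # unknown_prefix | pattern_mismatch | non_canonical | cross_file_duplicate
    message: str
    collection: str = ""
    key: Optional[MappingKey] = None


def load_registry(path) -> Dict[str, str]:
    """Read a prefix → identifier-regex registry from YAML or two-column TSV."""
    path = str(path)
    if path.endswith((".yaml", ".yml")):
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return {str(k).lower(): str(v) for k, v in data.items()}
    registry = {}
    with open(path, encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if len(row) >= 2:
                registry[row[0].lower()] = row[1]
    return registry


def lint_ledger(ledger: MappingLedger, registry: Mapping[str, str]) -> List[LintViolation]:
    """Data-quality checks; reports problems, never raises on them.

    Checks every entity reference for a known prefix and a pattern-compliant
    identifier, every mapping for canonical orientation, and the four
    collections for cross-file duplicate keys.
    """
    violations: List[LintViolation] = []
    compiled = {prefix: re.compile(pattern) for prefix, pattern in registry.items()}
    for collection, mapping in ledger:
        key = mapping_key(mapping)
        for ref in (mapping.subject, mapping.object):
            pattern = compiled.get(ref.prefix)
            if pattern is None:
                violations.append(
                    LintViolation(
                        "unknown_prefix",
                        f"prefix {ref.prefix!r} not in registry ({ref.curie})",
                        collection,
                        key,
                    )
                )
            elif not pattern.fullmatch(ref.identifier):
                violations.append(
                    LintViolation(
                        "pattern_mismatch",
                        f"identifier {ref.identifier!r} fails pattern "
                        f"{pattern.pattern!r} for prefix {ref.prefix!r}",
                        collection,
                        key,
                    )
                )
        canonical = canonicalize(mapping, ledger.symmetric)
        if mapping_key(canonical) != key:
            violations.append(
                LintViolation(
                    "non_canonical",
                    f"mapping {key} is not in canonical orientation",
                    collection,
                    key,
                )
            )
    for key, first, second in ledger.cross_collection_duplicates():
        violations.append(
            LintViolation(
                "cross_file_duplicate",
                f"mapping {key} present in both {first!r} and {second!r}",
                second,
                key,
            )
        )
    return violations


# -- summary ---------------------------------------------------------------


@dataclass
class LedgerSummary:
    """Counts per collection, predicate, unordered prefix pair, and curator."""

    collections: Dict[str, int] = field(default_factory=dict)
    predicates: Dict[str, int] = field(default_factory=dict)
    prefix_pairs: Dict[Tuple[str, str], int] = field(default_factory=dict)
    prefix_pairs_by_collection: Dict[str, Dict[Tuple[str, str], int]] = field(default_factory=dict)
    curators: Dict[str, int] = field(default_factory=dict)


def summarize_ledger(ledger: MappingLedger) -> LedgerSummary:
    predicates: Counter = Counter()
    pairs: Counter = Counter()
    by_collection: Dict[str, Counter] = {name: Counter() for name in COLLECTIONS}
    curators: Counter = Counter()
    for collection, mapping in ledger:
        predicates[mapping.predicate] += 1
        pair = tuple(sorted((mapping.subject.prefix, mapping.object.prefix)))
        pairs[pair] += 1
        by_collection[collection][pair] += 1
        if isinstance(mapping.provenance, CurationMetadata):
            curators[mapping.provenance.curator_orcid] += 1
    return LedgerSummary(
        collections=ledger.sizes(),
        predicates=dict(predicates),
        prefix_pairs=dict(pairs),
        prefix_pairs_by_collection={k: dict(v) for k, v in by_collection.items()},
        curators=dict(curators),
    )
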