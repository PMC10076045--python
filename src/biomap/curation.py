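"""Non-interactive curation: apply verdicts to predictions, add manual mappings.

Verdicts move a mapping from the predicted collection into the curated
collection matching the verdict, replacing its prediction provenance with the
curator's ORCID.  A scriptable TSV "verdict file" (subject, predicate, object,
verdict, orcid — applied in file order) stands in for an interactive review
session and replays deterministically.
"""

from __future__ import annotations

import csv
from typing import Iterable, Tuple

from .core import (
    BiomapError,
    CurationMetadata,
    EntityReference,
    MappingKey,
    MappingLedger,
    SemanticMapping,
    canonicalize,
    mapping_key,
)

__all__ = ["record_verdict", "add_manual_mapping", "read_verdict_file", "apply_verdict_file"]


class CurationError(BiomapError):
    pass


def record_verdict(
    ledger: MappingLedger,
    key: MappingKey,
    verdict: str,
    orcid: str,
) -> MappingLedger:
    """Move a predicted mapping into the verdict's curated collection.

    The prediction is removed from ``predicted`` and re-added with curation
    provenance, conserving the total mapping count.  Re-curation of an
    already-curated key is rejected; delete the earlier curation first.
    """
    if verdict not in ("positive", "negative", "unsure"):
        raise CurationError(f"unknown verdict {verdict!r}")
    if key not in ledger.predicted:
        raise CurationError(f"mapping {key} is not among the predictions")
    provenance = CurationMetadata(curator_orcid=orcid, verdict=verdict)  # validates ORCID
    prediction = ledger.remove(key, "predicted")
    curated = SemanticMapping(
        subject=prediction.subject,
        predicate=prediction.predicate,
        object=prediction.object,
        provenance=provenance,
    )
    ledger.add(curated, verdict)
    return ledger


def add_manual_mapping(
    ledger: MappingLedger,
    mapping: SemanticMapping,
    verdict: str,
    orcid: str,
) -> MappingLedger:
    """Add a novel curation not present among the predictions."""
    if verdict not in ("positive", "negative", "unsure"):
        raise CurationError(f"unknown verdict {verdict!r}")
    curated = SemanticMapping(
        subject=mapping.subject,
        predicate=mapping.predicate,
        object=mapping.object,
        provenance=CurationMetadata(curator_orcid=orcid, verdict=verdict),
    )
    ledger.add(curated, verdict)  # raises DuplicateMappingError naming the collection
    return ledger


def read_verdict_file(path) -> Iterable[Tuple[str, str, str, str, str]]:
    """Rows of a verdict TSV: subject CURIE, predicate, object CURIE, verdict, orcid."""
    rows = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            rows.append(
                (row["subject"], row["predicate"], row["object"], row["verdict"], row["orcid"])
            )
    return rows


def apply_verdict_file(ledger: MappingLedger, path) -> MappingLedger:
    """Apply a verdict file in file order."""
    for subject, predicate, obj, verdict, orcid in read_verdict_file(path):
        probe = canonicalize(
            SemanticMapping(
                subject=EntityReference.from_curie(subject),
                predicate=predicate,
                object=EntityReference.from_curie(obj),
                provenance=CurationMetadata(curator_orcid=orcid, verdict=verdict),
            ),
            ledger.symmetric,
        )
        record_verdict(ledger, mapping_key(probe), verdict, orcid)
    return ledger
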