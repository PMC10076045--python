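"""Novelty filtering, scope restriction, frequency-weighted prioritization, sampling.

All filters are pure and order-preserving.  ``prioritize_by_frequency``
implements the coverage rule used to focus curation effort: pick the smallest
set of most-frequent unmapped terms whose usage counts reach a target fraction
of the total (e.g. the terms accounting for 80% of unmapped instances).
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .core import MappingLedger, SemanticMapping, mapping_key

__all__ = [
    "filter_novel",
    "filter_scope",
    "prioritize_by_frequency",
    "sample_for_evaluation",
    "PrioritizationResult",
]


def filter_novel(
    predictions: Sequence[SemanticMapping],
    ledger: MappingLedger,
    primary: Iterable[SemanticMapping] = (),
) -> List[SemanticMapping]:
    """Keep predictions not already curated, predicted, or provided by a
    primary resource.

    A prediction is removed when its mapping key appears in any ledger
    collection or among the primary mappings (all inputs canonical, so a
    mirror of an existing mapping is removed too).  Keys include the
    predicate: an existing broadMatch does not block an exactMatch prediction.
    """
    blocked = ledger.all_keys()
    blocked.update(mapping_key(m) for m in primary)
    return [p for p in predictions if mapping_key(p) not in blocked]


def filter_scope(
    predictions: Sequence[SemanticMapping],
    prefix_pair: Optional[Tuple[str, str]] = None,
    min_confidence: Optional[float] = None,
    query: Optional[str] = None,
) -> List[SemanticMapping]:
    """Restrict to an unordered prefix pair, a confidence floor, and/or a
    case-insensitive substring over names and CURIEs."""
    pair = frozenset(p.lower() for p in prefix_pair) if prefix_pair else None
    needle = query.lower() if query else None
    out = []
    for m in predictions:
        if pair is not None and {m.subject.prefix, m.object.prefix} != pair:
            continue
        if min_confidence is not None and (m.confidence is None or m.confidence < min_confidence):
            continue
        if needle is not None:
            haystack = " ".join(
                (m.subject.name, m.object.name, m.subject.curie, m.object.curie)
            ).lower()
            if needle not in haystack:
                continue
        out.append(m)
    return out


@dataclass(frozen=True)
class PrioritizationResult:
    selection: Tuple[str, ...]  # term CURIEs, most frequent first
    achieved_coverage: float
    total: int


def prioritize_by_frequency(
    unmapped_terms: Dict[str, int],
    coverage_target: float,
) -> PrioritizationResult:
    """Shortest most-frequent-first selection reaching the coverage target.

    Terms are sorted by count descending (ties: CURIE ascending); the returned
    prefix is the shortest one whose cumulative count is at least
    ``coverage_target`` times the total count.
    """
    if not 0.0 <= coverage_target <= 1.0:
        raise ValueError("coverage_target must be in [0, 1]")
    if any(count < 0 for count in unmapped_terms.values()):
        raise ValueError("counts must be nonnegative")
    total = sum(unmapped_terms.values())
    if total == 0:
        if coverage_target > 0:
            raise ValueError("total count is 0; cannot reach a positive coverage target")
        return PrioritizationResult(selection=(), achieved_coverage=0.0, total=0)
    ranked = sorted(unmapped_terms.items(), key=lambda kv: (-kv[1], kv[0]))
    selection: List[str] = []
    cumulative = 0
    for curie, count in ranked:
        if cumulative >= coverage_target * total:
            break
        selection.append(curie)
        cumulative += count
    return PrioritizationResult(
        selection=tuple(selection),
        achieved_coverage=cumulative / total,
        total=total,
    )


def sample_for_evaluation(
    predictions: Sequence[SemanticMapping],
    n: int,
    seed: int,
) -> List[SemanticMapping]:
    """Uniform sample without replacement, fully determined by ``seed``."""
    if n > len(predictions):
        raise ValueError(f"cannot sample {n} from {len(predictions)} predictions")
    rng = random.Random(seed)
    return rng.sample(list(predictions), n)
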