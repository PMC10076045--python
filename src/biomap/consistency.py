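"""Mapping-graph construction, quality-assurance motifs, and multi-hop inference.

The positive and negative exactMatch curations form a labeled undirected
graph.  Because equivalence is transitive, a connected component of the
positive subgraph behaves as one semantic unit ("clique" in the loose sense),
and three motifs signal curation problems:

* duplicate prefix — two nodes of one component come from the same resource,
  so one of them (and its incident edges) is mapped incorrectly;
* incomplete clique — a pair of component members with no direct edge suggests
  a missing high-confidence mapping, proposable by transitivity;
* unstable clique — a negative edge inside one positive component means some
  positive (or the negative) edge is wrong.

``infer_multihop`` composes chains of exactMatch mappings across an explicit
ordered list of mapping collections (e.g. CCLE→Cellosaurus→EFO), recording
the intermediate CURIEs of every path as provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Literal, Sequence, Tuple

import networkx as nx

from .core import (
    EXACT_MATCH,
    EntityReference,
    MappingLedger,
    PredictionMetadata,
    SemanticMapping,
    canonicalize,
)

__all__ = [
    "INFERRED_CONFIDENCE",
    "MappingGraph",
    "MotifReport",
    "build_graph",
    "find_duplicate_prefix_components",
    "propose_missing_edges",
    "find_negative_conflicts",
    "infer_multihop",
]

#: Confidence attached to mappings proposed by transitivity.
INFERRED_CONFIDENCE = 0.95

Motif = Literal["duplicate_prefix", "incomplete_clique", "unstable_clique"]


@dataclass
class MappingGraph:
    """Undirected graph over entity CURIEs with positive and negative edge sets.

    Positive/negative overlap is not assumed away — an edge present in both is
    exactly what the unstable-clique motif reports.
    """

    positive: nx.Graph = field(default_factory=nx.Graph)
    negative: nx.Graph = field(default_factory=nx.Graph)
    references: Dict[str, EntityReference] = field(default_factory=dict)

    def _touch(self, ref: EntityReference) -> str:
        self.references.setdefault(ref.curie, ref)
        self.positive.add_node(ref.curie)
        self.negative.add_node(ref.curie)
        return ref.curie

    def add_positive(self, subject: EntityReference, obj: EntityReference) -> None:
        self.positive.add_edge(self._touch(subject), self._touch(obj))

    def add_negative(self, subject: EntityReference, obj: EntityReference) -> None:
        self.negative.add_edge(self._touch(subject), self._touch(obj))

    def positive_components(self) -> List[List[str]]:
        """Non-singleton components of the positive subgraph, canonically ordered."""
        components = [
            sorted(c) for c in nx.connected_components(self.positive) if len(c) > 1
        ]
        components.sort(key=lambda c: c[0])
        return components


@dataclass(frozen=True)
class MotifReport:
    motif: Motif
    component: Tuple[str, ...]  # sorted node CURIEs, connected in the positive subgraph
    detail: str
    nodes: Tuple[str, ...] = ()  # the offending nodes / conflicting edge


def build_graph(ledger: MappingLedger, include_predicted: bool = False) -> MappingGraph:
    """Graph from the union of positive and negative exactMatch mappings.

    Other predicates are ignored.  With ``include_predicted``, predicted
    exactMatch mappings are added as positive edges.
    """
    graph = MappingGraph()
    for mapping in ledger.positive.values():
        if mapping.predicate == EXACT_MATCH:
            graph.add_positive(mapping.subject, mapping.object)
    if include_predicted:
        for mapping in ledger.predicted.values():
            if mapping.predicate == EXACT_MATCH:
                graph.add_positive(mapping.subject, mapping.object)
    for mapping in ledger.negative.values():
        if mapping.predicate == EXACT_MATCH:
            graph.add_negative(mapping.subject, mapping.object)
    return graph


def _prefix(curie: str) -> str:
    return curie.partition(":")[0]


def find_duplicate_prefix_components(graph: MappingGraph) -> List[MotifReport]:
    """One report per (positive component, prefix occurring on ≥ 2 nodes)."""
    reports: List[MotifReport] = []
    for component in graph.positive_components():
        by_prefix: Dict[str, List[str]] = {}
        for curie in component:
            by_prefix.setdefault(_prefix(curie), []).append(curie)
        for prefix in sorted(by_prefix):
            nodes = by_prefix[prefix]
            if len(nodes) >= 2:
                reports.append(
                    MotifReport(
                        motif="duplicate_prefix",
                        component=tuple(component),
                        detail=f"prefix {prefix!r} appears on {len(nodes)} nodes",
                        nodes=tuple(nodes),
                    )
                )
    return reports


def propose_missing_edges(
    graph: MappingGraph,
    tool: str = "biomap-transitivity",
) -> List[SemanticMapping]:
    """Propose exactMatch mappings completing each positive component.

    Every unordered pair of component members with distinct prefixes, no
    existing positive edge, and no negative edge becomes a canonical
    prediction (method inferred-transitivity, fixed confidence).  Same-prefix
    pairs are never proposed — they belong to the duplicate-prefix motif.
    """
    proposals: List[SemanticMapping] = []
    for component in graph.positive_components():
        for i, u in enumerate(component):
            for v in component[i + 1 :]:
                if _prefix(u) == _prefix(v):
                    continue
                if graph.positive.has_edge(u, v) or graph.negative.has_edge(u, v):
                    continue
                proposals.append(
                    canonicalize(
                        SemanticMapping(
                            subject=graph.references[u],
                            predicate=EXACT_MATCH,
                            object=graph.references[v],
                            provenance=PredictionMetadata(
                                tool=tool,
                                method="inferred-transitivity",
                                confidence=INFERRED_CONFIDENCE,
                            ),
                        )
                    )
                )
    return sorted(proposals, key=lambda m: m.key)


def find_negative_conflicts(graph: MappingGraph) -> List[MotifReport]:
    """Report every negative edge whose endpoints are positively connected,
    with one shortest positive path between them."""
    reports: List[MotifReport] = []
    for u, v in sorted(tuple(sorted(e)) for e in graph.negative.edges):
        if u not in graph.positive or v not in graph.positive:
            continue
        if not nx.has_path(graph.positive, u, v):
            continue
        path = nx.shortest_path(graph.positive, u, v)
        component = sorted(nx.node_connected_component(graph.positive, u))
        reports.append(
            MotifReport(
                motif="unstable_clique",
                component=tuple(component),
                detail="negative edge inside positive component; positive path: "
                + " -- ".join(path),
                nodes=(u, v),
            )
        )
    reports.sort(key=lambda r: (r.component[0], r.nodes))
    return reports


def infer_multihop(
    hops: Sequence[Iterable[SemanticMapping]],
    max_hops: int,
    tool: str = "biomap-multihop",
) -> List[SemanticMapping]:
    """Compose exactMatch chains through an ordered list of mapping collections.

    A chain starts at either endpoint of a hop-1 mapping and extends through
    one mapping of each subsequent collection, never revisiting a node.  Each
    resulting endpoint pair is emitted once as a canonical exactMatch
    prediction whose provenance lists the intermediate CURIEs of every
    distinct path.
    """
    if max_hops < 2:
        raise ValueError("max_hops must be at least 2")
    if max_hops > len(hops):
        raise ValueError(
            f"max_hops={max_hops} exceeds the {len(hops)} provided mapping collections"
        )
    hops = [list(collection) for collection in hops[:max_hops]]

    # adjacency per hop: curie -> list of (neighbor curie)
    adjacency: List[Dict[str, List[str]]] = []
    references: Dict[str, EntityReference] = {}
    for collection in hops:
        adj: Dict[str, List[str]] = {}
        for mapping in collection:
            if mapping.predicate != EXACT_MATCH:
                continue
            s, o = mapping.subject, mapping.object
            references.setdefault(s.curie, s)
            references.setdefault(o.curie, o)
            adj.setdefault(s.curie, []).append(o.curie)
            adj.setdefault(o.curie, []).append(s.curie)
        adjacency.append(adj)

    # chains: (nodes so far); extend through each hop in order
    chains: List[Tuple[str, ...]] = [
        (start,) for start in sorted(adjacency[0]) if adjacency[0]
    ]
    for adj in adjacency:
        extended: List[Tuple[str, ...]] = []
        for chain in chains:
            for neighbor in adj.get(chain[-1], ()):
                if neighbor not in chain:
                    extended.append(chain + (neighbor,))
        chains = extended

    # group full-length chains by canonical endpoint pair
    paths_by_pair: Dict[Tuple[str, str], List[Tuple[str, ...]]] = {}
    for chain in chains:
        a, b = chain[0], chain[-1]
        if (_a := references[a].pair()) == references[b].pair():
            continue
        if references[b].pair() < _a:
            pair = (b, a)
            intermediates = tuple(reversed(chain[1:-1]))
        else:
            pair = (a, b)
            intermediates = chain[1:-1]
        bucket = paths_by_pair.setdefault(pair, [])
        if intermediates not in bucket:
            bucket.append(intermediates)

    out = []
    for (a, b), paths in sorted(paths_by_pair.items()):
        out.append(
            SemanticMapping(
                subject=references[a],
                predicate=EXACT_MATCH,
                object=references[b],
                provenance=PredictionMetadata(
                    tool=tool,
                    method="inferred-transitivity",
                    confidence=INFERRED_CONFIDENCE,
                    paths=tuple(sorted(paths)),
                ),
            )
        )
    return out
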