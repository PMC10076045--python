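"""Shared factories and independent oracles for the test suite."""

from __future__ import annotations

import random
from typing import Dict, List, Set, Tuple

import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

from biomap import (
    EXACT_MATCH,
    CurationMetadata,
    EntityReference,
    MappingGraph,
    PredictionMetadata,
    SemanticMapping,
)

ORCID = "0000-0001-2345-6789"


def ref(curie: str, name: str = "") -> EntityReference:
    return EntityReference.from_curie(curie, name=name)


def predicted(subject: str, obj: str, predicate: str = EXACT_MATCH, confidence: float = 0.9,
              subject_name: str = "", object_name: str = "") -> SemanticMapping:
    return SemanticMapping(
        subject=ref(subject, subject_name),
        predicate=predicate,
        object=ref(obj, object_name),
        provenance=PredictionMetadata(tool="test-tool", method="lexical", confidence=confidence),
    )


def curated(subject: str, obj: str, verdict: str = "positive", predicate: str = EXACT_MATCH,
            orcid: str = ORCID) -> SemanticMapping:
    return SemanticMapping(
        subject=ref(subject),
        predicate=predicate,
        object=ref(obj),
        provenance=CurationMetadata(curator_orcid=orcid, verdict=verdict),
    )


# -- random graphs and brute-force motif oracles ---------------------------

PREFIX_POOL = ["pa", "pb", "pc", "pd", "pe", "pf"]


def random_mapping_graph(rng: random.Random, max_nodes: int = 50) -> MappingGraph:
    n = rng.randint(2, max_nodes)
    nodes = [
        EntityReference(prefix=rng.choice(PREFIX_POOL), identifier=str(i), name=f"node {i}")
        for i in range(n)
    ]
    graph = MappingGraph()
    for node in nodes:
        graph._touch(node)
    n_pos = rng.randint(0, 2 * n)
    n_neg = rng.randint(0, n // 2)
    for _ in range(n_pos):
        u, v = rng.sample(nodes, 2)
        graph.add_positive(u, v)
    for _ in range(n_neg):
        u, v = rng.sample(nodes, 2)
        graph.add_negative(u, v)
    return graph


class UnionFind:
    """Hand-rolled union-find, independent of the networkx-based detectors."""

    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def positive_components_oracle(graph: MappingGraph) -> List[Set[str]]:
    uf = UnionFind(list(graph.positive.nodes))
    for u, v in graph.positive.edges:
        uf.union(u, v)
    groups: Dict[str, Set[str]] = {}
    for node in graph.positive.nodes:
        groups.setdefault(uf.find(node), set()).add(node)
    return [g for g in groups.values() if len(g) > 1]


def duplicate_prefix_oracle(graph: MappingGraph) -> Set[Tuple[Tuple[str, ...], str]]:
    """(sorted component, prefix) pairs where the prefix occurs on >= 2 nodes."""
    found = set()
    for component in positive_components_oracle(graph):
        prefixes = [c.partition(":")[0] for c in component]
        for prefix in set(prefixes):
            if prefixes.count(prefix) >= 2:
                found.add((tuple(sorted(component)), prefix))
    return found


def missing_edges_oracle(graph: MappingGraph) -> Set[Tuple[str, str]]:
    """Exhaustive pair enumeration of proposable transitive edges."""
    proposals = set()
    for component in positive_components_oracle(graph):
        members = sorted(component)
        for i, u in enumerate(members):
            for v in members[i + 1:]:
                if u.partition(":")[0] == v.partition(":")[0]:
                    continue
                if graph.positive.has_edge(u, v) or graph.negative.has_edge(u, v):
                    continue
                proposals.add((u, v))
    return proposals


def negative_conflicts_oracle(graph: MappingGraph) -> Set[Tuple[str, str]]:
    """Negative edges whose endpoints share a positive component."""
    uf = UnionFind(list(graph.positive.nodes))
    for u, v in graph.positive.edges:
        uf.union(u, v)
    conflicts = set()
    for u, v in graph.negative.edges:
        if u in graph.positive and v in graph.positive and uf.find(u) == uf.find(v):
            conflicts.add(tuple(sorted((u, v))))
    return conflicts


@pytest.fixture
def registry() -> Dict[str, str]:
    """A prefix registry covering the fake prefixes of the synthetic ledger."""
    patterns = {p: r"\d+" for p in ("alpha", "bravo", "chem", "dis", "enz", "mocka", "mockb")}
    patterns.update({p: r"\d+" for p in PREFIX_POOL})
    patterns["mesh"] = r"[CD]\d+"
    patterns["chebi"] = r"\d+"
    return patterns
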