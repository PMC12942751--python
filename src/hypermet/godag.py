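"""Gene Ontology term hierarchy as a directed acyclic graph.

Parent links follow ``is_a`` and ``relationship: part_of`` edges; the
ancestor set of a term (the term itself plus everything reachable through
parent links) drives the semantic similarity used as GO vertex features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx


@dataclass
class GoDag:
    """DAG over GO term ids with child -> parent edges."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @classmethod
    def from_edges(cls, terms: list[str], parent_links: list[tuple[str, str]]) -> "GoDag":
        """Build from explicit (child, parent) links; validates acyclicity."""
        g = nx.DiGraph()
        g.add_nodes_from(terms)
        for child, parent in parent_links:
            if child not in g or parent not in g:
                raise ValueError(f"parent link ({child!r}, {parent!r}) references unknown term")
            g.add_edge(child, parent)
        dag = cls(g)
        dag.validate()
        return dag

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("GO term hierarchy contains a cycle")

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    @property
    def terms(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def roots(self) -> list[str]:
        return [t for t in self.graph.nodes if self.graph.out_degree(t) == 0]

    def parents(self, term: str) -> list[str]:
        self._require(term)
        return list(self.graph.successors(term))

    def ancestor_set(self, term: str) -> frozenset[str]:
        """The term itself plus all is_a/part_of ancestors."""
        self._require(term)
        return frozenset({term} | nx.descendants(self.graph, term))

    def _require(self, term: str) -> None:
        if term not in self.graph:
            raise KeyError(f"GO term {term!r} not in DAG")
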