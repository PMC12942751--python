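"""Disease-as-hyperedge hypergraph: incidence matrix, degrees, statistics.

Each disease is one hyperedge over the union of its directly associated
metabolites and GO terms, plus the proteins reached through the
metabolite-protein links of those metabolites (optionally also through
protein-GO links of the disease's GO terms).  The incidence matrix H is
|V| x |E| (vertices x hyperedges) with H[i, j] = 1 iff vertex i belongs
to disease hyperedge j.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .catalog import EntityCatalog, VERTEX_TYPES


@dataclass
class AssociationTables:
    """The four flat relation tables feeding hypergraph construction."""

    disease_metabolite: list[tuple[str, str]] = field(default_factory=list)
    disease_go: list[tuple[str, str]] = field(default_factory=list)
    protein_go: list[tuple[str, str]] = field(default_factory=list)
    metabolite_protein: list[tuple[str, str]] = field(default_factory=list)

    def as_dict(self) -> dict[str, list[tuple[str, str]]]:
        return {
            "disease_metabolite": self.disease_metabolite,
            "disease_go": self.disease_go,
            "protein_go": self.protein_go,
            "metabolite_protein": self.metabolite_protein,
        }


@dataclass
class Hypergraph:
    """Binary incidence structure over non-disease vertices and disease hyperedges."""

    vertex_ids: list[str]
    hyperedge_ids: list[str]
    incidence: sp.csr_matrix  # |V| x |E|, entries in {0, 1}
    vertex_types: list[str]
    pruned_vertices: list[str] = field(default_factory=list)
    dropped_hyperedges: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n_v, n_e = self.incidence.shape
        if n_v != len(self.vertex_ids) or n_e != len(self.hyperedge_ids):
            raise ValueError("incidence shape does not match id lists")
        if len(self.vertex_types) != n_v:
            raise ValueError("vertex_types length mismatch")

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_ids)

    @property
    def n_hyperedges(self) -> int:
        return len(self.hyperedge_ids)

    def vertex_index(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.vertex_ids)}

    def hyperedge_index(self) -> dict[str, int]:
        return {e: j for j, e in enumerate(self.hyperedge_ids)}

    def members(self, hyperedge_id: str) -> list[str]:
        j = self.hyperedge_index()[hyperedge_id]
        rows = self.incidence.getcol(j).nonzero()[0]
        return [self.vertex_ids[i] for i in rows]

    def to_pairs(self) -> list[tuple[str, str]]:
        """Coordinate-list export: (vertex_id, disease_id) per nonzero."""
        coo = self.incidence.tocoo()
        return [
            (self.vertex_ids[i], self.hyperedge_ids[j])
            for i, j in zip(coo.row.tolist(), coo.col.tolist())
        ]


@dataclass
class DegreePair:
    """Diagonals of the vertex-degree (D_v) and hyperedge-degree (D_e) matrices."""

    vertex_degrees: np.ndarray
    hyperedge_degrees: np.ndarray


@dataclass
class StatsSummary:
    hyperedge_size_median: float
    hyperedge_size_mean: float
    hyperedge_size_max: int
    vertex_degree_median: float
    type_counts: dict[str, int]
    total_vertices: int
    total_hyperedges: int

    def as_dict(self) -> dict:
        return {
            "hyperedge_size": {
                "median": self.hyperedge_size_median,
                "mean": self.hyperedge_size_mean,
                "max": self.hyperedge_size_max,
            },
            "vertex_degree_median": self.vertex_degree_median,
            "type_counts": self.type_counts,
            "total_vertices": self.total_vertices,
            "total_hyperedges": self.total_hyperedges,
        }


def _check_row(pair: tuple[str, str], table: str, catalog: EntityCatalog,
               src_type: str, dst_type: str) -> None:
    src, dst = pair
    for ent, want in ((src, src_type), (dst, dst_type)):
        if ent not in catalog:
            raise ValueError(f"{table} row ({src!r}, {dst!r}): id {ent!r} not in catalog")
        got = catalog.type_of(ent)
        if got != want:
            raise ValueError(
                f"{table} row ({src!r}, {dst!r}): {ent!r} is a {got}, expected {want}"
            )


def build_hypergraph(
    associations: AssociationTables,
    catalog: EntityCatalog,
    protein_via_go: bool = False,
) -> Hypergraph:
    """Assemble the disease hypergraph from the four association tables.

    Disease hyperedge j is the union of (a) metabolites directly linked to
    disease j, (b) GO terms directly linked to disease j, and (c) proteins
    linked (via metabolite-protein rows) to any metabolite in (a).  With
    ``protein_via_go`` proteins additionally join through protein-GO links
    of the terms in (b).

    Empty hyperedges are dropped with a warning (at least one must remain);
    vertices belonging to no hyperedge are pruned and recorded.
    """
    schema = {
        "disease_metabolite": ("disease", "metabolite"),
        "disease_go": ("disease", "go_term"),
        "protein_go": ("protein", "go_term"),
        "metabolite_protein": ("metabolite", "protein"),
    }
    for table, rows in associations.as_dict().items():
        src_t, dst_t = schema[table]
        for pair in rows:
            _check_row(pair, table, catalog, src_t, dst_t)

    diseases = catalog.ids_of_type("disease")
    if not diseases:
        raise ValueError("no hyperedges: catalog contains no diseases")

    met_of_disease: dict[str, set[str]] = {d: set() for d in diseases}
    go_of_disease: dict[str, set[str]] = {d: set() for d in diseases}
    for d, m in associations.disease_metabolite:
        met_of_disease[d].add(m)
    for d, g in associations.disease_go:
        go_of_disease[d].add(g)

    prot_of_met: dict[str, set[str]] = {}
    for m, p in associations.metabolite_protein:
        prot_of_met.setdefault(m, set()).add(p)
    prot_of_go: dict[str, set[str]] = {}
    for p, g in associations.protein_go:
        prot_of_go.setdefault(g, set()).add(p)

    membership: dict[str, set[str]] = {}
    for d in diseases:
        members = set(met_of_disease[d]) | set(go_of_disease[d])
        for m in met_of_disease[d]:
            members |= prot_of_met.get(m, set())
        if protein_via_go:
            for g in go_of_disease[d]:
                members |= prot_of_go.get(g, set())
        membership[d] = members

    kept = [d for d in diseases if membership[d]]
    dropped = [d for d in diseases if not membership[d]]
    if not kept:
        raise ValueError("no hyperedges: every disease has an empty membership set")
    if dropped:
        warnings.warn(f"dropping {len(dropped)} empty disease hyperedges: {dropped[:5]}...")

    all_vertices = [v for t in VERTEX_TYPES for v in catalog.ids_of_type(t)]
    used = set().union(*(membership[d] for d in kept))
    vertex_ids = [v for v in all_vertices if v in used]
    pruned = [v for v in all_vertices if v not in used]

    v_index = {v: i for i, v in enumerate(vertex_ids)}
    rows, cols = [], []
    for j, d in enumerate(kept):
        for v in membership[d]:
            rows.append(v_index[v])
            cols.append(j)
    incidence = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(vertex_ids), len(kept)),
    )
    vertex_types = [catalog.type_of(v) for v in vertex_ids]
    return Hypergraph(vertex_ids, kept, incidence, vertex_types,
                      pruned_vertices=pruned, dropped_hyperedges=dropped)


def degree_pair(h: Hypergraph) -> DegreePair:
    """Row sums (vertex degrees) and column sums (hyperedge degrees)."""
    dv = np.asarray(h.incidence.sum(axis=1)).ravel().astype(np.int64)
    de = np.asarray(h.incidence.sum(axis=0)).ravel().astype(np.int64)
    return DegreePair(vertex_degrees=dv, hyperedge_degrees=de)


def summarize(h: Hypergraph) -> StatsSummary:
    """Distribution summaries of hyperedge sizes and vertex degrees.

    The median of an even-length list is the mean of the two central
    order statistics (numpy's convention).
    """
    deg = degree_pair(h)
    sizes = deg.hyperedge_degrees
    counts = {t: 0 for t in VERTEX_TYPES}
    for t in h.vertex_types:
        counts[t] += 1
    return StatsSummary(
        hyperedge_size_median=float(np.median(sizes)),
        hyperedge_size_mean=float(np.mean(sizes)),
        hyperedge_size_max=int(sizes.max()),
        vertex_degree_median=float(np.median(deg.vertex_degrees)),
        type_counts=counts,
        total_vertices=h.n_vertices,
        total_hyperedges=h.n_hyperedges,
    )
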