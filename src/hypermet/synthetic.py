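"""Seeded synthetic worlds with planted module structure.

A world emulates the statistical structure the pipeline exploits in real
data — structurally similar metabolites share disease associations —
without any download: entities are assigned to latent modules, every
association type is drawn Bernoulli(p_in) within a module and
Bernoulli(p_out) across, metabolite fingerprints share a module-specific
bit block, protein sequences are mutated copies of a module ancestor, and
the GO hierarchy is a forest of per-module trees under one root.  The
module assignment is the recoverable ground truth used by separation and
classification tests.

``toy_fixture`` returns the tiny hand-checkable instances referenced
throughout the unit tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .catalog import EntityCatalog
from .godag import GoDag
from .hypergraph import AssociationTables
from .similarity import Fingerprint

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SynthConfig:
    n_diseases: int = 50
    n_metabolites: int = 300
    n_proteins: int = 100
    n_go: int = 160
    n_modules: int = 4
    p_in: float = 0.1
    p_out: float = 0.003
    fp_bits: int = 2048
    fp_module_block: int = 64
    fp_noise_bits: int = 16
    seq_length: int = 120
    seq_mutation_rate: float = 0.1
    go_branching: int = 3
    go_depth: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_out < self.p_in <= 1:
            raise ValueError("need 0 <= p_out < p_in <= 1")
        counts = (self.n_diseases, self.n_metabolites, self.n_proteins, self.n_go)
        if any(c < self.n_modules for c in counts):
            raise ValueError("every entity count must be >= n_modules")
        if self.n_modules * self.fp_module_block + self.fp_noise_bits > self.fp_bits:
            raise ValueError("fingerprint blocks do not fit in fp_bits")


@dataclass
class SynthWorld:
    catalog: EntityCatalog
    tables: AssociationTables
    fingerprints: dict[str, Fingerprint]
    sequences: dict[str, str]
    godag: GoDag
    module_of: dict[str, int]
    config: SynthConfig = field(default_factory=SynthConfig)

    def positives(self) -> list[tuple[str, str]]:
        """Known (disease, metabolite) association pairs."""
        return list(dict.fromkeys(self.tables.disease_metabolite))


def _bernoulli_links(
    rng: np.random.Generator,
    src_ids: list[str],
    dst_ids: list[str],
    src_mod: np.ndarray,
    dst_mod: np.ndarray,
    p_in: float,
    p_out: float,
) -> list[tuple[str, str]]:
    same = src_mod[:, None] == dst_mod[None, :]
    p = np.where(same, p_in, p_out)
    draw = rng.random(p.shape) < p
    ii, jj = np.nonzero(draw)
    return [(src_ids[i], dst_ids[j]) for i, j in zip(ii.tolist(), jj.tolist())]


def _module_godag(go_ids: list[str], go_mod: np.ndarray, config: SynthConfig,
                  root: str) -> GoDag:
    """Forest of per-module b-ary trees under a single shared root."""
    links: list[tuple[str, str]] = []
    depth: dict[str, int] = {root: 0}
    parent_of: dict[str, str] = {}
    for mod in range(config.n_modules):
        members = [g for g, m in zip(go_ids, go_mod.tolist()) if m == mod]
        for i, term in enumerate(members):
            if i == 0:
                parent = root
            else:
                parent = members[(i - 1) // config.go_branching]
                while depth[parent] >= config.go_depth:  # cap tree depth
                    parent = parent_of[parent]
            links.append((term, parent))
            parent_of[term] = parent
            depth[term] = depth[parent] + 1
    return GoDag.from_edges([root] + go_ids, links)


def generate_world(config: SynthConfig | None = None) -> SynthWorld:
    """Draw a complete world from the config; same config + seed => same world."""
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    L = config.n_modules

    dis_ids = [f"D{i:04d}" for i in range(config.n_diseases)]
    met_ids = [f"M{i:04d}" for i in range(config.n_metabolites)]
    pro_ids = [f"P{i:04d}" for i in range(config.n_proteins)]
    go_root = "GO:0000000"
    go_ids = [f"GO:{i + 1:07d}" for i in range(config.n_go)]

    # Uniform module assignment, with each module guaranteed >= 1 member
    # per entity type (first L entities cycle through the modules).
    def assign(n: int) -> np.ndarray:
        base = np.arange(n) % L
        return base[rng.permutation(n)]

    dis_mod = assign(config.n_diseases)
    met_mod = assign(config.n_metabolites)
    pro_mod = assign(config.n_proteins)
    go_mod = assign(config.n_go)

    tables = AssociationTables(
        disease_metabolite=_bernoulli_links(rng, dis_ids, met_ids, dis_mod, met_mod,
                                            config.p_in, config.p_out),
        disease_go=_bernoulli_links(rng, dis_ids, go_ids, dis_mod, go_mod,
                                    config.p_in, config.p_out),
        protein_go=_bernoulli_links(rng, pro_ids, go_ids, pro_mod, go_mod,
                                    config.p_in, config.p_out),
        metabolite_protein=_bernoulli_links(rng, met_ids, pro_ids, met_mod, pro_mod,
                                            config.p_in, config.p_out),
    )

    # Every disease must keep at least one metabolite member.
    linked = {d for d, _ in tables.disease_metabolite}
    for d, mod in zip(dis_ids, dis_mod.tolist()):
        if d not in linked:
            within = [m for m, mm in zip(met_ids, met_mod.tolist()) if mm == mod]
            tables.disease_metabolite.append((d, within[rng.integers(len(within))]))

    # Fingerprints: full module block plus uniform noise bits from the tail range.
    noise_lo = L * config.fp_module_block
    fingerprints: dict[str, Fingerprint] = {}
    for m, mod in zip(met_ids, met_mod.tolist()):
        block = range(mod * config.fp_module_block, (mod + 1) * config.fp_module_block)
        noise = rng.integers(noise_lo, config.fp_bits, size=config.fp_noise_bits)
        fingerprints[m] = Fingerprint.from_bits(set(block) | set(noise.tolist()),
                                                config.fp_bits)

    # Protein sequences: per-module ancestor with i.i.d. substitutions.
    aa = np.array(list(_AA))
    ancestors = [rng.integers(0, len(_AA), size=config.seq_length) for _ in range(L)]
    sequences: dict[str, str] = {}
    for p, mod in zip(pro_ids, pro_mod.tolist()):
        seq = ancestors[mod].copy()
        mutate = rng.random(config.seq_length) < config.seq_mutation_rate
        seq[mutate] = rng.integers(0, len(_AA), size=int(mutate.sum()))
        sequences[p] = "".join(aa[seq])

    godag = _module_godag(go_ids, go_mod, config, go_root)

    catalog = EntityCatalog()
    catalog.add_all(met_ids, "metabolite")
    catalog.add_all(pro_ids, "protein")
    catalog.add_all([go_root] + go_ids, "go_term")
    catalog.add_all(dis_ids, "disease")

    module_of: dict[str, int] = {}
    for ids, mods in ((dis_ids, dis_mod), (met_ids, met_mod),
                      (pro_ids, pro_mod), (go_ids, go_mod)):
        module_of.update(zip(ids, mods.tolist()))
    module_of[go_root] = -1  # shared root belongs to no module

    return SynthWorld(catalog, tables, fingerprints, sequences, godag,
                      module_of, config)


# ---------------------------------------------------------------------------
# Hand-checkable fixtures


def _fixture_pair_edge() -> SynthWorld:
    """One disease hyperedge over two vertices (a metabolite and a GO term)."""
    catalog = EntityCatalog()
    catalog.add("m1", "metabolite")
    catalog.add("g1", "go_term")
    catalog.add("d1", "disease")
    tables = AssociationTables(disease_metabolite=[("d1", "m1")],
                               disease_go=[("d1", "g1")])
    dag = GoDag.from_edges(["g1"], [])
    fp = {"m1": Fingerprint.from_bits({0, 1}, 16)}
    return SynthWorld(catalog, tables, fp, {}, dag,
                      {"m1": 0, "g1": 0, "d1": 0}, SynthConfig())


def _fixture_triple_edge() -> SynthWorld:
    """Three vertices, two hyperedges; incidence [[1,0],[1,1],[0,1]]."""
    catalog = EntityCatalog()
    catalog.add_all(["m1", "m2"], "metabolite")
    catalog.add("g1", "go_term")
    catalog.add_all(["d1", "d2"], "disease")
    tables = AssociationTables(
        disease_metabolite=[("d1", "m1"), ("d1", "m2"), ("d2", "m2")],
        disease_go=[("d2", "g1")],
    )
    dag = GoDag.from_edges(["g1"], [])
    fp = {m: Fingerprint.from_bits({i}, 16) for i, m in enumerate(["m1", "m2"])}
    return SynthWorld(catalog, tables, fp, {}, dag,
                      {k: 0 for k in ["m1", "m2", "g1", "d1", "d2"]}, SynthConfig())


def _fixture_go_chain() -> SynthWorld:
    """GO chain root -> a -> b: sim(a, b) = 2/3, sim(root, b) = 1/3."""
    catalog = EntityCatalog()
    catalog.add("m1", "metabolite")
    catalog.add_all(["root", "a", "b"], "go_term")
    catalog.add("d1", "disease")
    tables = AssociationTables(disease_metabolite=[("d1", "m1")],
                               disease_go=[("d1", "b")])
    dag = GoDag.from_edges(["root", "a", "b"], [("a", "root"), ("b", "a")])
    fp = {"m1": Fingerprint.from_bits({0}, 16)}
    return SynthWorld(catalog, tables, fp, {}, dag,
                      {k: 0 for k in ["m1", "root", "a", "b", "d1"]}, SynthConfig())


def _fixture_indirect_toy() -> SynthWorld:
    """Two-hop filter toy: protein p1 reaches d1, only m2 touches p1,
    so the indirect exclusion set is exactly {(m2, d1)}."""
    catalog = EntityCatalog()
    catalog.add_all(["m1", "m2", "m3", "m4"], "metabolite")
    catalog.add("p1", "protein")
    catalog.add("g1", "go_term")
    catalog.add("d1", "disease")
    tables = AssociationTables(
        disease_metabolite=[("d1", "m1")],
        disease_go=[("d1", "g1")],
        protein_go=[("p1", "g1")],
        metabolite_protein=[("m2", "p1")],
    )
    dag = GoDag.from_edges(["g1"], [])
    fp = {m: Fingerprint.from_bits({i}, 16)
          for i, m in enumerate(["m1", "m2", "m3", "m4"])}
    return SynthWorld(catalog, tables, fp, {"p1": "MKV"}, dag,
                      {k: 0 for k in ["m1", "m2", "m3", "m4", "p1", "g1", "d1"]},
                      SynthConfig())


_FIXTURES = {
    "pair_edge": _fixture_pair_edge,
    "triple_edge": _fixture_triple_edge,
    "go_chain": _fixture_go_chain,
    "indirect_toy": _fixture_indirect_toy,
}


def toy_fixture(name: str) -> SynthWorld:
    """Return a named hand-checkable world; stable across releases."""
    try:
        return _FIXTURES[name]()
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
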