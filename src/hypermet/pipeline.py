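"""End-to-end orchestration: world -> hypergraph -> features -> embeddings
-> labeled pairs -> cross-validated classifier.

Every stage draws its seed deterministically from one root seed
(``stage_seed``), so a whole experiment is reproducible from a single
integer.  Problem sizes (embedding width, autoencoder epochs) default to
desk-scale values suitable for synthetic worlds; the per-stage configs
accept the full-scale settings as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .association import LabeledPairSet, indirect_pairs, sample_negatives
from .autoencoder import AutoencoderConfig, per_type_autoencode
from .evaluation import CvReport, cross_validate
from .hgnn import EmbeddingSet, HgnnConfig, TrainedHgnn, hyperedge_embeddings, train_embeddings
from .hypergraph import Hypergraph, build_hypergraph
from .similarity import (
    SimilarityMatrix,
    go_similarity_matrix,
    protein_similarity_from_sequences,
    tanimoto_matrix,
)
from .synthetic import SynthWorld

_STAGES = ("similarity", "autoencoder", "hgnn", "sampling", "cv")


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed expansion from one root seed."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    return (root_seed * 10007 + _STAGES.index(stage) + 1) % (2**31)


@dataclass
class PipelineConfig:
    embed_dim: int = 64
    hidden_dim: int = 64
    dropout: float = 0.4
    weight_decay: float = 5e-5
    learning_rate: float = 0.01  # desk-scale worlds train in far fewer epochs
    max_epochs: int = 60
    patience: int = 10
    ae_max_epochs: int = 300
    protein_mode: str = "identity_fraction"
    protein_via_go: bool = False
    ratio: int = 1
    k: int = 5
    classifier_params: dict = field(default_factory=dict)
    seed: int = 0

    def hgnn_config(self) -> HgnnConfig:
        return HgnnConfig(
            embed_dim=self.embed_dim,
            hidden_dim=self.hidden_dim,
            dropout=self.dropout,
            weight_decay=self.weight_decay,
            learning_rate=self.learning_rate,
            max_epochs=self.max_epochs,
            patience=self.patience,
            seed=stage_seed(self.seed, "hgnn"),
        )


def world_similarities(
    world: SynthWorld, protein_mode: str = "identity_fraction"
) -> dict[str, SimilarityMatrix]:
    """The three per-type similarity matrices of a world."""
    met_ids = world.catalog.ids_of_type("metabolite")
    go_ids = world.catalog.ids_of_type("go_term")
    out = {
        "metabolite": tanimoto_matrix([world.fingerprints[m] for m in met_ids], met_ids),
        "go_term": go_similarity_matrix(world.godag, go_ids),
    }
    pro_ids = world.catalog.ids_of_type("protein")
    if pro_ids:
        seqs = {p: world.sequences[p] for p in pro_ids}
        out["protein"] = protein_similarity_from_sequences(seqs, mode=protein_mode)
    return out


def embed_world(
    world: SynthWorld, config: PipelineConfig | None = None
) -> tuple[Hypergraph, EmbeddingSet, EmbeddingSet, TrainedHgnn]:
    """Hypergraph construction, per-type reduction, HGNN training, aggregation.

    Returns (hypergraph, vertex embeddings, disease hyperedge embeddings,
    training diagnostics).
    """
    config = config or PipelineConfig()
    h = build_hypergraph(world.tables, world.catalog,
                         protein_via_go=config.protein_via_go)
    sims = world_similarities(world, protein_mode=config.protein_mode)

    encoded: dict[str, dict[str, np.ndarray]] = {}
    ae_seed = stage_seed(config.seed, "autoencoder")
    for offset, (etype, sim) in enumerate(sorted(sims.items())):
        ae_cfg = AutoencoderConfig(max_epochs=config.ae_max_epochs,
                                   seed=ae_seed + offset)
        rows = per_type_autoencode(sim, config.embed_dim, ae_cfg)
        encoded[etype] = dict(zip(sim.labels, rows))

    features = np.vstack([
        encoded[etype][vid]
        for vid, etype in zip(h.vertex_ids, h.vertex_types)
    ])
    trained = train_embeddings(h, features, config.hgnn_config())
    disease_emb = hyperedge_embeddings(trained.embeddings, h)
    return h, trained.embeddings, disease_emb, trained


def derive_protein_disease(h: Hypergraph) -> list[tuple[str, str]]:
    """(protein, disease) links implied by hyperedge membership."""
    out = []
    for j, d in enumerate(h.hyperedge_ids):
        col = h.incidence.getcol(j).nonzero()[0]
        for i in col:
            if h.vertex_types[i] == "protein":
                out.append((h.vertex_ids[i], d))
    return out


def sample_world_pairs(
    world: SynthWorld, h: Hypergraph, ratio: int, seed: int
) -> tuple[LabeledPairSet, set[tuple[str, str]]]:
    """Positives from the world plus filtered uniform negatives.

    The sampling grid is restricted to diseases and metabolites that made
    it into the hypergraph (transductive setting: only those have
    embeddings).
    """
    from .catalog import EntityCatalog

    indirect = indirect_pairs(world.tables.metabolite_protein,
                              derive_protein_disease(h))
    grid = EntityCatalog()
    in_graph = set(h.vertex_ids)
    grid.add_all([m for m in world.catalog.ids_of_type("metabolite")
                  if m in in_graph], "metabolite")
    grid.add_all(h.hyperedge_ids, "disease")
    positives = [(d, m) for d, m in world.positives()
                 if m in in_graph and d in set(h.hyperedge_ids)]
    pairs = sample_negatives(positives, grid, ratio=ratio,
                             indirect=indirect, seed=seed)
    return pairs, indirect


@dataclass
class ExperimentResult:
    hypergraph: Hypergraph
    vertex_embeddings: EmbeddingSet
    disease_embeddings: EmbeddingSet
    pairs: LabeledPairSet
    report: CvReport
    trained: TrainedHgnn


def ratio_trend_study(
    n_replicates: int = 10,
    base_seed: int = 0,
    world_config=None,
    pipe_config: PipelineConfig | None = None,
    ratios: tuple[int, int] = (1, 10),
) -> list[dict[str, float]]:
    """Seeded replicates of the class-imbalance sweep at the two extreme
    ratios; used to check the expected direction (specificity rises,
    sensitivity falls as negatives outnumber positives).

    Returns one dict per replicate with SEN/SPE at each ratio.
    """
    from dataclasses import replace as dc_replace

    from .synthetic import SynthConfig, generate_world

    world_config = world_config or SynthConfig()
    pipe_config = pipe_config or PipelineConfig()
    out = []
    for rep in range(n_replicates):
        seed = (base_seed + 7919 * (rep + 1)) % (2**31)
        world = generate_world(dc_replace(world_config, seed=seed))
        cfg = dc_replace(pipe_config, seed=seed)
        h, vertex_emb, disease_emb, _ = embed_world(world, cfg)
        met_ids = [m for m in world.catalog.ids_of_type("metabolite")
                   if m in set(h.vertex_ids)]
        met_emb = vertex_emb.subset(met_ids)
        row: dict[str, float] = {"seed": seed}
        for r in ratios:
            pairs, _ = sample_world_pairs(world, h, r,
                                          stage_seed(seed, "sampling") + r)
            rep_cv = cross_validate(pairs, disease_emb, met_emb,
                                    cfg.classifier_params, k=cfg.k,
                                    seed=stage_seed(seed, "cv"))
            row[f"SEN@{r}"] = rep_cv.mean["SEN"]
            row[f"SPE@{r}"] = rep_cv.mean["SPE"]
        out.append(row)
    return out


def run_experiment(
    world: SynthWorld, config: PipelineConfig | None = None
) -> ExperimentResult:
    """The full study on one world: embed, sample, cross-validate."""
    config = config or PipelineConfig()
    h, vertex_emb, disease_emb, trained = embed_world(world, config)
    pairs, _ = sample_world_pairs(world, h, config.ratio,
                                  stage_seed(config.seed, "sampling"))
    met_ids = world.catalog.ids_of_type("metabolite")
    met_emb = vertex_emb.subset([m for m in met_ids if m in vertex_emb.index()])
    report = cross_validate(pairs, disease_emb, met_emb,
                            config.classifier_params, k=config.k,
                            seed=stage_seed(config.seed, "cv"))
    return ExperimentResult(h, vertex_emb, disease_emb, pairs, report, trained)
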