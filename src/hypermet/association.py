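"""Labeled disease-metabolite pairs, filtered negative sampling, pair
features, and the gradient-boosted pair classifier.

Negative pairs are drawn uniformly without replacement from the full
disease x metabolite grid after removing (a) the known positives and (b)
pairs linked by any two-hop metabolite-protein-disease path, the most
likely hiding places for undiscovered true associations.  Each sampled
set is verified, not assumed, to be disjoint from both exclusion sets.

A pair's feature row is the disease hyperedge embedding concatenated
with the metabolite vertex embedding (disease block first), giving a
2 x embed_dim wide matrix fed to a leaf-wise gradient-boosted tree
ensemble (LightGBM, leaf L2 coefficient 0.1, otherwise library defaults).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .catalog import EntityCatalog
from .hgnn import EmbeddingSet

# Candidate pools are materialized explicitly below this grid size and
# rejection-sampled above it.
POOL_MATERIALIZE_LIMIT = 10_000_000


@dataclass
class LabeledPairSet:
    """(disease_id, metabolite_id, label) triples with the sampling ratio."""

    diseases: list[str]
    metabolites: list[str]
    labels: np.ndarray
    ratio: int = 1

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        n = len(self.diseases)
        if len(self.metabolites) != n or len(self.labels) != n:
            raise ValueError("pair set columns have unequal lengths")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")
        pairs = list(zip(self.diseases, self.metabolites))
        if len(set(pairs)) != n:
            raise ValueError("duplicate (disease, metabolite) rows")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.diseases, self.metabolites))

    def positives(self) -> set[tuple[str, str]]:
        return {p for p, y in zip(self.pairs, self.labels) if y == 1}

    def negatives(self) -> set[tuple[str, str]]:
        return {p for p, y in zip(self.pairs, self.labels) if y == 0}


def indirect_pairs(
    metabolite_protein: Iterable[tuple[str, str]],
    protein_disease: Iterable[tuple[str, str]],
) -> set[tuple[str, str]]:
    """Exactly the (metabolite, disease) pairs joined by a shared protein."""
    diseases_of_protein: dict[str, set[str]] = {}
    for p, d in protein_disease:
        diseases_of_protein.setdefault(p, set()).add(d)
    out: set[tuple[str, str]] = set()
    for m, p in metabolite_protein:
        for d in diseases_of_protein.get(p, ()):
            out.add((m, d))
    return out


def sample_negatives(
    positives: Sequence[tuple[str, str]],
    catalog: EntityCatalog,
    ratio: int,
    indirect: set[tuple[str, str]] | None = None,
    seed: int = 0,
) -> LabeledPairSet:
    """Uniform negative sample over the filtered candidate pool.

    ``positives`` are (disease, metabolite) pairs; ``indirect`` holds
    (metabolite, disease) pairs excluded by the two-hop filter.  The
    returned set contains all positives (label 1) plus ratio x |positives|
    verified negatives (label 0).
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    positives = list(dict.fromkeys(positives))
    if not positives:
        raise ValueError("no positive pairs given")
    indirect_dm = {(d, m) for (m, d) in (indirect or set())}
    diseases = catalog.ids_of_type("disease")
    metabolites = catalog.ids_of_type("metabolite")
    excluded = set(positives) | indirect_dm
    n_needed = ratio * len(positives)
    grid = len(diseases) * len(metabolites)
    rng = np.random.default_rng(seed)

    if grid <= POOL_MATERIALIZE_LIMIT:
        pool = [(d, m) for d in diseases for m in metabolites if (d, m) not in excluded]
        if len(pool) < n_needed:
            raise ValueError(
                f"candidate pool too small: {len(pool)} pairs available, "
                f"{n_needed} required (ratio {ratio} x {len(positives)} positives)"
            )
        idx = rng.choice(len(pool), size=n_needed, replace=False)
        negatives = [pool[i] for i in sorted(idx)]
    else:  # rejection sampling over the implicit grid
        if grid - len(excluded) < n_needed:
            raise ValueError(
                f"candidate pool too small: {grid - len(excluded)} pairs available, "
                f"{n_needed} required"
            )
        chosen: set[tuple[str, str]] = set()
        while len(chosen) < n_needed:
            d = diseases[rng.integers(len(diseases))]
            m = metabolites[rng.integers(len(metabolites))]
            if (d, m) not in excluded and (d, m) not in chosen:
                chosen.add((d, m))
        negatives = sorted(chosen)

    # Verification pass: the disjointness is proven, not assumed.
    overlap = set(negatives) & excluded
    if overlap:
        raise AssertionError(f"sampled negatives overlap exclusions: {sorted(overlap)[:5]}")

    ds = [d for d, _ in positives] + [d for d, _ in negatives]
    ms = [m for _, m in positives] + [m for _, m in negatives]
    labels = np.concatenate([np.ones(len(positives), int), np.zeros(len(negatives), int)])
    return LabeledPairSet(ds, ms, labels, ratio=ratio)


@dataclass
class PairFeatureMatrix:
    """Row-aligned concatenated [disease ‖ metabolite] embedding features."""

    values: np.ndarray
    pair_set: LabeledPairSet
    embed_dim: int

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.pair_set), 2 * self.embed_dim):
            raise ValueError("feature matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("pair features contain non-finite values")


def build_pair_features(
    pairs: LabeledPairSet,
    disease_emb: EmbeddingSet,
    metabolite_emb: EmbeddingSet,
) -> PairFeatureMatrix:
    """Row = [disease vector ‖ metabolite vector], disease block first."""
    if disease_emb.dim != metabolite_emb.dim:
        raise ValueError(
            f"embedding dims differ: disease {disease_emb.dim} vs "
            f"metabolite {metabolite_emb.dim}"
        )
    d_idx = disease_emb.index()
    m_idx = metabolite_emb.index()
    rows = np.empty((len(pairs), 2 * disease_emb.dim))
    for i, (d, m) in enumerate(pairs.pairs):
        if d not in d_idx:
            raise KeyError(f"no embedding for disease {d!r}")
        if m not in m_idx:
            raise KeyError(f"no embedding for metabolite {m!r}")
        rows[i, : disease_emb.dim] = disease_emb.vectors[d_idx[d]]
        rows[i, disease_emb.dim:] = metabolite_emb.vectors[m_idx[m]]
    return PairFeatureMatrix(rows, pairs, disease_emb.dim)


@dataclass
class BoostedModel:
    """Trained leaf-wise gradient-boosted tree ensemble for pair classification."""

    booster: object
    params: dict = field(default_factory=dict)
    n_features: int = 0

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        if features.size and features.shape[1] != self.n_features:
            raise ValueError(
                f"feature width {features.shape[1]} != training width {self.n_features}"
            )
        if features.shape[0] == 0:
            return np.empty(0)
        import warnings

        with warnings.catch_warnings():
            # fit() saw a bare ndarray too; the feature-name warning is noise
            warnings.filterwarnings("ignore", message=".*valid feature names.*")
            return self.booster.predict_proba(features)[:, 1]

    @property
    def feature_importances(self) -> np.ndarray:
        return np.asarray(self.booster.feature_importances_, dtype=float)


def train_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    params: dict | None = None,
    seed: int = 0,
) -> BoostedModel:
    """Fit the LightGBM pair classifier.

    Defaults follow the library except the leaf L2 coefficient (0.1); no
    hyperparameter search.  Single-threaded and seeded for reproducibility.
    """
    import lightgbm

    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if features.shape[0] != labels.shape[0]:
        raise ValueError("features and labels are misaligned")
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels contain a single class")
    merged = {
        "reg_lambda": 0.1,
        "random_state": seed,
        "n_jobs": 1,
        "deterministic": True,
        "force_row_wise": True,
        "verbosity": -1,
    }
    merged.update(params or {})
    clf = lightgbm.LGBMClassifier(**merged)
    clf.fit(features, labels)
    return BoostedModel(booster=clf, params=merged, n_features=features.shape[1])


class _LoadedBooster:
    """predict_proba shim around a bare lightgbm Booster loaded from disk."""

    def __init__(self, booster):
        self._booster = booster

    def predict_proba(self, x):
        p1 = np.asarray(self._booster.predict(x))
        return np.column_stack([1.0 - p1, p1])

    @property
    def feature_importances_(self):
        return self._booster.feature_importance()


def save_model(model: BoostedModel, path) -> None:
    """Serialize to a single text file plus a JSON sidecar (params, width)."""
    import json
    from pathlib import Path

    path = Path(path)
    model.booster.booster_.save_model(str(path))
    sidecar = {"params": {k: v for k, v in model.params.items()},
               "n_features": model.n_features}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path) -> BoostedModel:
    import json
    from pathlib import Path

    import lightgbm

    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    booster = lightgbm.Booster(model_file=str(path))
    return BoostedModel(booster=_LoadedBooster(booster),
                        params=sidecar["params"], n_features=sidecar["n_features"])


def predict_pairs(
    model: BoostedModel, features: np.ndarray, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Scores (unrounded probabilities) and hard labels (1 iff score >= threshold)."""
    scores = model.predict_proba(features)
    return scores, (scores >= threshold).astype(int)


def rank_metabolites(
    model: BoostedModel,
    disease_id: str,
    candidates: Sequence[str],
    disease_emb: EmbeddingSet,
    metabolite_emb: EmbeddingSet,
) -> list[tuple[str, float]]:
    """Candidates sorted by descending score; ties broken by metabolite id."""
    if disease_id not in disease_emb.index():
        raise KeyError(f"unknown disease {disease_id!r}")
    candidates = list(candidates)
    pairs = LabeledPairSet([disease_id] * len(candidates), candidates,
                           np.zeros(len(candidates), int))
    feats = build_pair_features(pairs, disease_emb, metabolite_emb)
    scores, _ = predict_pairs(model, feats.values)
    order = sorted(range(len(candidates)), key=lambda i: (-scores[i], candidates[i]))
    return [(candidates[i], float(scores[i])) for i in order]
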