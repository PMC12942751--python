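"""Spectral hypergraph message passing and self-supervised embedding training.

The smoothing operator

    Θ = D_v^{-1/2} H W_e D_e^{-1} Hᵀ D_v^{-1/2},    W_e = I,

performs one vertex -> hyperedge -> vertex round of degree-normalized
message passing (hypergraph Laplacian smoothing).  Two layers of
``activation(Θ X W)`` map the stacked per-type features to the embedding
space.  Because no association labels may leak into the classifier's
inputs, the layer weights are trained self-supervised: the embeddings
must reconstruct hyperedge membership, scoring each (vertex, hyperedge)
pair as sigmoid(z_v · a_e) with a_e the mean of the member embeddings,
against binary cross-entropy on the incidence matrix.

Everything runs on CPU in NumPy; gradients are derived by hand and
optimized with Adam (learning rate, betas, L2 weight decay, dropout and
early stopping per :class:`HgnnConfig`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .hypergraph import Hypergraph, degree_pair
from .optim import Adam, fan_in_uniform

# Above this many incidence cells the training objective switches from the
# dense full-incidence loss to 1:1 sampled positive/negative pairs.
DENSE_CELL_LIMIT = 5_000_000


@dataclass
class HgnnConfig:
    n_layers: int = 2
    embed_dim: int = 500
    hidden_dim: int = 500
    dropout: float = 0.4
    weight_decay: float = 5e-5
    learning_rate: float = 0.001
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    max_epochs: int = 200
    patience: int = 10
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.patience > self.max_epochs:
            raise ValueError("patience cannot exceed max_epochs")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")


@dataclass
class EmbeddingSet:
    """Fixed-width real vectors for a set of entities (vertices or hyperedges)."""

    ids: list[str]
    vectors: np.ndarray
    role: str  # "vertex" or "hyperedge"

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.ids):
            raise ValueError("vectors shape does not match ids")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding vectors contain non-finite values")
        if self.role not in ("vertex", "hyperedge"):
            raise ValueError(f"unknown role {self.role!r}")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def index(self) -> dict[str, int]:
        return {e: i for i, e in enumerate(self.ids)}

    def get(self, entity_id: str) -> np.ndarray:
        try:
            return self.vectors[self.index()[entity_id]]
        except KeyError:
            raise KeyError(f"no embedding for entity {entity_id!r}") from None

    def subset(self, ids: list[str]) -> "EmbeddingSet":
        idx = self.index()
        missing = [i for i in ids if i not in idx]
        if missing:
            raise KeyError(f"no embedding for entities {missing[:5]}")
        return EmbeddingSet(list(ids), self.vectors[[idx[i] for i in ids]], self.role)


class SmoothingOperator:
    """Θ held in factored sparse form; applied without materialization.

    The factors are H_s = D_v^{-1/2} H and the exact diagonal D_e^{-1},
    so Θ = H_s D_e^{-1} H_sᵀ (keeping D_e^{-1} unsplit avoids square-root
    rounding on hand-checkable instances)."""

    def __init__(self, h_scaled: sp.csr_matrix, de_inv: np.ndarray, n_vertices: int):
        self._hs = h_scaled
        self._de_inv = de_inv
        self.shape = (n_vertices, n_vertices)

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Θ @ x, exploiting the |V| x |E| factorization."""
        return np.asarray(self._hs @ (self._de_inv[:, None] * (self._hs.T @ x)))

    def dense(self) -> np.ndarray:
        """Materialize Θ (small instances only)."""
        return np.asarray((self._hs @ sp.diags(self._de_inv) @ self._hs.T).todense())


def build_smoothing_operator(h: Hypergraph) -> SmoothingOperator:
    """Θ = D_v^{-1/2} H D_e^{-1} Hᵀ D_v^{-1/2} with identity hyperedge weights."""
    deg = degree_pair(h)
    if (deg.vertex_degrees == 0).any() or (deg.hyperedge_degrees == 0).any():
        raise ValueError("smoothing operator requires no zero-degree vertex or empty hyperedge")
    dv_isqrt = 1.0 / np.sqrt(deg.vertex_degrees.astype(float))
    de_inv = 1.0 / deg.hyperedge_degrees.astype(float)
    hs = (sp.diags(dv_isqrt) @ h.incidence.astype(float)).tocsr()
    return SmoothingOperator(hs, de_inv, h.n_vertices)


def hgnn_layer(
    x: np.ndarray,
    theta: SmoothingOperator,
    w: np.ndarray,
    training: bool = False,
    config: HgnnConfig | None = None,
    activation: str = "relu",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One message-passing layer: activation(Θ · X · W), inverted dropout
    after the activation when ``training`` is set.  Eval mode is deterministic."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] != theta.shape[0]:
        raise ValueError(f"feature rows {x.shape} do not match operator {theta.shape}")
    if w.shape[0] != x.shape[1]:
        raise ValueError(f"weight shape {w.shape} incompatible with features {x.shape}")
    out = theta.apply(x) @ w
    if activation == "relu":
        out = np.maximum(out, 0.0)
    elif activation != "identity":
        raise ValueError(f"unknown activation {activation!r}")
    if training:
        config = config or HgnnConfig()
        p = config.dropout
        if p > 0:
            rng = rng or np.random.default_rng(config.seed)
            mask = rng.random(out.shape) >= p
            out = out * mask / (1.0 - p)
    return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _bce(p: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    eps = 1e-12
    ll = y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)
    return float(-(w * ll).sum() / w.sum())


class _Objective:
    """Hyperedge-membership reconstruction loss on a column split.

    A seeded fraction of hyperedge columns is held out for validation;
    holding out columns (not individual cells) keeps the objective
    equivariant under vertex permutation.  Positive incidence cells are
    up-weighted to balance the (much larger) negative cell mass, which is
    the dense deterministic equivalent of 1:1 negative pair sampling.
    """

    def __init__(self, incidence: sp.csr_matrix, cfg: HgnnConfig, rng: np.random.Generator):
        n_v, n_e = incidence.shape
        self.y = np.asarray(incidence.todense(), dtype=float)
        de = self.y.sum(axis=0)
        self.m_agg = self.y / de  # |V| x |E|, column-normalized (mean aggregation)
        if n_e >= 5:
            n_val = max(1, int(round(cfg.val_fraction * n_e)))
            perm = rng.permutation(n_e)
            val_cols = np.zeros(n_e, dtype=bool)
            val_cols[perm[:n_val]] = True
        else:
            val_cols = np.zeros(n_e, dtype=bool)  # too few hyperedges: validate on train
        self.train_w = self._weights(~val_cols if val_cols.any() else np.ones(n_e, bool))
        self.val_w = self._weights(val_cols if val_cols.any() else np.ones(n_e, bool))

    def _weights(self, cols: np.ndarray) -> np.ndarray:
        w = np.zeros_like(self.y)
        sub = self.y[:, cols]
        n_pos = sub.sum()
        n_neg = sub.size - n_pos
        pos_w = (n_neg / n_pos) if n_pos > 0 else 1.0
        w[:, cols] = np.where(self.y[:, cols] == 1, pos_w, 1.0)
        return w

    def scores(self, z: np.ndarray) -> np.ndarray:
        a = self.m_agg.T @ z          # hyperedge aggregates, |E| x d
        return _sigmoid(z @ a.T)      # |V| x |E|

    def loss(self, z: np.ndarray, val: bool = False) -> float:
        return _bce(self.scores(z), self.y, self.val_w if val else self.train_w)

    def grad_wrt_z(self, z: np.ndarray) -> tuple[float, np.ndarray]:
        a = self.m_agg.T @ z
        s = _sigmoid(z @ a.T)
        w = self.train_w
        loss = _bce(s, self.y, w)
        ds = w * (s - self.y) / w.sum()
        dz = ds @ a + self.m_agg @ (ds.T @ z)
        return loss, dz


@dataclass
class TrainedHgnn:
    embeddings: "EmbeddingSet"
    weights: list[np.ndarray]
    train_history: list[float] = field(default_factory=list)
    val_history: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0


def train_embeddings(
    h: Hypergraph, features: np.ndarray, config: HgnnConfig | None = None
) -> TrainedHgnn:
    """Train the two-layer network and return vertex embeddings.

    ``features`` are the stacked per-type autoencoded rows, aligned with
    ``h.vertex_ids``.  Training is full-batch Adam with dropout, L2 weight
    decay and early stopping on the held-out-column validation loss; the
    returned embeddings are the eval-mode forward pass of the best-
    validation weights.  Fixed seed => identical output.
    """
    config = config or HgnnConfig()
    x0 = np.asarray(features, dtype=float)
    if x0.shape[0] != h.n_vertices:
        raise ValueError("feature rows do not align with hypergraph vertices")
    if h.n_vertices * h.n_hyperedges > DENSE_CELL_LIMIT:
        raise ValueError(
            "incidence too large for the dense reconstruction objective; "
            "reduce the problem or train on a subsampled hypergraph"
        )
    rng = np.random.default_rng(config.seed)
    theta = build_smoothing_operator(h)
    objective = _Objective(h.incidence, config, rng)

    d_in, d_hid, d_out = x0.shape[1], config.hidden_dim, config.embed_dim
    w1 = fan_in_uniform(rng, d_in, d_hid)
    w2 = fan_in_uniform(rng, d_hid, d_out)
    opt = Adam([w1, w2], lr=config.learning_rate, beta1=config.adam_beta1,
               beta2=config.adam_beta2, weight_decay=config.weight_decay)

    tx0 = theta.apply(x0)  # constant across epochs
    p = config.dropout

    def forward_eval() -> np.ndarray:
        h1 = np.maximum(tx0 @ w1, 0.0)
        return np.maximum(theta.apply(h1) @ w2, 0.0)

    best_val = objective.loss(forward_eval(), val=True)
    val_history = [best_val]
    train_history: list[float] = []
    best_w = [w1.copy(), w2.copy()]
    best_epoch = 0
    stale = 0
    epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        p1 = tx0 @ w1
        h1 = np.maximum(p1, 0.0)
        if p > 0:
            m1 = (rng.random(h1.shape) >= p) / (1.0 - p)
            h1d = h1 * m1
        else:
            h1d = h1
        th1 = theta.apply(h1d)
        p2 = th1 @ w2
        z0 = np.maximum(p2, 0.0)
        if p > 0:
            m2 = (rng.random(z0.shape) >= p) / (1.0 - p)
            z = z0 * m2
        else:
            z = z0

        loss, dz = objective.grad_wrt_z(z)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite training loss at epoch {epoch}; "
                "check input features and learning rate"
            )
        train_history.append(loss)
        if p > 0:
            dz = dz * m2
        dp2 = dz * (p2 > 0)
        g_w2 = th1.T @ dp2
        dh1d = theta.apply(dp2 @ w2.T)  # Θ is symmetric
        if p > 0:
            dh1d = dh1d * m1
        dp1 = dh1d * (p1 > 0)
        g_w1 = tx0.T @ dp1
        opt.step([g_w1, g_w2])

        val = objective.loss(forward_eval(), val=True)
        val_history.append(val)
        if val < best_val:
            best_val = val
            best_w = [w1.copy(), w2.copy()]
            best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break

    w1[...], w2[...] = best_w[0], best_w[1]
    emb = EmbeddingSet(list(h.vertex_ids), forward_eval(), role="vertex")
    return TrainedHgnn(embeddings=emb, weights=[w1, w2],
                       train_history=train_history, val_history=val_history,
                       stopped_epoch=epoch, best_epoch=best_epoch)


def hyperedge_embeddings(vertex_emb: EmbeddingSet, h: Hypergraph) -> EmbeddingSet:
    """Hyperedge embedding = arithmetic mean of its member vertex embeddings."""
    de = np.asarray(h.incidence.sum(axis=0)).ravel()
    if (de == 0).any():
        empty = [h.hyperedge_ids[j] for j in np.nonzero(de == 0)[0]]
        raise ValueError(f"empty hyperedges cannot be embedded: {empty[:5]}")
    aligned = vertex_emb.subset(h.vertex_ids)  # raises on missing members
    m = h.incidence.astype(float).multiply(1.0 / de)  # column-normalized
    vectors = np.asarray(m.T @ aligned.vectors)
    return EmbeddingSet(list(h.hyperedge_ids), vectors, role="hyperedge")
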