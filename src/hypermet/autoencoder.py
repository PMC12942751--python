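"""Autoencoder reduction of per-type similarity rows to a shared width.

Each entity type's similarity matrix has its own width (one column per
entity of that type), so the rows cannot be stacked into one vertex
feature matrix directly.  A per-type autoencoder compresses every row to
a common ``d``-dimensional code; the encoded rows of all three types are
then stacked as the initial vertex features for message passing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optim import Adam, fan_in_uniform
from .similarity import SimilarityMatrix


@dataclass
class AutoencoderConfig:
    learning_rate: float = 0.01
    max_epochs: int = 1000
    tol: float = 1e-7          # stop when MSE improvement falls below this
    activation: str = "linear"  # "linear" or "tanh" encoder nonlinearity
    seed: int = 0


def _act(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "linear":
        return x
    if kind == "tanh":
        return np.tanh(x)
    raise ValueError(f"unknown activation {kind!r}")


def _act_grad(pre: np.ndarray, post: np.ndarray, kind: str) -> np.ndarray:
    if kind == "linear":
        return np.ones_like(pre)
    return 1.0 - post ** 2


class Autoencoder:
    """Single-hidden-layer autoencoder trained full-batch with Adam on MSE."""

    def __init__(self, n_in: int, d: int, config: AutoencoderConfig):
        if d < 1 or n_in < 1:
            raise ValueError("dimensions must be >= 1")
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.W_enc = fan_in_uniform(rng, n_in, d)
        self.b_enc = np.zeros(d)
        self.W_dec = fan_in_uniform(rng, d, n_in)
        self.b_dec = np.zeros(n_in)
        self.history: list[float] = []

    def encode(self, x: np.ndarray) -> np.ndarray:
        return _act(x @ self.W_enc + self.b_enc, self.config.activation)

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        return self.encode(x) @ self.W_dec + self.b_dec

    def fit(self, x: np.ndarray) -> "Autoencoder":
        cfg = self.config
        params = [self.W_enc, self.b_enc, self.W_dec, self.b_dec]
        opt = Adam(params, lr=cfg.learning_rate)
        prev = np.inf
        for _ in range(cfg.max_epochs):
            pre = x @ self.W_enc + self.b_enc
            code = _act(pre, cfg.activation)
            recon = code @ self.W_dec + self.b_dec
            err = recon - x
            loss = float(np.mean(err ** 2))
            self.history.append(loss)
            d_recon = 2.0 * err / err.size
            g_Wdec = code.T @ d_recon
            g_bdec = d_recon.sum(axis=0)
            d_code = d_recon @ self.W_dec.T
            d_pre = d_code * _act_grad(pre, code, cfg.activation)
            g_Wenc = x.T @ d_pre
            g_benc = d_pre.sum(axis=0)
            opt.step([g_Wenc, g_benc, g_Wdec, g_bdec])
            if abs(prev - loss) < cfg.tol:
                break
            prev = loss
        return self

    @property
    def final_loss(self) -> float:
        return self.history[-1] if self.history else float("nan")


def per_type_autoencode(
    sim: SimilarityMatrix, d: int, config: AutoencoderConfig | None = None
) -> np.ndarray:
    """Encode similarity rows to ``d`` dimensions; deterministic under seed."""
    config = config or AutoencoderConfig()
    x = np.asarray(sim.values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("similarity matrix contains non-finite values")
    ae = Autoencoder(x.shape[1], d, config).fit(x)
    return ae.encode(x)
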