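"""Parametric t-SNE: a fixed 2-D map that accepts new points.

Ordinary t-SNE re-optimizes every coordinate when a point is added, so a
map of reference samples would shift under every query.  Here a small
feed-forward network (default layer widths K, 160, 160, 640, 2; rectifier
hidden units, linear output) is trained with the t-SNE objective — KL
divergence between Gaussian input-space affinities P and Student-t (1 d.f.)
map-space affinities Q, computed per mini-batch — using the Adam optimizer.
Once trained, embedding is a pure feed-forward pass: existing coordinates
never move, and one-hot topic vectors give fixed topic anchor positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "EmbedConfig",
    "EmbeddingModel",
    "pairwise_affinities",
    "train_embedder",
    "embed_points",
    "topic_coordinates",
    "plot_map",
]

EMBED_FORMAT_VERSION = 1


@dataclass
class EmbedConfig:
    layer_sizes: list[int] | None = None  # defaults to [K, 160, 160, 640, 2]
    tsne_perplexity: float = 30.0
    epochs: int = 200
    batch_size: int = 512
    learning_rate: float = 1e-3
    seed: int = 0


@dataclass
class EmbeddingModel:
    """Feed-forward map from K-dim topic mixtures to 2-D coordinates."""

    layer_sizes: list[int]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    activation: str = "relu"
    metadata: dict = field(default_factory=dict)

    @property
    def K(self) -> int:
        return self.layer_sizes[0]

    def forward(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.K:
            raise ValueError(f"expected rows of width {self.K}, got shape {X.shape}")
        h = X
        last = len(self.weights) - 1
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ W + b
            if i < last:
                np.maximum(h, 0.0, out=h)
        return h


# ---------------------------------------------------------------------------
# affinities
# ---------------------------------------------------------------------------

def _conditional_row(d2_row: np.ndarray, target_entropy: float,
                     tol: float = 1e-5, max_iter: int = 100) -> np.ndarray:
    """Calibrate one point's Gaussian bandwidth by bisection on the
    precision so the conditional distribution hits the target entropy."""
    beta, beta_lo, beta_hi = 1.0, 0.0, np.inf
    p = np.empty_like(d2_row)
    for _ in range(max_iter):
        np.exp(-d2_row * beta, out=p)
        total = p.sum()
        if total <= 0:
            h = 0.0
        else:
            p /= total
            nz = p > 0
            h = float(-(p[nz] * np.log2(p[nz])).sum())
        diff = h - target_entropy
        if abs(diff) < tol:
            return p
        if diff > 0:  # entropy too high -> narrow the kernel
            beta_lo = beta
            beta = beta * 2.0 if not np.isfinite(beta_hi) else 0.5 * (beta_lo + beta_hi)
        else:
            beta_hi = beta
            beta = beta / 2.0 if beta_lo == 0.0 else 0.5 * (beta_lo + beta_hi)
    if abs(h - target_entropy) > 0.5:
        raise ValueError(
            "bandwidth calibration failed (duplicate-heavy or degenerate input)"
        )
    return p


def pairwise_affinities(theta_rows: np.ndarray, tsne_perplexity: float = 30.0
                        ) -> np.ndarray:
    """Symmetrized t-SNE input affinities P for a set of points.

    Per-point Gaussian bandwidths are calibrated so each conditional
    distribution has entropy log2(perplexity); the matrix is symmetrized as
    (p_{j|i} + p_{i|j}) / 2N, has a zero diagonal, and sums to one.
    """
    X = np.asarray(theta_rows, dtype=np.float64)
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 points")
    perp = min(tsne_perplexity, (n - 1) / 3.0)
    target = np.log2(perp)
    sq = (X ** 2).sum(axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * X @ X.T, 0.0)
    cond = np.zeros((n, n))
    idx = np.arange(n)
    for i in range(n):
        others = idx != i
        cond[i, others] = _conditional_row(d2[i, others], target)
    P = (cond + cond.T) / (2.0 * n)
    return P


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _init_network(layer_sizes: list[int], rng: np.random.Generator
                  ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    weights, biases = [], []
    for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        scale = np.sqrt(2.0 / fan_in)
        weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def _batch_loss_and_grad(X: np.ndarray, P: np.ndarray,
                         weights: list[np.ndarray], biases: list[np.ndarray]
                         ) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
    last = len(weights) - 1
    acts = [X]
    pres = []
    h = X
    for i, (W, b) in enumerate(zip(weights, biases)):
        pre = h @ W + b
        pres.append(pre)
        h = np.maximum(pre, 0.0) if i < last else pre
        acts.append(h)
    Y = acts[-1]
    n = Y.shape[0]
    sq = (Y ** 2).sum(axis=1)
    num = 1.0 / (1.0 + np.maximum(sq[:, None] + sq[None, :] - 2.0 * Y @ Y.T, 0.0))
    np.fill_diagonal(num, 0.0)
    Q = num / num.sum()
    mask = P > 0
    loss = float((P[mask] * np.log(P[mask] / np.maximum(Q[mask], 1e-12))).sum())
    # dKL/dY, the standard t-SNE gradient with the Student-t kernel
    PQ = (P - Q) * num
    dY = 4.0 * ((np.diag(PQ.sum(axis=1)) - PQ) @ Y)
    grads_W: list[np.ndarray] = [None] * len(weights)
    grads_b: list[np.ndarray] = [None] * len(weights)
    delta = dY
    for i in range(last, -1, -1):
        grads_W[i] = acts[i].T @ delta
        grads_b[i] = delta.sum(axis=0)
        if i > 0:
            delta = (delta @ weights[i].T) * (pres[i - 1] > 0)
    return loss, grads_W, grads_b


def train_embedder(theta: np.ndarray, config: EmbedConfig | None = None
                   ) -> EmbeddingModel:
    """Fit the parametric t-SNE network on topic mixtures.

    Mini-batches are re-drawn each epoch; affinities are computed per batch.
    Deterministic given the config seed.  Raises on a non-finite loss.
    """
    cfg = config or EmbedConfig()
    X = np.asarray(theta, dtype=np.float64)
    D, K = X.shape
    if D < 10:
        raise ValueError("need at least 10 training points")
    layer_sizes = cfg.layer_sizes or [K, 160, 160, 640, 2]
    if layer_sizes[0] != K or layer_sizes[-1] != 2:
        raise ValueError("layer sizes must run from K inputs to 2 outputs")
    rng = np.random.default_rng(cfg.seed)
    weights, biases = _init_network(layer_sizes, rng)
    mW = [np.zeros_like(w) for w in weights]
    vW = [np.zeros_like(w) for w in weights]
    mb = [np.zeros_like(b) for b in biases]
    vb = [np.zeros_like(b) for b in biases]
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0
    batch = min(cfg.batch_size, D)
    epoch_losses = []
    for _ in range(cfg.epochs):
        order = rng.permutation(D)
        losses = []
        for start in range(0, D, batch):
            idx = order[start:start + batch]
            if idx.size < 4:
                continue
            P = pairwise_affinities(X[idx], cfg.tsne_perplexity)
            loss, gW, gb = _batch_loss_and_grad(X[idx], P, weights, biases)
            if not np.isfinite(loss):
                raise FloatingPointError("embedding loss became non-finite")
            losses.append(loss)
            step += 1
            lr_t = cfg.learning_rate * np.sqrt(1 - b2 ** step) / (1 - b1 ** step)
            for i in range(len(weights)):
                mW[i] = b1 * mW[i] + (1 - b1) * gW[i]
                vW[i] = b2 * vW[i] + (1 - b2) * gW[i] ** 2
                weights[i] -= lr_t * mW[i] / (np.sqrt(vW[i]) + eps)
                mb[i] = b1 * mb[i] + (1 - b1) * gb[i]
                vb[i] = b2 * vb[i] + (1 - b2) * gb[i] ** 2
                biases[i] -= lr_t * mb[i] / (np.sqrt(vb[i]) + eps)
        epoch_losses.append(float(np.mean(losses)))
    return EmbeddingModel(
        layer_sizes=layer_sizes,
        weights=weights,
        biases=biases,
        metadata={
            "tsne_perplexity": cfg.tsne_perplexity,
            "epochs": cfg.epochs,
            "batch_size": batch,
            "learning_rate": cfg.learning_rate,
            "seed": cfg.seed,
            "epoch_losses": epoch_losses,
        },
    )


def embed_points(model: EmbeddingModel, rows: np.ndarray) -> np.ndarray:
    """Map topic mixtures to 2-D coordinates (pure function; adding points
    never moves existing ones)."""
    return model.forward(np.atleast_2d(rows))


def topic_coordinates(model: EmbeddingModel) -> np.ndarray:
    """Anchor positions of the K topics: the images of one-hot mixtures."""
    return model.forward(np.eye(model.K))


def plot_map(coords: np.ndarray, anchors: np.ndarray | None = None,
             path: str | Path | None = None, labels=None):
    """Static scatter plot of a 2-D map, optionally with topic anchors."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(coords[:, 0], coords[:, 1], s=8, c="#777777",
               label="samples" if anchors is not None else None)
    if labels is not None:
        sc = ax.scatter(coords[:, 0], coords[:, 1], s=8, c=labels, cmap="tab10")
        fig.colorbar(sc, ax=ax, shrink=0.8)
    if anchors is not None:
        ax.scatter(anchors[:, 0], anchors[:, 1], s=60, marker="*",
                   c="crimson", label="topic anchors")
        for k, (x, y) in enumerate(anchors):
            ax.annotate(str(k), (x, y), fontsize=8)
        ax.legend(loc="best", fontsize=8)
    ax.set_xlabel("map x")
    ax.set_ylabel("map y")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


# ---------------------------------------------------------------------------
# archive
# ---------------------------------------------------------------------------

def save_embedder(model: EmbeddingModel, path: str | Path) -> None:
    payload = {
        "format": "ecotopics-embedder",
        "version": EMBED_FORMAT_VERSION,
        "layer_sizes": model.layer_sizes,
        "weights": [w.tolist() for w in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "activation": model.activation,
        "metadata": model.metadata,
    }
    Path(path).write_text(json.dumps(payload))


def load_embedder(path: str | Path) -> EmbeddingModel:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: corrupt or truncated embedder archive") from exc
    if payload.get("format") != "ecotopics-embedder":
        raise ValueError(f"{path}: not an embedder archive")
    if payload.get("version") != EMBED_FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported archive version")
    return EmbeddingModel(
        layer_sizes=list(payload["layer_sizes"]),
        weights=[np.array(w) for w in payload["weights"]],
        biases=[np.array(b) for b in payload["biases"]],
        activation=payload.get("activation", "relu"),
        metadata=payload.get("metadata", {}),
    )
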