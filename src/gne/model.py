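"""The GNE embedding model.

A shallow neural encoder learns one d-dimensional vector per gene by fusing
two information sources early, before a shared multilayer perceptron:

* a trainable embedding-lookup table for the gene's identity (topology),
* a non-linear transform (ELU) of the gene's expression profile.

The two d-vectors are concatenated, with the attribute half scaled by the
importance weight ``lam``, and passed through ``k`` hidden layers (Tanh by
default) to produce a node representation h_i. A second table ``W_out``
holds each gene's representation as a *neighbor*, v~_j. The model is trained
so that the inner product v~_j . h_i is large for interacting gene pairs,
using the skip-gram objective with negative sampling: each observed edge is
contrasted against a few genes drawn from a degree^0.75 noise distribution
outside the neighborhood of i. The final embedding of gene i is
y_i = h_i + v~_i.

Everything is plain numpy with hand-derived gradients and a minimal Adam
optimizer; at the network sizes this package targets (10^2 - 10^4 genes)
dense batched linear algebra is fast and keeps runs bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit

from .graph_io import GeneNetwork, ExpressionMatrix, Pair

__all__ = [
    "GNEHyper",
    "GNEParams",
    "GeneEmbeddings",
    "NoiseSampler",
    "init_params",
    "lookup_structure",
    "transform_attributes",
    "fuse",
    "hidden_forward",
    "score_pair",
    "conditional_prob",
    "sample_noise_genes",
    "sgns_loss",
    "loss_and_grads",
    "train",
    "final_embeddings",
]


# ---------------------------------------------------------------------------
# Activations

def _elu(z: np.ndarray) -> np.ndarray:
    return np.where(z > 0, z, np.expm1(np.minimum(z, 0.0)))


def _elu_grad(z: np.ndarray) -> np.ndarray:
    return np.where(z > 0, 1.0, np.exp(np.minimum(z, 0.0)))


def _tanh(z: np.ndarray) -> np.ndarray:
    return np.tanh(z)


def _tanh_grad(z: np.ndarray) -> np.ndarray:
    t = np.tanh(z)
    return 1.0 - t * t


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def _relu_grad(z: np.ndarray) -> np.ndarray:
    return (z > 0).astype(float)


def _identity(z: np.ndarray) -> np.ndarray:
    return z


def _one(z: np.ndarray) -> np.ndarray:
    return np.ones_like(z)


_ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "elu": (_elu, _elu_grad),
    "tanh": (_tanh, _tanh_grad),
    "relu": (_relu, _relu_grad),
    "identity": (_identity, _one),
}


def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    """log sigma(x), computed in log-space (no overflow for large |x|)."""
    return -np.logaddexp(0.0, -x)


# ---------------------------------------------------------------------------
# Hyperparameters and parameters


@dataclass
class GNEHyper:
    """Model and training hyperparameters.

    Defaults are the grid optimum reported for the yeast interaction network
    (learning rate 0.005, batch 256, d=128, 20 epochs, 10 negative samples,
    one Tanh hidden layer over an ELU attribute transform). ``lam`` weighs
    expression relative to topology: 0 is topology-only, 1 full weight.
    """

    d: int = 128
    lam: float = 1.0
    k: int = 1
    attr_activation: str = "elu"
    hidden_activation: str = "tanh"
    learning_rate: float = 0.005
    batch_size: int = 256
    epochs: int = 20
    num_neg: int = 10
    dropout: float = 0.0
    batch_norm: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.num_neg < 1:
            raise ValueError("num_neg must be >= 1")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        for name in (self.attr_activation, self.hidden_activation):
            if name not in _ACTIVATIONS:
                raise ValueError(f"unknown activation {name!r}")


@dataclass
class HiddenLayer:
    W: np.ndarray  # (out, in)
    b: np.ndarray  # (out,)
    # batch-norm parameters (present only when enabled)
    gamma: np.ndarray | None = None
    beta: np.ndarray | None = None
    running_mean: np.ndarray | None = None
    running_var: np.ndarray | None = None


@dataclass
class GNEParams:
    """All trainable tensors of the model.

    ``W_id`` (d x M) holds the structure embedding per gene as a column;
    ``W_att`` (d x E) transforms expression profiles; ``hidden`` are the
    shared MLP layers (first maps 2d -> d, the rest d -> d); ``W_out``
    (M x d) holds each gene's neighbor representation v~_j as a row.
    """

    W_id: np.ndarray
    W_att: np.ndarray
    hidden: list[HiddenLayer]
    W_out: np.ndarray

    @property
    def d(self) -> int:
        return self.W_id.shape[0]

    @property
    def M(self) -> int:
        return self.W_id.shape[1]

    @property
    def E(self) -> int:
        return self.W_att.shape[1]

    def trainable(self) -> list[tuple[str, np.ndarray]]:
        """Named references to every trainable array (excludes running stats)."""
        out = [("W_id", self.W_id), ("W_att", self.W_att)]
        for l, layer in enumerate(self.hidden):
            out.append((f"hidden{l}.W", layer.W))
            out.append((f"hidden{l}.b", layer.b))
            if layer.gamma is not None:
                out.append((f"hidden{l}.gamma", layer.gamma))
                out.append((f"hidden{l}.beta", layer.beta))
        out.append(("W_out", self.W_out))
        return out


@dataclass
class GeneEmbeddings:
    """Final per-gene representations, row i = h_i + v~_i."""

    genes: list[str]
    Y: np.ndarray

    @property
    def d(self) -> int:
        return self.Y.shape[1]


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


def init_params(hyper: GNEHyper, M: int, E: int, seed: int | None = None) -> GNEParams:
    """Scaled-uniform (Glorot) initialization; biases zero; deterministic."""
    if M < 2:
        raise ValueError("need at least 2 genes")
    if E < 0:
        raise ValueError("E must be >= 0")
    rng = np.random.default_rng(hyper.seed if seed is None else seed)
    d = hyper.d
    W_id = _glorot(rng, (d, M))
    W_att = _glorot(rng, (d, E)) if E > 0 else np.zeros((d, 0))
    hidden: list[HiddenLayer] = []
    in_dim = 2 * d
    for _ in range(hyper.k):
        layer = HiddenLayer(W=_glorot(rng, (d, in_dim)), b=np.zeros(d))
        if hyper.batch_norm:
            layer.gamma = np.ones(d)
            layer.beta = np.zeros(d)
            layer.running_mean = np.zeros(d)
            layer.running_var = np.ones(d)
        hidden.append(layer)
        in_dim = d
    W_out = _glorot(rng, (M, d))
    return GNEParams(W_id=W_id, W_att=W_att, hidden=hidden, W_out=W_out)


def zero_grads(params: GNEParams) -> GNEParams:
    """A GNEParams-shaped container of zero arrays, used as gradient storage."""
    hidden = []
    for layer in params.hidden:
        hidden.append(
            HiddenLayer(
                W=np.zeros_like(layer.W),
                b=np.zeros_like(layer.b),
                gamma=None if layer.gamma is None else np.zeros_like(layer.gamma),
                beta=None if layer.beta is None else np.zeros_like(layer.beta),
            )
        )
    return GNEParams(
        W_id=np.zeros_like(params.W_id),
        W_att=np.zeros_like(params.W_att),
        hidden=hidden,
        W_out=np.zeros_like(params.W_out),
    )


# ---------------------------------------------------------------------------
# Forward pieces (spec-level single-vector operations)


def lookup_structure(params: GNEParams, i: int) -> np.ndarray:
    """Structure embedding of gene i: column i of W_id (W_id . one_hot(i))."""
    if not 0 <= i < params.M:
        raise IndexError(f"gene index {i} out of range for M={params.M}")
    return params.W_id[:, i].copy()


def transform_attributes(
    params: GNEParams, x: np.ndarray, activation: str = "elu"
) -> np.ndarray:
    """Attribute embedding: elementwise activation of W_att . x."""
    x = np.asarray(x, dtype=float)
    if x.shape != (params.E,):
        raise ValueError(f"expected expression vector of length {params.E}, got {x.shape}")
    act, _ = _ACTIVATIONS[activation]
    return act(params.W_att @ x)


def fuse(v_s: np.ndarray, v_a: np.ndarray, lam: float) -> np.ndarray:
    """Early fusion: concatenate [v_s ; lam * v_a]."""
    v_s = np.asarray(v_s, dtype=float)
    v_a = np.asarray(v_a, dtype=float)
    if v_s.shape != v_a.shape:
        raise ValueError("structure and attribute embeddings must have equal length")
    return np.concatenate([v_s, lam * v_a])


def score_pair(h_i: np.ndarray, v_tilde_j: np.ndarray) -> float:
    """Proximity score f(v_i, v_j) = v~_j . h_i."""
    h_i = np.asarray(h_i, dtype=float)
    v_tilde_j = np.asarray(v_tilde_j, dtype=float)
    if h_i.shape != v_tilde_j.shape:
        raise ValueError("vectors must have equal length")
    return float(h_i @ v_tilde_j)


# ---------------------------------------------------------------------------
# Batched encoder (forward + backward)


class _EncodeCache:
    __slots__ = ("idx", "z_a", "v_a", "fused", "layers")

    def __init__(self):
        self.layers: list[dict] = []


def _encode(
    params: GNEParams,
    hyper: GNEHyper,
    X: np.ndarray,
    idx: np.ndarray,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, _EncodeCache]:
    """Encode genes ``idx`` to their hidden representations h (batch x d)."""
    attr_act, _ = _ACTIVATIONS[hyper.attr_activation]
    hid_act, _ = _ACTIVATIONS[hyper.hidden_activation]
    cache = _EncodeCache()
    cache.idx = idx
    v_s = params.W_id[:, idx].T
    z_a = X[idx] @ params.W_att.T
    v_a = attr_act(z_a)
    cache.z_a = z_a
    cache.v_a = v_a
    h = np.concatenate([v_s, hyper.lam * v_a], axis=1)
    cache.fused = h
    B = h.shape[0]
    eps = 1e-5
    for layer in params.hidden:
        entry: dict = {"input": h}
        a = h @ layer.W.T + layer.b
        entry["a"] = a
        if layer.gamma is not None:
            if train_mode and B > 1:
                mu = a.mean(axis=0)
                var = a.var(axis=0)
                layer.running_mean = 0.9 * layer.running_mean + 0.1 * mu
                layer.running_var = 0.9 * layer.running_var + 0.1 * var
            else:
                mu = layer.running_mean
                var = layer.running_var
            inv_std = 1.0 / np.sqrt(var + eps)
            xhat = (a - mu) * inv_std
            z = layer.gamma * xhat + layer.beta
            entry["bn"] = (xhat, inv_std, train_mode and B > 1)
        else:
            z = a
        entry["z"] = z
        h = hid_act(z)
        if train_mode and hyper.dropout > 0:
            if rng is None:
                raise ValueError("dropout in train mode requires an rng")
            keep = 1.0 - hyper.dropout
            mask = (rng.random(h.shape) < keep) / keep
            entry["mask"] = mask
            h = h * mask
        cache.layers.append(entry)
    return h, cache


def _encode_backward(
    grad_h: np.ndarray,
    params: GNEParams,
    hyper: GNEHyper,
    X: np.ndarray,
    cache: _EncodeCache,
    grads: GNEParams,
) -> None:
    """Accumulate gradients of a scalar loss w.r.t. all encoder parameters."""
    _, attr_grad = _ACTIVATIONS[hyper.attr_activation]
    _, hid_grad = _ACTIVATIONS[hyper.hidden_activation]
    g = grad_h
    for layer, glayer, entry in zip(
        reversed(params.hidden), reversed(grads.hidden), reversed(cache.layers)
    ):
        if "mask" in entry:
            g = g * entry["mask"]
        gz = g * hid_grad(entry["z"])
        if layer.gamma is not None:
            xhat, inv_std, used_batch_stats = entry["bn"]
            glayer.gamma += (gz * xhat).sum(axis=0)
            glayer.beta += gz.sum(axis=0)
            gxhat = gz * layer.gamma
            if used_batch_stats:
                B = gz.shape[0]
                ga = (inv_std / B) * (
                    B * gxhat
                    - gxhat.sum(axis=0)
                    - xhat * (gxhat * xhat).sum(axis=0)
                )
            else:
                ga = gxhat * inv_std
        else:
            ga = gz
        glayer.W += ga.T @ entry["input"]
        glayer.b += ga.sum(axis=0)
        g = ga @ layer.W
    d = params.d
    g_vs = g[:, :d]
    g_va = g[:, d:] * hyper.lam
    np.add.at(grads.W_id.T, cache.idx, g_vs)
    gz_a = g_va * attr_grad(cache.z_a)
    grads.W_att += gz_a.T @ X[cache.idx]


def hidden_forward(
    params: GNEParams,
    hyper: GNEHyper,
    fused: np.ndarray,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Run the shared MLP on one fused 2d-vector; returns the d-vector h."""
    fused = np.asarray(fused, dtype=float)
    if fused.shape != (2 * params.d,):
        raise ValueError(f"expected fused vector of length {2 * params.d}")
    hid_act, _ = _ACTIVATIONS[hyper.hidden_activation]
    h = fused[None, :]
    eps = 1e-5
    for layer in params.hidden:
        a = h @ layer.W.T + layer.b
        if layer.gamma is not None:
            a = layer.gamma * (a - layer.running_mean) / np.sqrt(layer.running_var + eps) + layer.beta
        h = hid_act(a)
        if train_mode and hyper.dropout > 0:
            if rng is None:
                raise ValueError("dropout in train mode requires an rng")
            keep = 1.0 - hyper.dropout
            h = h * ((rng.random(h.shape) < keep) / keep)
    return h[0]


def conditional_prob(
    params: GNEParams, hyper: GNEHyper, X: np.ndarray, i: int
) -> np.ndarray:
    """Softmax distribution p(. | v_i) over all M genes, max-stabilized."""
    if not 0 <= i < params.M:
        raise IndexError(f"gene index {i} out of range")
    h, _ = _encode(params, hyper, X, np.array([i]), train_mode=False)
    scores = params.W_out @ h[0]
    if not np.all(np.isfinite(scores)):
        raise FloatingPointError("non-finite proximity score")
    scores = scores - scores.max()
    e = np.exp(scores)
    return e / e.sum()


# ---------------------------------------------------------------------------
# Negative sampling


class NoiseSampler:
    """Noise distribution over genes: unigram weighted by degree^0.75.

    Samples for source gene i are drawn from the distribution restricted to
    genes outside N_i and distinct from i (renormalized over the eligible
    set, equivalent to rejection sampling). Errors if no eligible gene
    carries probability mass.
    """

    def __init__(self, net: GeneNetwork, power: float = 0.75):
        deg = net.degrees().astype(float)
        w = deg**power
        if w.sum() == 0:
            w = np.ones_like(w)  # empty network: uniform noise
        self.probs = w / w.sum()
        self.forbidden = net.adjacency()
        np.fill_diagonal(self.forbidden, True)
        self.M = net.M

    def sample(
        self, sources: np.ndarray, num_neg: int, rng: np.random.Generator
    ) -> np.ndarray:
        """Draw (len(sources) x num_neg) noise gene indices."""
        sources = np.asarray(sources)
        w = np.where(self.forbidden[sources], 0.0, self.probs[None, :])
        mass = w.sum(axis=1)
        if np.any(mass == 0):
            bad = int(sources[np.argmax(mass == 0)])
            raise ValueError(
                f"no eligible noise gene for source {bad}: every gene with "
                "probability mass lies in its neighborhood"
            )
        cdf = np.cumsum(w, axis=1)
        u = rng.random((len(sources), num_neg)) * mass[:, None]
        # vectorized inverse-CDF lookup per row
        neg = np.empty((len(sources), num_neg), dtype=np.int64)
        for r in range(len(sources)):
            neg[r] = np.searchsorted(cdf[r], u[r], side="right")
        return np.minimum(neg, self.M - 1)


def sample_noise_genes(
    net: GeneNetwork,
    i: int,
    num_neg: int,
    rng: np.random.Generator | int | None = None,
) -> list[int]:
    """Draw ``num_neg`` noise genes for source gene ``i`` (see NoiseSampler)."""
    if num_neg < 1:
        raise ValueError("num_neg must be >= 1")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    sampler = NoiseSampler(net)
    return sampler.sample(np.array([i]), num_neg, rng)[0].tolist()


# ---------------------------------------------------------------------------
# Loss and training


def loss_and_grads(
    params: GNEParams,
    hyper: GNEHyper,
    X: np.ndarray,
    pos_i: np.ndarray,
    pos_j: np.ndarray,
    neg: np.ndarray,
    train_mode: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[float, GNEParams]:
    """Negative-sampling skip-gram loss and gradients for given noise draws.

    loss = -(1/B) sum_b [ log sigma(v~_{j_b} . h_{i_b})
                          + sum_n log sigma(-v~_{n} . h_{i_b}) ]

    ``neg`` has shape (B, num_neg). Deterministic given its arguments (rng is
    consumed only for dropout masks). Gradients are returned in a
    GNEParams-shaped container.
    """
    pos_i = np.asarray(pos_i, dtype=np.int64)
    pos_j = np.asarray(pos_j, dtype=np.int64)
    neg = np.asarray(neg, dtype=np.int64)
    B = len(pos_i)
    if B == 0:
        raise ValueError("empty batch")
    h, cache = _encode(params, hyper, X, pos_i, train_mode=train_mode, rng=rng)
    s_pos = np.einsum("bd,bd->b", h, params.W_out[pos_j])
    W_neg = params.W_out[neg]  # (B, K, d)
    s_neg = np.einsum("bkd,bd->bk", W_neg, h)
    loss = float(np.mean(-_log_sigmoid(s_pos) - _log_sigmoid(-s_neg).sum(axis=1)))
    grads = zero_grads(params)
    g_pos = -expit(-s_pos) / B  # dL/ds_pos
    g_neg = expit(s_neg) / B  # dL/ds_neg
    np.add.at(grads.W_out, pos_j, g_pos[:, None] * h)
    np.add.at(
        grads.W_out,
        neg.reshape(-1),
        (g_neg[:, :, None] * h[:, None, :]).reshape(-1, params.d),
    )
    grad_h = g_pos[:, None] * params.W_out[pos_j] + np.einsum(
        "bk,bkd->bd", g_neg, W_neg
    )
    _encode_backward(grad_h, params, hyper, X, cache, grads)
    return loss, grads


def sgns_loss(
    params: GNEParams,
    batch: Sequence[Pair],
    hyper: GNEHyper,
    X: np.ndarray,
    sampler: NoiseSampler,
    rng: np.random.Generator,
    train_mode: bool = True,
) -> tuple[float, GNEParams]:
    """Sample noise genes for a batch of directed positive pairs, then
    compute the negative-sampling loss and its gradients."""
    if len(batch) == 0:
        raise ValueError("empty batch")
    pos_i = np.array([p[0] for p in batch], dtype=np.int64)
    pos_j = np.array([p[1] for p in batch], dtype=np.int64)
    neg = sampler.sample(pos_i, hyper.num_neg, rng)
    return loss_and_grads(
        params, hyper, X, pos_i, pos_j, neg, train_mode=train_mode, rng=rng
    )


class Adam:
    """Adam with the cited defaults beta1=0.9, beta2=0.999, eps=1e-8."""

    def __init__(self, params: GNEParams, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {name: np.zeros_like(a) for name, a in params.trainable()}
        self.v = {name: np.zeros_like(a) for name, a in params.trainable()}

    def step(self, params: GNEParams, grads: GNEParams) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        gmap = dict(grads.trainable())
        for name, arr in params.trainable():
            g = gmap[name]
            m = self.m[name]
            v = self.v[name]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            arr -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def train(
    net: GeneNetwork,
    expr: ExpressionMatrix,
    hyper: GNEHyper,
    train_pos: Sequence[Pair],
) -> tuple[GNEParams, list[float]]:
    """Fit the model on the given positive edges; return params and per-epoch
    mean loss.

    Each undirected edge contributes both directed instances (i->j and j->i);
    one epoch is a seed-shuffled pass over all directed instances in
    mini-batches, each step drawing fresh noise genes and applying one Adam
    update. Fully deterministic given ``hyper.seed``.
    """
    if len(train_pos) == 0:
        raise ValueError("train_pos must be nonempty")
    if list(net.genes) != list(expr.genes):
        raise ValueError("network and expression matrix are not aligned (run align())")
    X = expr.values
    params = init_params(hyper, net.M, expr.E, seed=hyper.seed)
    sampler = NoiseSampler(net)
    rng = np.random.default_rng(np.random.SeedSequence(hyper.seed).spawn(1)[0])
    src = np.array([[i, j] for i, j in train_pos] + [[j, i] for i, j in train_pos])
    n = len(src)
    history: list[float] = []
    optimizer = Adam(params, lr=hyper.learning_rate)
    for epoch in range(hyper.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, hyper.batch_size):
            batch = src[order[start:start + hyper.batch_size]]
            pos_i, pos_j = batch[:, 0], batch[:, 1]
            neg = sampler.sample(pos_i, hyper.num_neg, rng)
            loss, grads = loss_and_grads(
                params, hyper, X, pos_i, pos_j, neg, train_mode=True, rng=rng
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {start // hyper.batch_size}; "
                    "try a smaller learning rate"
                )
            optimizer.step(params, grads)
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return params, history


def final_embeddings(
    params: GNEParams,
    net: GeneNetwork,
    expr: ExpressionMatrix,
    hyper: GNEHyper,
) -> GeneEmbeddings:
    """Final representation y_i = h_i + v~_i (eval-mode forward pass)."""
    H, _ = _encode(params, hyper, expr.values, np.arange(net.M), train_mode=False)
    return GeneEmbeddings(genes=list(net.genes), Y=H + params.W_out)
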