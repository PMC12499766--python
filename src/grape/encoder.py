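"""Graph-regularized attention encoder.

Each layer of the graph-normalized convolutional network (GNCN) first
transforms node features with a learnable weight matrix, rescales every
transformed row to a common norm ``s`` (the graph-regularization step that
keeps feature magnitudes from collapsing or exploding during repeated
neighborhood averaging — the over-smoothing failure mode of sparse
interaction graphs), then propagates with the symmetrically degree-normalized
adjacency including a self term:

    z_i = n_i / (d_i + 1) + Σ_{j∈N(i)} n_j / (√(d_i+1) √(d_j+1)),

equivalently  s · D̂^{-1/2} Â D̂^{-1/2} g(XW)  with  Â = A + I.

A single global attention block (scaled dot-product, softmax over all nodes,
residual + layer normalization) follows the GNCN stack so any node can
attend to any other regardless of graph distance.  Pairs are scored by an
MLP head on the concatenated TCR and epitope embeddings.

Numpy reference implementations of each operation are exposed for direct
use and for testing; the ``*_t`` functions build the same computation on
autodiff tensors for training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from ._autograd import Tensor, concat, fixed_matmul

__all__ = [
    "EncoderConfig", "feature_transform", "normalize_scale",
    "gncn_propagate", "gncn_matrix_form", "propagation_matrix",
    "global_attention", "init_params", "encode_graph", "score_pairs",
    "count_trainable_parameters",
]

# softplus inverse of 1.0: initial raw value giving scale s = 1
_SOFTPLUS_INV_1 = math.log(math.expm1(1.0))


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture hyperparameters.

    ``input_dim`` must match the embedding provider width (320 for both the
    8M-tier protein language model and the default hashed k-mer provider).
    The attention-free default configuration stays under 200 000 trainable
    parameters.
    """

    input_dim: int = 320
    hidden_dim: int = 128
    n_gncn_layers: int = 2
    attention: bool = True
    attention_dim: int = 128
    head_dims: tuple = (160, 64, 1)
    pair_product: bool = True        # include z_t ⊙ z_e in the head input
    interaction_shortcut: bool = True  # linear term on raw x_t ⊙ x_e
    graph_norm: bool = True          # ablation: identity instead of g(.)
    learn_scale: bool = True
    epsilon: float = 1e-12
    dropout: float = 0.5             # on the pair-head activations, train only
    seed: int = 0

    def __post_init__(self):
        if self.hidden_dim <= 0 or self.input_dim <= 0:
            raise ValueError("widths must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.head_dims[-1] != 1:
            raise ValueError("head must end in a single logit")


# ---------------------------------------------------------------------------
# numpy reference operations
# ---------------------------------------------------------------------------

def feature_transform(X, W) -> np.ndarray:
    """Linear feature transform H = X W."""
    X, W = np.asarray(X), np.asarray(W)
    if X.shape[1] != W.shape[0]:
        raise ValueError(f"shape mismatch: {X.shape} @ {W.shape}")
    return X @ W


def normalize_scale(H, s: float, epsilon: float = 1e-12) -> np.ndarray:
    """Rescale every row to norm ``s`` (zero rows stay zero)."""
    if s <= 0:
        raise ValueError("s must be positive")
    H = np.asarray(H, dtype=np.float64)
    norms = np.linalg.norm(H, axis=-1, keepdims=True)
    return s * H / np.maximum(norms, epsilon)


def gncn_propagate(N, A) -> np.ndarray:
    """Message-form propagation with self term (per-node sum over N(i))."""
    N = np.asarray(N, dtype=np.float64)
    if sp.issparse(A):
        A = A.toarray()
    A = np.asarray(A, dtype=np.float64)
    if A.shape[0] != A.shape[1] or A.shape[0] != N.shape[0]:
        raise ValueError("shape mismatch between N and A")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    d = A.sum(axis=1)
    inv = 1.0 / np.sqrt(d + 1.0)
    self_term = N / (d + 1.0)[:, None]
    neighbor_term = inv[:, None] * (A @ (N * inv[:, None]))
    return self_term + neighbor_term


def propagation_matrix(A) -> sp.csr_matrix:
    """P = D̂^{-1/2} Â D̂^{-1/2} with Â = A + I (self-loop interpretation)."""
    if not sp.issparse(A):
        A = sp.csr_matrix(np.asarray(A, dtype=np.float64))
    n = A.shape[0]
    a_hat = A + sp.identity(n, format="csr")
    d_hat = np.asarray(a_hat.sum(axis=1)).ravel()
    inv_sqrt = sp.diags(1.0 / np.sqrt(d_hat))
    return (inv_sqrt @ a_hat @ inv_sqrt).tocsr()


def gncn_matrix_form(N, A) -> np.ndarray:
    """Matrix-form propagation P N; agrees with the message form."""
    return propagation_matrix(A) @ np.asarray(N, dtype=np.float64)


def global_attention(H, W_Q, W_K, W_V, return_weights: bool = False):
    """Scaled dot-product attention over all nodes.

    Returns Softmax(Q Kᵀ / √h) V; the attention matrix has rows summing
    to one.
    """
    H = np.asarray(H, dtype=np.float64)
    Q, K, V = H @ W_Q, H @ W_K, H @ W_V
    h = Q.shape[1]
    logits = Q @ K.T / math.sqrt(h)
    logits -= logits.max(axis=1, keepdims=True)
    weights = np.exp(logits)
    weights /= weights.sum(axis=1, keepdims=True)
    out = weights @ V
    return (out, weights) if return_weights else out


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

def _glorot(rng, fan_in, fan_out):
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_params(config: EncoderConfig, rng=None) -> dict:
    """Initialize all trainable parameters as autodiff tensors."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    m, f = config.input_dim, config.hidden_dim
    p: dict[str, Tensor] = {}
    # identical initialization for the two type channels: the product block
    # of the pair head then starts as a sketch of the raw inner product
    # (independent random projections would decorrelate it); the channels
    # diverge freely during training.
    proj0 = _glorot(rng, m, f)
    for tag in ("tcr", "epi"):
        p[f"proj_{tag}_W"] = Tensor(proj0.copy(), requires_grad=True)
        p[f"proj_{tag}_b"] = Tensor(np.zeros(f), requires_grad=True)
    for layer in range(config.n_gncn_layers):
        p[f"gncn{layer}_W"] = Tensor(_glorot(rng, f, f), requires_grad=True)
        if config.learn_scale:
            p[f"gncn{layer}_s"] = Tensor(
                np.array(_SOFTPLUS_INV_1), requires_grad=True
            )
    if config.attention:
        h = config.attention_dim
        for tag in ("Q", "K", "V"):
            p[f"attn_W{tag}"] = Tensor(_glorot(rng, f, h), requires_grad=True)
        p["ln_gamma"] = Tensor(np.ones(f), requires_grad=True)
        p["ln_beta"] = Tensor(np.zeros(f), requires_grad=True)
    pair_dim = (3 if config.pair_product else 2) * f
    widths = (pair_dim,) + tuple(config.head_dims)
    for layer, (w_in, w_out) in enumerate(zip(widths[:-1], widths[1:])):
        p[f"head{layer}_W"] = Tensor(_glorot(rng, w_in, w_out), requires_grad=True)
        p[f"head{layer}_b"] = Tensor(np.zeros(w_out), requires_grad=True)
    if config.interaction_shortcut:
        p["shortcut_w"] = Tensor(np.zeros(m), requires_grad=True)
    return p


def count_trainable_parameters(config: EncoderConfig) -> int:
    """Exact count of scalar trainable parameters for a configuration."""
    params = init_params(config, np.random.default_rng(0))
    return int(sum(p.data.size for p in params.values()))


# ---------------------------------------------------------------------------
# tensor forward pass
# ---------------------------------------------------------------------------

def _scale_value(params: dict, layer: int, config: EncoderConfig) -> Tensor:
    if config.learn_scale:
        return params[f"gncn{layer}_s"].softplus()
    return Tensor(np.array(1.0))


def _layer_norm(x: Tensor, gamma: Tensor, beta: Tensor,
                eps: float = 1e-6) -> Tensor:
    mu = x.mean(axis=1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=1, keepdims=True)
    return centered / (var + eps).sqrt() * gamma + beta


def encode_graph(graph, config: EncoderConfig, params: dict) -> Tensor:
    """Full encoder forward pass over the graph: returns Z_final (n×f).

    Pipeline: per-type input projection (separate channels for TCR and
    epitope nodes) → stacked GNCN layers with ReLU between layers → one
    global attention block with residual connection and layer
    normalization (skipped when ``config.attention`` is False).  Dropout
    regularization lives in the pair scorer, not here, so encoding is
    deterministic given parameters.
    """
    if not params:
        raise ValueError("uninitialized parameters")
    n_tcr = graph.n_tcr
    x_tcr = Tensor(graph.X[:n_tcr])
    x_epi = Tensor(graph.X[n_tcr:])
    h_tcr = x_tcr @ params["proj_tcr_W"] + params["proj_tcr_b"]
    h_epi = x_epi @ params["proj_epi_W"] + params["proj_epi_b"]
    H = concat([h_tcr, h_epi], axis=0).relu()

    P = propagation_matrix(graph.adjacency())
    for layer in range(config.n_gncn_layers):
        H = H @ params[f"gncn{layer}_W"]
        if config.graph_norm:
            norms = (H * H).sum(axis=1, keepdims=True).sqrt()
            H = H / norms.clip_min(config.epsilon) * _scale_value(
                params, layer, config
            )
        H = fixed_matmul(P, H)
        if layer < config.n_gncn_layers - 1:
            H = H.relu()

    if config.attention:
        Q = H @ params["attn_WQ"]
        K = H @ params["attn_WK"]
        V = H @ params["attn_WV"]
        logits = (Q @ K.T) * (1.0 / math.sqrt(config.attention_dim))
        attn = logits.softmax(axis=-1)
        H = _layer_norm(H + attn @ V, params["ln_gamma"], params["ln_beta"])
    return H


def _dropout(h: Tensor, rate: float, rng) -> Tensor:
    keep = (rng.random(h.data.shape) >= rate) / (1.0 - rate)
    return h * keep


def score_pairs(Z: Tensor, tcr_idx, epi_idx, params: dict,
                config: EncoderConfig, X=None, dropout_rng=None) -> Tensor:
    """Pair scorer; returns raw logits.

    Deep path: MLP on the concatenated pair representation
    (z_tcr ‖ z_epitope, optionally also z_tcr ⊙ z_epitope).  Wide path
    (``interaction_shortcut``): a linear term on the elementwise product of
    the raw input embeddings x_tcr ⊙ x_epitope — hashed k-mer and language
    model features carry pair evidence in co-activated dimensions that a
    dense projection cannot keep separated, so the scorer retains a direct
    linear view of them.  ``X`` (raw node features) is required for the
    shortcut.
    """
    t_idx = np.asarray(tcr_idx, dtype=np.intp)
    e_idx = np.asarray(epi_idx, dtype=np.intp)
    z_t, z_e = Z.gather(t_idx), Z.gather(e_idx)
    parts = [z_t, z_e]
    if config.pair_product:
        parts.append(z_t * z_e)
    h = concat(parts, axis=1)
    train_mode = dropout_rng is not None and config.dropout > 0
    if train_mode:
        h = _dropout(h, config.dropout, dropout_rng)
    n_layers = len(config.head_dims)
    for layer in range(n_layers):
        h = h @ params[f"head{layer}_W"] + params[f"head{layer}_b"]
        if layer < n_layers - 1:
            h = h.relu()
            if train_mode:
                h = _dropout(h, config.dropout, dropout_rng)
    logits = h.reshape(-1)
    if config.interaction_shortcut:
        if X is None:
            raise ValueError("interaction shortcut requires raw features X")
        logits = logits + Tensor(X[t_idx] * X[e_idx]) @ params["shortcut_w"]
    return logits


def score_pairs_numpy(Z: np.ndarray, tcr_idx, epi_idx, params: dict,
                      config: EncoderConfig, X=None) -> np.ndarray:
    """Inference-time scorer on plain arrays (no tape)."""
    t_idx = np.asarray(tcr_idx, dtype=np.intp)
    e_idx = np.asarray(epi_idx, dtype=np.intp)
    parts = [Z[t_idx], Z[e_idx]]
    if config.pair_product:
        parts.append(Z[t_idx] * Z[e_idx])
    z = np.concatenate(parts, axis=1)
    n_layers = len(config.head_dims)
    for layer in range(n_layers):
        z = z @ params[f"head{layer}_W"].data + params[f"head{layer}_b"].data
        if layer < n_layers - 1:
            z = np.maximum(z, 0.0)
    logits = z.reshape(-1)
    if config.interaction_shortcut:
        if X is None:
            raise ValueError("interaction shortcut requires raw features X")
        logits = logits + (X[t_idx] * X[e_idx]) @ params["shortcut_w"].data
    return logits
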