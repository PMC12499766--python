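"""AUC-maximization machinery.

The empirical AUC is the probability that a random positive outscores a
random negative.  Direct optimization of the pairwise squared surrogate

    L_pair = E[(1 − (f(x) − f(x')))² | y = 1, y' = −1]

requires positive–negative pairs in every batch; the equivalent stochastic
saddle-point form decomposes it into per-sample terms with three auxiliary
scalars — a and b track the class score means and α (the max variable)
their gap:

    F(f, y; a, b, α) = (1−p)(f−a)² 1[y=1] + p(f−b)² 1[y=−1]
                       + 2(1+α)(p f 1[y=−1] − (1−p) f 1[y=1]) − p(1−p)α².

With p the positive-class prior, minimizing the mean of F over (model, a, b)
while maximizing over α reproduces the pairwise objective up to an additive
constant: min_{a,b} max_α mean F = p(1−p)(L_pair − 1), attained at
a* = mean(f | +), b* = mean(f | −), α* = b* − a*.  The constant does not
move the optimum, and the per-sample form allows plain stochastic updates.

Training mixes the AUC term with binary cross-entropy:
L = τ·L_AUC + (1−τ)·L_BCE.  The AUC terms act on raw logits; BCE on the
logistic transform (its calibration role).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from ._autograd import Tensor

logger = logging.getLogger(__name__)


@dataclass
class AUCState:
    """Saddle variables and class prior; margin is fixed at 1."""

    a: float = 0.0
    b: float = 0.0
    alpha: float = 0.0
    p: float = 0.5
    margin: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")


@dataclass
class LossConfig:
    tau: float = 0.5
    model_lr: float = 1e-3
    aux_lr: float = 1e-2          # shared by (a, b) descent and alpha ascent
    weight_decay: float = 0.0     # optional stand-in for the ||w|| <= R bound

    def __post_init__(self):
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError("tau must lie in [0, 1]")


def _split_classes(scores, labels):
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos, neg = scores[labels == 1], scores[labels != 1]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def empirical_auc(scores, labels) -> float:
    """Mann–Whitney rank AUC; ties between classes count one half."""
    pos, neg = _split_classes(scores, labels)
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    return float(
        (r_pos - len(pos) * (len(pos) + 1) / 2.0) / (len(pos) * len(neg))
    )


def pairwise_auc_enumeration(scores, labels) -> float:
    """Brute-force pair enumeration oracle for the rank AUC."""
    pos, neg = _split_classes(scores, labels)
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum())
                 / (len(pos) * len(neg)))


def pairwise_surrogate_loss(scores, labels, margin: float = 1.0) -> float:
    """Mean squared surrogate over all (positive, negative) pairs."""
    pos, neg = _split_classes(scores, labels)
    return float(np.mean((margin - (pos[:, None] - neg[None, :])) ** 2))


def saddle_objective_F(score: float, y: int, state: AUCState) -> float:
    """Per-sample saddle objective; y in {+1, −1}."""
    if y not in (1, -1):
        raise ValueError("y must be +1 or -1")
    p, a, b, alpha = state.p, state.a, state.b, state.alpha
    pos, neg = (y == 1), (y == -1)
    value = (1 - p) * (score - a) ** 2 * pos + p * (score - b) ** 2 * neg
    value += 2 * (1 + alpha) * (p * score * neg - (1 - p) * score * pos)
    value -= p * (1 - p) * alpha ** 2
    return float(value)


def saddle_loss_mean(scores, labels, state: AUCState) -> float:
    """Vectorized batch mean of F (labels in {0, 1})."""
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    p, a, b, alpha = state.p, state.a, state.b, state.alpha
    f = (
        (1 - p) * (scores - a) ** 2 * y
        + p * (scores - b) ** 2 * (1 - y)
        + 2 * (1 + alpha) * (p * scores * (1 - y) - (1 - p) * scores * y)
        - p * (1 - p) * alpha ** 2
    )
    return float(f.mean())


def optimal_aux(scores, labels) -> tuple[float, float, float]:
    """Closed-form stationary point: class means and their gap."""
    pos, neg = _split_classes(scores, labels)
    a, b = float(pos.mean()), float(neg.mean())
    return a, b, b - a


def minmax_saddle_value(scores, labels, p: float | None = None) -> float:
    """min over (a, b), max over α of the batch mean of F."""
    labels = np.asarray(labels)
    if p is None:
        p = float((labels == 1).mean())
    a, b, alpha = optimal_aux(scores, labels)
    return saddle_loss_mean(scores, labels, AUCState(a=a, b=b, alpha=alpha, p=p))


def mixed_loss(l_auc: float, l_bce: float, tau: float) -> float:
    """τ-weighted combination of the AUC and cross-entropy terms."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    return tau * l_auc + (1 - tau) * l_bce


# ---------------------------------------------------------------------------
# tensor losses and the simultaneous min–max step
# ---------------------------------------------------------------------------

def saddle_loss_t(scores: Tensor, labels, a: Tensor, b: Tensor,
                  alpha: Tensor, p: float) -> Tensor:
    y = np.asarray(labels, dtype=np.float64)
    pos_term = (scores - a) ** 2 * ((1 - p) * y)
    neg_term = (scores - b) ** 2 * (p * (1 - y))
    cross = (alpha + 1.0) * (scores * (2 * p * (1 - y) - 2 * (1 - p) * y))
    penalty = alpha * alpha * (-p * (1 - p))
    return (pos_term + neg_term + cross).mean() + penalty


def bce_loss_t(logits: Tensor, labels) -> Tensor:
    """Stable binary cross-entropy on logits: softplus(z) − z·y, averaged."""
    y = np.asarray(labels, dtype=np.float64)
    return (logits.softplus() - logits * y).mean()


class NonFiniteGradient(RuntimeError):
    """Raised when a saddle step produces NaN/inf gradients."""


def saddle_update_step(forward_fn, labels, params: dict, state: AUCState,
                       config: LossConfig, optimizer=None) -> dict:
    """One simultaneous min–max step on an edge batch.

    ``forward_fn(params) -> Tensor`` produces raw logits for the batch.
    Model parameters and (a, b) take a gradient-descent step; α takes an
    ascent step.  Non-finite gradients reject the step with a diagnostic.
    Returns the loss components for logging.
    """
    y = np.asarray(labels, dtype=np.float64)
    a_t = Tensor(np.array(state.a), requires_grad=True)
    b_t = Tensor(np.array(state.b), requires_grad=True)
    alpha_t = Tensor(np.array(state.alpha), requires_grad=True)

    scores = forward_fn(params)
    l_auc = saddle_loss_t(scores, y, a_t, b_t, alpha_t, state.p)
    l_bce = bce_loss_t(scores, y)
    loss = l_auc * config.tau + l_bce * (1.0 - config.tau)
    for p_t in params.values():
        p_t.grad = None
    loss.backward()

    grads = [t.grad for t in (a_t, b_t, alpha_t)]
    grads += [p_t.grad for p_t in params.values() if p_t.grad is not None]
    if any(g is not None and not np.all(np.isfinite(g)) for g in grads):
        logger.warning("non-finite gradient; saddle step rejected")
        raise NonFiniteGradient("non-finite gradient in saddle update step")

    if optimizer is not None:
        optimizer.step()
    else:
        for p_t in params.values():
            if p_t.grad is not None:
                p_t.data = p_t.data - config.model_lr * p_t.grad
    if a_t.grad is not None:
        state.a -= config.aux_lr * float(a_t.grad)
    if b_t.grad is not None:
        state.b -= config.aux_lr * float(b_t.grad)
    if alpha_t.grad is not None:
        state.alpha += config.aux_lr * float(alpha_t.grad)

    return {
        "loss": float(loss.data),
        "l_auc": float(l_auc.data),
        "l_bce": float(l_bce.data),
        "a": state.a, "b": state.b, "alpha": state.alpha, "p": state.p,
    }
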