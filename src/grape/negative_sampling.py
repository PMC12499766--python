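"""Negative edge sampling: initial per-epitope quotas and dynamic updates.

Unobserved TCR–epitope pairs stand in for negatives.  Initially each
epitope draws a fixed quota of TCRs (default 10) uniformly without
replacement from candidates not positively paired with it.  During
training, negatives the model already classifies as positive
(probability ≥ threshold, i.e. misclassified) are retained — they are the
informative ones — while a fraction M of the correctly classified
negatives is replaced by fresh draws.  Resampling is gated on validation
improvement: it runs for the next epoch only when performance surpasses
the previous best.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class SamplerConfig:
    negatives_per_epitope: int = 10
    resample_fraction: float = 0.1          # M
    threshold: float = 0.5
    gated: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.negatives_per_epitope < 0:
            raise ValueError("quota must be >= 0")
        if not 0.0 <= self.resample_fraction <= 1.0:
            raise ValueError("resample fraction M must lie in [0, 1]")


@dataclass
class SamplerState:
    negatives: list                          # [(tcr_idx, epi_idx), ...]
    pools: dict = field(repr=False)          # epi_idx -> np.ndarray of candidate tcr_idx
    positives: set = field(repr=False)
    best_metric: float = -np.inf
    rng: np.random.Generator = None
    shortfalls: int = 0
    last_replaced: int = 0
    last_retained: int = 0

    def negative_set(self) -> set:
        return set(self.negatives)


def build_pools(positive_edges, epitope_indices, candidate_tcrs) -> dict:
    """Per-epitope candidate TCRs, excluding positively paired ones."""
    pos_by_epi: dict[int, set] = {int(e): set() for e in epitope_indices}
    for t, e in positive_edges:
        pos_by_epi.setdefault(int(e), set()).add(int(t))
    candidates = np.asarray(sorted(int(t) for t in candidate_tcrs))
    pools = {}
    for e in epitope_indices:
        excluded = pos_by_epi.get(int(e), set())
        pools[int(e)] = np.array(
            [t for t in candidates if t not in excluded], dtype=np.intp
        )
    return pools


def initial_negatives(positive_edges, epitope_indices, candidate_tcrs,
                      config: SamplerConfig,
                      rng: np.random.Generator | None = None) -> SamplerState:
    """Draw the starting negative set: per-epitope uniform quota.

    When an epitope has fewer candidates than the quota, all candidates are
    taken and the shortfall is logged.
    """
    candidate_tcrs = list(candidate_tcrs)
    if not candidate_tcrs:
        raise ValueError("no candidate TCR nodes to sample from")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    pools = build_pools(positive_edges, epitope_indices, candidate_tcrs)
    negatives, shortfalls = [], 0
    for e in sorted(pools):
        pool = pools[e]
        take = min(config.negatives_per_epitope, len(pool))
        if take < config.negatives_per_epitope:
            shortfalls += config.negatives_per_epitope - take
        chosen = rng.choice(pool, size=take, replace=False) if take else []
        negatives.extend((int(t), int(e)) for t in sorted(int(c) for c in chosen))
    if shortfalls:
        logger.warning("negative sampling shortfall: %d slots unfilled", shortfalls)
    positives = {(int(t), int(e)) for t, e in positive_edges}
    return SamplerState(negatives=negatives, pools=pools, positives=positives,
                        rng=rng, shortfalls=shortfalls)


def dynamic_resample(state: SamplerState, probabilities, config: SamplerConfig,
                     metric: float | None = None) -> SamplerState:
    """Replace floor(M × n_correct) correctly classified negatives in place.

    ``probabilities`` aligns with ``state.negatives``.  Misclassified
    negatives (probability ≥ threshold) are always retained.  Replacements
    are drawn from the same epitope's pool, avoiding positives and current
    negatives, preserving per-epitope quotas.  With gating enabled the
    update is skipped unless ``metric`` surpasses the best seen so far.
    """
    probabilities = np.asarray(probabilities, dtype=np.float64)
    if len(probabilities) != len(state.negatives):
        raise ValueError("predictions do not cover the current negative set")

    run = True
    if config.gated and metric is not None:
        run = metric > state.best_metric
    if metric is not None:
        state.best_metric = max(state.best_metric, metric)
    state.last_replaced = 0
    state.last_retained = len(state.negatives)
    if not run or config.resample_fraction == 0.0:
        return state

    correct_idx = [i for i, p in enumerate(probabilities)
                   if p < config.threshold]
    n_replace = int(np.floor(config.resample_fraction * len(correct_idx)))
    if n_replace == 0:
        return state
    chosen = state.rng.choice(len(correct_idx), size=n_replace, replace=False)
    replace_idx = {correct_idx[int(i)] for i in chosen}

    current = set(state.negatives)
    new_negatives = list(state.negatives)
    replaced = 0
    for i in sorted(replace_idx):
        t_old, e = state.negatives[i]
        pool = state.pools[e]
        forbidden = current
        fresh = [t for t in pool if (int(t), e) not in forbidden]
        if not fresh:
            continue  # exhausted pool: keep the old edge
        t_new = int(state.rng.choice(np.asarray(fresh, dtype=np.intp)))
        current.discard((t_old, e))
        current.add((t_new, e))
        new_negatives[i] = (t_new, e)
        replaced += 1
    state.negatives = new_negatives
    state.last_replaced = replaced
    state.last_retained = len(new_negatives) - replaced
    return state
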