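"""Training, evaluation, and prediction orchestration.

Training builds the train-fold graph (observed edges plus sampled
negatives), runs simultaneous min–max updates of the mixed
τ·AUC + (1−τ)·BCE loss over edge mini-batches (the whole graph is
re-encoded each step — cheap at the scales this package targets), applies
gated dynamic negative resampling once per epoch, and tracks validation
AUC for best-checkpoint selection and early stopping.

Evaluation is transductive and leakage-safe: held-out pairs are scored
from node embeddings computed with the train-edge adjacency only;
validation edges never participate in message passing, validation TCRs
never appear in training folds (StrictTCR), and validation negatives are
drawn from validation-fold TCRs so the two negative sets cannot overlap.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import average_precision_score

from . import auc_loss, negative_sampling
from ._autograd import Adam
from .data_io import FoldAssignment, InteractionRecord, split_records
from .embeddings import EmbedderSpec, embed_sequences
from .encoder import (EncoderConfig, encode_graph, init_params, score_pairs,
                      score_pairs_numpy)
from .graph_build import build_bipartite_graph, replace_negative_edges

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 128
    lr: float = 1e-3
    aux_lr: float = 1e-2
    weight_decay: float = 1e-2    # encoder/head only; wide term and biases exempt
    tau: float = 0.5
    resample_fraction: float = 0.1        # M
    negatives_per_epitope: int = 10
    val_negatives_per_epitope: int | None = None
    seed: int = 0
    fold: int = 0
    patience: int = 10
    # ablation switches ("w/o GA", "w/o DS", "w/o AUC", "w/o GN")
    attention: bool = True
    dynamic_sampling: bool = True
    auc_loss: bool = True
    graph_normalization: bool = True

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class Metrics:
    auc: float
    aupr: float
    loss_trace: list = field(default_factory=list)
    best_epoch: int = 0


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def evaluate_scores(scores, labels) -> tuple[float, float]:
    """AUC via the rank statistic; AUPR as step-wise average precision."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("evaluation requires both classes")
    auc = auc_loss.empirical_auc(scores, labels)
    aupr = float(average_precision_score(labels, scores))
    return auc, aupr


def _edges_with_negatives(base_graph, sampler_state):
    """Train graph = observed edges plus the sampler's current negatives."""
    add = [edge for edge in sampler_state.negatives
           if not base_graph.has_edge(*edge)]
    return replace_negative_edges(base_graph, [], add)


def train(records, folds: FoldAssignment, train_config: TrainConfig,
          encoder_config: EncoderConfig | None = None,
          loss_config: auc_loss.LossConfig | None = None,
          sampler_config: negative_sampling.SamplerConfig | None = None,
          embed_spec: EmbedderSpec | None = None,
          candidate_tcrs=None,
          log_path=None):
    """Train on all folds except ``train_config.fold``; validate on it.

    ``candidate_tcrs`` optionally widens the negative-sampling TCR pool
    beyond the record TCRs (e.g. repertoire TCRs without observed
    interactions); such sequences must be covered by the fold assignment so
    train- and validation-fold negative edges stay disjoint.

    Returns (checkpoint dict, Metrics).  Two runs with the same seed and
    configuration produce identical metric traces.
    """
    cfg = train_config
    rng = np.random.default_rng(cfg.seed)
    embed_spec = embed_spec or EmbedderSpec()
    encoder_config = encoder_config or EncoderConfig(attention=cfg.attention)
    encoder_config = EncoderConfig(**{
        **asdict_cfg(encoder_config),
        "attention": cfg.attention,
        "graph_norm": cfg.graph_normalization,
    })
    tau = cfg.tau if cfg.auc_loss else 0.0
    loss_config = loss_config or auc_loss.LossConfig(
        tau=tau, model_lr=cfg.lr, aux_lr=cfg.aux_lr)
    loss_config.tau = tau
    m_frac = cfg.resample_fraction if cfg.dynamic_sampling else 0.0
    sampler_config = sampler_config or negative_sampling.SamplerConfig(
        negatives_per_epitope=cfg.negatives_per_epitope,
        resample_fraction=m_frac, seed=cfg.seed)
    sampler_config.resample_fraction = m_frac

    train_records, val_records = split_records(records, folds, cfg.fold)
    if not train_records:
        raise ValueError("empty training fold")
    # StrictTCR runtime guard
    train_tcrs = {r.tcr for r in train_records}
    val_tcrs = {r.tcr for r in val_records}
    assert not train_tcrs & val_tcrs, "StrictTCR violation: shared TCRs"

    extra = sorted(
        (set(candidate_tcrs) if candidate_tcrs else set())
        & set(folds.assignment)
    )
    pool_train = train_tcrs | {t for t in extra
                               if folds.fold_of(t) != cfg.fold}
    pool_val = val_tcrs | {t for t in extra
                           if folds.fold_of(t) == cfg.fold}

    sequences = ([r.tcr for r in records] + [r.epitope for r in records]
                 + extra)
    embeddings = embed_sequences(sequences, embed_spec)

    base_graph = build_bipartite_graph(
        train_records, embeddings,
        extra_tcrs=sorted((val_tcrs | pool_train | pool_val) - train_tcrs),
        extra_epitopes=sorted({r.epitope for r in val_records}),
    )
    epi_indices = [base_graph.epitope_index(e)
                   for e in base_graph.epitope_sequences]
    train_tcr_idx = sorted(base_graph.tcr_index(t) for t in pool_train)
    val_tcr_idx = sorted(base_graph.tcr_index(t) for t in pool_val)

    sampler_rng = np.random.default_rng(rng.integers(2**31))
    state = negative_sampling.initial_negatives(
        base_graph.positive_edges, epi_indices, train_tcr_idx,
        sampler_config, sampler_rng)

    # validation pairs: held-out records plus validation-fold negatives,
    # drawn from validation TCRs only (disjoint from training negatives).
    val_pairs = [(base_graph.tcr_index(r.tcr),
                  base_graph.epitope_index(r.epitope), r.label)
                 for r in val_records]
    if val_tcr_idx:
        val_quota = cfg.val_negatives_per_epitope
        if val_quota is None:
            val_quota = sampler_config.negatives_per_epitope
        val_neg_cfg = negative_sampling.SamplerConfig(
            negatives_per_epitope=val_quota,
            resample_fraction=0.0, seed=cfg.seed + 1)
        val_state = negative_sampling.initial_negatives(
            base_graph.positive_edges, epi_indices, val_tcr_idx,
            val_neg_cfg, np.random.default_rng(cfg.seed + 1))
        observed = {(int(t), int(e)) for t, e, _ in val_pairs}
        val_pairs += [(t, e, 0) for t, e in val_state.negatives
                      if (t, e) not in observed]
        assert not set(val_state.negatives) & state.negative_set(), \
            "StrictTCR violation: shared negative edges"
    val_t = np.array([p[0] for p in val_pairs], dtype=np.intp)
    val_e = np.array([p[1] for p in val_pairs], dtype=np.intp)
    val_y = np.array([p[2] for p in val_pairs])
    if len(np.unique(val_y)) < 2:
        raise ValueError("validation fold has a single class")

    params = init_params(encoder_config, np.random.default_rng(cfg.seed))
    if loss_config.weight_decay > 0:
        # explicit norm-bound proxy: uniform decay on every parameter
        optimizer = Adam(params, lr=cfg.lr,
                         weight_decay=loss_config.weight_decay)
    else:
        optimizer = Adam(
            params, lr=cfg.lr, weight_decay=cfg.weight_decay,
            decay_exclude=lambda n: (n == "shortcut_w" or n.endswith("_b")
                                     or n.startswith("ln_")))
    graph = _edges_with_negatives(base_graph, state)
    auc_state = auc_loss.AUCState(p=float(graph.labels.mean()))

    dropout_rng = np.random.default_rng(rng.integers(2**31))
    best = {"auc": -np.inf, "epoch": 0, "params": None, "aupr": 0.0,
            "edges": None}
    trace = []
    since_best = 0
    log_fh = open(log_path, "a") if log_path else None
    try:
        for epoch in range(cfg.epochs):
            edges, labels = graph.edges, graph.labels
            order = rng.permutation(len(edges))
            epoch_losses = []
            for start in range(0, len(order), cfg.batch_size):
                batch = order[start:start + cfg.batch_size]
                b_t, b_e = edges[batch, 0], edges[batch, 1]
                b_y = labels[batch]

                def forward(p, b_t=b_t, b_e=b_e):
                    Z = encode_graph(graph, encoder_config, p)
                    return score_pairs(Z, b_t, b_e, p, encoder_config,
                                       X=graph.X, dropout_rng=dropout_rng)

                optimizer.zero_grad()
                info = auc_loss.saddle_update_step(
                    forward, b_y, params, auc_state, loss_config, optimizer)
                epoch_losses.append(info["loss"])

            # epoch-end encode for validation + sampler predictions
            Z = encode_graph(graph, encoder_config, params).data
            val_scores = score_pairs_numpy(Z, val_t, val_e, params,
                                           encoder_config, X=graph.X)
            val_auc, val_aupr = evaluate_scores(val_scores, val_y)
            trace.append(float(np.mean(epoch_losses)))
            improved = val_auc > best["auc"]
            if improved:
                best = {
                    "auc": val_auc, "aupr": val_aupr, "epoch": epoch,
                    "params": {k: v.data.copy() for k, v in params.items()},
                    "edges": (graph.edges.copy(), graph.labels.copy()),
                }
                since_best = 0
            else:
                since_best += 1

            if log_fh:
                log_fh.write(json.dumps({
                    "epoch": epoch, "loss": trace[-1],
                    "l_auc": info["l_auc"], "l_bce": info["l_bce"],
                    "a": auc_state.a, "b": auc_state.b,
                    "alpha": auc_state.alpha, "p": auc_state.p,
                    "val_auc": val_auc, "val_aupr": val_aupr,
                    "retained": state.last_retained,
                    "replaced": state.last_replaced,
                    "shortfalls": state.shortfalls,
                }) + "\n")

            if since_best > cfg.patience:
                break

            if sampler_config.resample_fraction > 0:
                neg_idx = np.array(state.negatives, dtype=np.intp)
                neg_scores = score_pairs_numpy(
                    Z, neg_idx[:, 0], neg_idx[:, 1], params, encoder_config,
                    X=graph.X)
                old = state.negative_set()
                state = negative_sampling.dynamic_resample(
                    state, _sigmoid(neg_scores), sampler_config,
                    metric=val_auc)
                if state.negative_set() != old:
                    graph = _edges_with_negatives(base_graph, state)
                    auc_state.p = float(graph.labels.mean())
    finally:
        if log_fh:
            log_fh.close()

    checkpoint = {
        "params": best["params"],
        "encoder_config": asdict_cfg(encoder_config),
        "embed_spec": asdict(embed_spec),
        "tcr_sequences": list(base_graph.tcr_sequences),
        "epitope_sequences": list(base_graph.epitope_sequences),
        "edges": best["edges"][0],
        "edge_labels": best["edges"][1],
        "seed": cfg.seed,
    }
    metrics = Metrics(auc=float(best["auc"]), aupr=float(best["aupr"]),
                      loss_trace=trace, best_epoch=int(best["epoch"]))
    return checkpoint, metrics


def asdict_cfg(cfg) -> dict:
    from dataclasses import asdict as _as
    d = _as(cfg)
    d["head_dims"] = tuple(d["head_dims"])
    return d


def _restore_graph(checkpoint, extra_tcrs=(), extra_epitopes=()):
    spec = EmbedderSpec(**checkpoint["embed_spec"])
    tcrs = list(checkpoint["tcr_sequences"]) + [
        t for t in extra_tcrs if t not in set(checkpoint["tcr_sequences"])]
    epis = list(checkpoint["epitope_sequences"]) + [
        e for e in extra_epitopes
        if e not in set(checkpoint["epitope_sequences"])]
    embeddings = embed_sequences(tcrs + epis, spec)
    old_nt = len(checkpoint["tcr_sequences"])
    records = [
        InteractionRecord(checkpoint["tcr_sequences"][int(i)],
                          checkpoint["epitope_sequences"][int(j) - old_nt],
                          int(y))
        for (i, j), y in zip(checkpoint["edges"], checkpoint["edge_labels"])
    ]
    graph = build_bipartite_graph(
        records, embeddings,
        extra_tcrs=[t for t in tcrs],
        extra_epitopes=[e for e in epis])
    return graph


def _checkpoint_params(checkpoint):
    from ._autograd import Tensor
    return {k: Tensor(v) for k, v in checkpoint["params"].items()}


def predict(checkpoint, pairs) -> "pd.DataFrame":
    """Per-pair binding probabilities; unseen sequences join the graph as
    isolated nodes (train-edge adjacency only)."""
    import pandas as pd

    pairs = [(t, e) for t, e in pairs]
    graph = _restore_graph(checkpoint,
                           extra_tcrs={t for t, _ in pairs},
                           extra_epitopes={e for _, e in pairs})
    cfg = EncoderConfig(**checkpoint["encoder_config"])
    params = _checkpoint_params(checkpoint)
    Z = encode_graph(graph, cfg, params).data
    t_idx = np.array([graph.tcr_index(t) for t, _ in pairs], dtype=np.intp)
    e_idx = np.array([graph.epitope_index(e) for _, e in pairs], dtype=np.intp)
    logits = score_pairs_numpy(Z, t_idx, e_idx, params, cfg, X=graph.X)
    return pd.DataFrame({
        "cdr3b": [t for t, _ in pairs],
        "epitope": [e for _, e in pairs],
        "probability": _sigmoid(logits),
    })


def evaluate(checkpoint, records) -> Metrics:
    """Score labeled records against a checkpoint (transductive)."""
    records = list(records)
    labels = np.array([r.label for r in records])
    if len(np.unique(labels)) < 2:
        raise ValueError("evaluation requires both classes")
    table = predict(checkpoint, [(r.tcr, r.epitope) for r in records])
    auc, aupr = evaluate_scores(table["probability"].to_numpy(), labels)
    return Metrics(auc=auc, aupr=aupr)


def save_checkpoint(checkpoint, path) -> None:
    """Single binary container with a JSON header for reproducibility."""
    header = {k: checkpoint[k] for k in
              ("encoder_config", "embed_spec", "seed")}
    arrays = {f"param_{k}": v for k, v in checkpoint["params"].items()}
    np.savez(
        path,
        __header__=json.dumps(header),
        __tcrs__=np.array(checkpoint["tcr_sequences"]),
        __epitopes__=np.array(checkpoint["epitope_sequences"]),
        __edges__=checkpoint["edges"],
        __edge_labels__=checkpoint["edge_labels"],
        **arrays,
    )


def load_checkpoint(path) -> dict:
    with np.load(path, allow_pickle=False) as data:
        header = json.loads(str(data["__header__"]))
        header["encoder_config"]["head_dims"] = tuple(
            header["encoder_config"]["head_dims"])
        return {
            "params": {k[len("param_"):]: data[k]
                       for k in data.files if k.startswith("param_")},
            "encoder_config": header["encoder_config"],
            "embed_spec": header["embed_spec"],
            "seed": header["seed"],
            "tcr_sequences": [str(s) for s in data["__tcrs__"]],
            "epitope_sequences": [str(s) for s in data["__epitopes__"]],
            "edges": data["__edges__"],
            "edge_labels": data["__edge_labels__"],
        }
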