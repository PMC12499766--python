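"""TCR–epitope bipartite interaction graph.

Nodes are typed (TCR or epitope) and carry sequence-embedding feature rows;
edges are labeled TCR–epitope pairs (1 = binds, 0 = does not).  A single
edge type represents both labels, so binding prediction is edge
classification, and the message-passing adjacency is built from whichever
edges are currently in the training edge set.  Node layout is deterministic:
TCR nodes first, then epitope nodes, each block sorted lexicographically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .data_io import InteractionRecord, deduplicate_records
from .embeddings import EmbeddingMatrix


@dataclass
class BipartiteGraph:
    tcr_sequences: list
    epitope_sequences: list
    X: np.ndarray
    edges: np.ndarray          # (E, 2) global node indices (tcr, epitope)
    labels: np.ndarray         # (E,) in {0, 1}
    adjacency_mode: str = "all"
    _edge_lookup: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._edge_lookup:
            self._edge_lookup = {
                (int(i), int(j)): k for k, (i, j) in enumerate(self.edges)
            }

    # -- layout --------------------------------------------------------------
    @property
    def n_tcr(self) -> int:
        return len(self.tcr_sequences)

    @property
    def n_epitope(self) -> int:
        return len(self.epitope_sequences)

    @property
    def n_nodes(self) -> int:
        return self.n_tcr + self.n_epitope

    def is_tcr_node(self, idx: int) -> bool:
        return idx < self.n_tcr

    def tcr_index(self, seq: str) -> int:
        return self._tcr_pos()[seq]

    def epitope_index(self, seq: str) -> int:
        return self.n_tcr + self._epi_pos()[seq]

    def _tcr_pos(self):
        if not hasattr(self, "_tcr_pos_cache"):
            self._tcr_pos_cache = {s: i for i, s in enumerate(self.tcr_sequences)}
        return self._tcr_pos_cache

    def _epi_pos(self):
        if not hasattr(self, "_epi_pos_cache"):
            self._epi_pos_cache = {s: i for i, s in enumerate(self.epitope_sequences)}
        return self._epi_pos_cache

    def node_sequence(self, idx: int) -> str:
        if idx < self.n_tcr:
            return self.tcr_sequences[idx]
        return self.epitope_sequences[idx - self.n_tcr]

    # -- edge bookkeeping ----------------------------------------------------
    def has_edge(self, i: int, j: int) -> bool:
        return (i, j) in self._edge_lookup

    def edge_label(self, i: int, j: int) -> int:
        return int(self.labels[self._edge_lookup[(i, j)]])

    @property
    def positive_edges(self) -> np.ndarray:
        return self.edges[self.labels == 1]

    @property
    def negative_edges(self) -> np.ndarray:
        return self.edges[self.labels == 0]

    # -- adjacency -----------------------------------------------------------
    def adjacency(self) -> sp.csr_matrix:
        """Symmetric binary adjacency (no self-loops) over current edges.

        With ``adjacency_mode='positives_only'`` label-0 edges are excluded
        from message passing (ablation alternative); the default propagates
        over both labels.
        """
        if self.adjacency_mode == "positives_only":
            edges = self.positive_edges
        else:
            edges = self.edges
        n = self.n_nodes
        if len(edges) == 0:
            return sp.csr_matrix((n, n))
        i, j = edges[:, 0], edges[:, 1]
        data = np.ones(len(edges))
        a = sp.coo_matrix((data, (i, j)), shape=(n, n))
        a = a + a.T
        a.data[:] = 1.0
        return a.tocsr()

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency().sum(axis=1)).ravel()


def build_bipartite_graph(
    records,
    embeddings: EmbeddingMatrix,
    extra_tcrs=(),
    extra_epitopes=(),
    adjacency_mode: str = "all",
) -> BipartiteGraph:
    """Assemble the graph from labeled records and a feature provider.

    One node per unique TCR and epitope, one edge per unique pair
    (conflicting duplicate labels resolve to the positive).  ``extra_*``
    sequences are added as isolated nodes — used for transductive scoring of
    held-out pairs whose edges must not enter message passing.
    """
    records = list(records)
    if not records:
        raise ValueError("records must be non-empty")
    records, _ = deduplicate_records(records)
    tcrs = sorted({r.tcr for r in records} | set(extra_tcrs))
    epitopes = sorted({r.epitope for r in records} | set(extra_epitopes))
    for seq in tcrs + epitopes:
        if seq not in embeddings:
            raise KeyError(f"no embedding for sequence {seq!r}")
    tcr_pos = {s: i for i, s in enumerate(tcrs)}
    epi_pos = {s: i for i, s in enumerate(epitopes)}
    n_tcr = len(tcrs)
    edges = np.array(
        [[tcr_pos[r.tcr], n_tcr + epi_pos[r.epitope]] for r in records],
        dtype=np.intp,
    ).reshape(len(records), 2)
    labels = np.array([r.label for r in records], dtype=np.intp)
    X = embeddings.submatrix(tcrs + epitopes)
    return BipartiteGraph(tcrs, epitopes, X, edges, labels,
                          adjacency_mode=adjacency_mode)


def _check_bipartite(graph: BipartiteGraph, i: int, j: int) -> None:
    if not (graph.is_tcr_node(i) and not graph.is_tcr_node(j)):
        raise ValueError(
            f"edge ({i}, {j}) is not a (TCR, epitope) pair in this layout"
        )


def replace_negative_edges(
    graph: BipartiteGraph, removed_edges, added_edges
) -> BipartiteGraph:
    """Swap negative edges in and out, leaving positives untouched.

    ``removed_edges`` must all be existing label-0 edges; ``added_edges``
    must be bipartite, absent from the edge set, and (in particular) must
    not duplicate a positive pair.  Returns a new graph sharing node layout
    and features.
    """
    removed = {(int(i), int(j)) for i, j in removed_edges}
    for i, j in removed:
        if not graph.has_edge(i, j):
            raise ValueError(f"cannot remove non-existent edge ({i}, {j})")
        if graph.edge_label(i, j) == 1:
            raise ValueError(f"cannot remove positive edge ({i}, {j})")
    keep = [k for k, (i, j) in enumerate(graph.edges)
            if (int(i), int(j)) not in removed]
    new_edges = [tuple(e) for e in graph.edges[keep]]
    new_labels = list(graph.labels[keep])
    present = set(new_edges)
    for i, j in added_edges:
        i, j = int(i), int(j)
        _check_bipartite(graph, i, j)
        if (i, j) in present:
            raise ValueError(f"edge ({i}, {j}) already present")
        present.add((i, j))
        new_edges.append((i, j))
        new_labels.append(0)
    return BipartiteGraph(
        graph.tcr_sequences,
        graph.epitope_sequences,
        graph.X,
        np.array(new_edges, dtype=np.intp).reshape(len(new_edges), 2),
        np.array(new_labels, dtype=np.intp),
        adjacency_mode=graph.adjacency_mode,
    )


def save_graph_tables(graph: BipartiteGraph, node_path, edge_path) -> None:
    """Serialize node and edge tables as TSV."""
    import pandas as pd

    nodes = pd.DataFrame({
        "index": np.arange(graph.n_nodes),
        "type": ["TCR"] * graph.n_tcr + ["EPITOPE"] * graph.n_epitope,
        "sequence": list(graph.tcr_sequences) + list(graph.epitope_sequences),
    })
    nodes.to_csv(node_path, sep="\t", index=False)
    edges = pd.DataFrame({
        "i": graph.edges[:, 0], "j": graph.edges[:, 1], "label": graph.labels,
    })
    edges.to_csv(edge_path, sep="\t", index=False)
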