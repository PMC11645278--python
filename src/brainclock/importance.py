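"""Node and edge ablation importance with bootstrap confidence intervals.

Importance of a node is the absolute change in predicted age when that
node is masked (feature row and adjacency row/column zeroed); edge
importance zeroes one symmetric adjacency entry. Ablation deltas are
computed once per test sample, then bootstrap replicates resample test
subjects with replacement, average the deltas, and normalize each
replicate's node (edge) scores by the replicate maximum; the report gives
across-replicate means with percentile 99% confidence intervals, sorted in
descending order of importance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError
from .gcn import GraphSample, TrainedModel, _forward_batch, normalized_adjacency


@dataclass
class ImportanceReport:
    nodes: pd.DataFrame  # label, mean, ci_low, ci_high, rank
    edges: pd.DataFrame | None
    n_bootstrap: int
    seed: int


def _params(model: TrainedModel) -> dict:
    return {"W0": model.W0, "b0": model.b0, "W1": model.W1, "b1": model.b1}


def _predict_masked(model, g, adjacency, features) -> float:
    pred, _ = _forward_batch(
        _params(model), normalized_adjacency(adjacency)[None], features[None]
    )
    return float(pred[0])


def ablate_node_effect(model: TrainedModel, g: GraphSample, node: int) -> float:
    """|prediction change| when a node's features and incident edges are zeroed."""
    R = g.n_nodes
    if not 0 <= node < R:
        raise ContractError(f"node {node} out of range [0, {R})")
    base = _predict_masked(model, g, g.adjacency, g.node_features)
    A = g.adjacency.copy()
    X = g.node_features.copy()
    A[node, :] = 0.0
    A[:, node] = 0.0
    X[node, :] = 0.0
    return abs(_predict_masked(model, g, A, X) - base)


def ablate_edge_effect(model: TrainedModel, g: GraphSample, i: int, j: int) -> float:
    """|prediction change| when the symmetric edge (i, j) is zeroed."""
    if i == j:
        raise ContractError("edge endpoints must differ")
    base = _predict_masked(model, g, g.adjacency, g.node_features)
    A = g.adjacency.copy()
    A[i, j] = A[j, i] = 0.0
    return abs(_predict_masked(model, g, A, g.node_features) - base)


def node_ablation_deltas(model: TrainedModel, samples) -> np.ndarray:
    """(n_samples, R) matrix of node ablation deltas, batched."""
    R = samples[0].n_nodes
    params = _params(model)
    out = np.empty((len(samples), R))
    eye = np.eye(R, dtype=bool)
    for si, g in enumerate(samples):
        base = _predict_masked(model, g, g.adjacency, g.node_features)
        A = np.broadcast_to(g.adjacency, (R, R, R)).copy()
        X = np.broadcast_to(g.node_features, (R, R, R)).copy()
        idx = np.arange(R)
        A[idx, idx, :] = 0.0
        A[idx, :, idx] = 0.0
        X[idx, idx, :] = 0.0
        pred, _ = _forward_batch(params, normalized_adjacency(A), X)
        out[si] = np.abs(pred - base)
    return out


def edge_ablation_deltas(model: TrainedModel, samples, edges) -> np.ndarray:
    """(n_samples, n_edges) ablation deltas for the listed (i, j) edges."""
    params = _params(model)
    E = len(edges)
    out = np.empty((len(samples), E))
    for si, g in enumerate(samples):
        base = _predict_masked(model, g, g.adjacency, g.node_features)
        A = np.broadcast_to(g.adjacency, (E,) + g.adjacency.shape).copy()
        for e, (i, j) in enumerate(edges):
            A[e, i, j] = A[e, j, i] = 0.0
        X = np.broadcast_to(g.node_features, (E,) + g.node_features.shape)
        pred, _ = _forward_batch(params, normalized_adjacency(A), np.ascontiguousarray(X))
        out[si] = np.abs(pred - base)
    return out


def _bootstrap_table(deltas: np.ndarray, labels, n_bootstrap, rng) -> pd.DataFrame:
    n = deltas.shape[0]
    scores = np.empty((n_bootstrap, deltas.shape[1]))
    for b in range(n_bootstrap):
        pick = rng.integers(n, size=n)
        mean_delta = deltas[pick].mean(axis=0)
        peak = mean_delta.max()
        scores[b] = mean_delta / peak if peak > 0 else 0.0
    mean = scores.mean(axis=0)
    lo, hi = np.percentile(scores, [0.5, 99.5], axis=0)
    order = np.argsort(-mean, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(1, len(order) + 1)
    tbl = pd.DataFrame(
        {"label": labels, "mean": mean, "ci_low": lo, "ci_high": hi, "rank": rank}
    )
    return tbl.sort_values("rank").reset_index(drop=True)


def bootstrap_importance(
    model: TrainedModel,
    test_set,
    n_bootstrap: int = 5000,
    seed: int = 0,
    node_labels=None,
    top_k_edges: int = 10,
) -> ImportanceReport:
    """Bootstrap node (and top-k edge) ablation importance with 99% CIs."""
    if not test_set:
        raise ContractError("test set must be non-empty")
    R = test_set[0].n_nodes
    labels = list(node_labels) if node_labels is not None else [f"region{i}" for i in range(R)]
    rng = np.random.default_rng(seed)
    node_deltas = node_ablation_deltas(model, test_set)
    nodes = _bootstrap_table(node_deltas, labels, n_bootstrap, rng)

    edges_tbl = None
    if top_k_edges > 0:
        all_edges = [(i, j) for i in range(R) for j in range(i + 1, R)]
        edge_deltas = edge_ablation_deltas(model, test_set, all_edges)
        keep = np.argsort(-edge_deltas.mean(axis=0), kind="stable")[:top_k_edges]
        edge_labels = [f"{labels[all_edges[e][0]]}--{labels[all_edges[e][1]]}" for e in keep]
        edges_tbl = _bootstrap_table(edge_deltas[:, keep], edge_labels, n_bootstrap, rng)
    return ImportanceReport(nodes=nodes, edges=edges_tbl, n_bootstrap=n_bootstrap, seed=seed)
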