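"""Morphological-connectivity graph construction.

A scan's N x 4 region feature matrix is turned into a weighted undirected
graph: nodes are cortical regions, edge weights are pairwise
dissimilarities between region feature vectors, under either the
Mahalanobis distance

    d_M(x_i, x_j) = ((x_i - x_j)^T S^{-1} (x_i - x_j))^{1/2}

with S the 4x4 covariance of the scan's N region vectors (estimated once
per scan — the only well-posed per-scan reading, and it whitens the four
heterogeneous-scale moments), or the Taxicab (Manhattan) distance

    d_T(x_i, x_j) = sum_k |x_ik - x_jk|.

A rejection quantile tau then prunes the *lowest* distances (the most
similar, least informative pairs): with q the tau-quantile of the scan's
upper-triangular distances, edges with d >= q are retained, so every scan
keeps the same graph density. Retained weights are the raw distances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .features import FeatureMatrix
from .normalization import AdjustedFeatureMatrix

__all__ = [
    "AdjacencyMatrix",
    "BrainGraph",
    "mahalanobis_distance",
    "taxicab_distance",
    "estimate_covariance",
    "build_adjacency",
    "threshold_graph",
    "build_graph",
    "serialize_graph",
    "deserialize_graph",
]

METRICS = ("mahalanobis", "taxicab")

FeatureLike = Union[FeatureMatrix, AdjustedFeatureMatrix, np.ndarray]


def _feature_values(X: FeatureLike) -> np.ndarray:
    if isinstance(X, (FeatureMatrix, AdjustedFeatureMatrix)):
        return np.asarray(X.values, dtype=float)
    return np.asarray(X, dtype=float)


def taxicab_distance(xi, xj) -> float:
    """L1 distance between two region feature vectors."""
    xi, xj = np.asarray(xi, float), np.asarray(xj, float)
    if not (np.all(np.isfinite(xi)) and np.all(np.isfinite(xj))):
        raise ValueError("non-finite feature vector")
    return float(np.abs(xi - xj).sum())


def mahalanobis_distance(xi, xj, S) -> float:
    """Mahalanobis distance under covariance S (symmetric positive
    definite; see :func:`estimate_covariance` for regularization)."""
    d = np.asarray(xi, float) - np.asarray(xj, float)
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite feature vector")
    S = np.asarray(S, float)
    try:
        L = np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        raise ValueError(
            "covariance is not positive definite "
            f"(condition number {np.linalg.cond(S):.3g})"
        ) from None
    y = np.linalg.solve(L, d)
    return float(np.sqrt(y @ y))


def estimate_covariance(
    X: FeatureLike,
    ridge_scale: float = 1e-6,
    cond_threshold: float = 1e8,
) -> np.ndarray:
    """4x4 sample covariance of a scan's N region feature vectors.

    Adds a ridge eps*I with eps = ridge_scale * trace/4 (or ridge_scale
    if the trace vanishes) whenever the condition number exceeds
    ``cond_threshold``, so degenerate scans (constant columns, identical
    rows) still yield a usable metric.
    """
    V = _feature_values(X)
    if V.shape[0] < 5:
        raise ValueError(f"need >= 5 region vectors to estimate covariance, got {V.shape[0]}")
    S = np.cov(V, rowvar=False)
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > cond_threshold:
        tr = float(np.trace(S))
        eps = ridge_scale * (tr / S.shape[0] if tr > 0 else 1.0)
        S = S + eps * np.eye(S.shape[0])
        cond = np.linalg.cond(S)
        if not np.isfinite(cond) or cond > 1e14:
            raise ValueError(
                f"covariance singular even after ridge (condition number {cond:.3g})"
            )
    return S


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Symmetric matrix of all pairwise region dissimilarities."""

    values: np.ndarray
    metric: str
    scan_id: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("adjacency has non-finite entries")
        if np.any(v < 0):
            raise ValueError("adjacency has negative entries")
        if np.any(np.diag(v) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        object.__setattr__(self, "values", v)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.values[iu]


def build_adjacency(X: FeatureLike, metric: str, scan_id: str = "") -> AdjacencyMatrix:
    """All N(N-1)/2 pairwise distances between region feature vectors."""
    V = _feature_values(X)
    if isinstance(X, (FeatureMatrix, AdjustedFeatureMatrix)) and not scan_id:
        scan_id = X.scan_id
    if metric == "taxicab":
        D = squareform(pdist(V, metric="cityblock"))
    elif metric == "mahalanobis":
        S = estimate_covariance(V)
        VI = np.linalg.inv(S)
        D = squareform(pdist(V, metric="mahalanobis", VI=VI))
    else:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    np.fill_diagonal(D, 0.0)
    return AdjacencyMatrix(values=D, metric=metric, scan_id=scan_id)


@dataclass(frozen=True)
class BrainGraph:
    """Weighted undirected thresholded graph plus node features.

    Edges are stored once per unordered pair with i < j; weights are the
    raw (positive) distances that survived the rejection quantile.
    """

    n_nodes: int
    edge_i: np.ndarray
    edge_j: np.ndarray
    edge_weight: np.ndarray
    tau: float
    metric: str
    scan_id: str = ""
    node_features: Optional[np.ndarray] = None

    def __post_init__(self):
        i = np.asarray(self.edge_i, dtype=int)
        j = np.asarray(self.edge_j, dtype=int)
        w = np.asarray(self.edge_weight, dtype=float)
        if not (i.shape == j.shape == w.shape):
            raise ValueError("edge arrays must have equal length")
        if i.size and (np.any(i >= j) or np.any(i < 0) or np.any(j >= self.n_nodes)):
            raise ValueError("edges must satisfy 0 <= i < j < n_nodes")
        if np.any(w <= 0):
            raise ValueError("edge weights must be positive")
        pairs = set(zip(i.tolist(), j.tolist()))
        if len(pairs) != i.size:
            raise ValueError("duplicate edges")
        object.__setattr__(self, "edge_i", i)
        object.__setattr__(self, "edge_j", j)
        object.__setattr__(self, "edge_weight", w)
        if self.node_features is not None:
            f = np.asarray(self.node_features, dtype=float)
            if f.shape[0] != self.n_nodes:
                raise ValueError("node_features rows must equal n_nodes")
            object.__setattr__(self, "node_features", f)

    @property
    def n_edges(self) -> int:
        return int(self.edge_i.size)

    def to_dense_adjacency(self) -> np.ndarray:
        A = np.zeros((self.n_nodes, self.n_nodes))
        A[self.edge_i, self.edge_j] = self.edge_weight
        A[self.edge_j, self.edge_i] = self.edge_weight
        return A

    def to_networkx(self):
        import networkx as nx

        G = nx.Graph(tau=self.tau, metric=self.metric, scan_id=self.scan_id)
        G.add_nodes_from(range(self.n_nodes))
        if self.node_features is not None:
            for n in range(self.n_nodes):
                G.nodes[n]["features"] = self.node_features[n].tolist()
        G.add_weighted_edges_from(
            zip(self.edge_i.tolist(), self.edge_j.tolist(),
                self.edge_weight.tolist())
        )
        return G


def threshold_graph(
    A: AdjacencyMatrix,
    tau: float,
    node_features: Optional[FeatureLike] = None,
) -> BrainGraph:
    """Prune the lowest ``tau``-quantile of distances.

    q is the linear-interpolation tau-quantile of the scan's own
    upper-triangular distances; edges with distance >= q are retained
    (ties inclusive), so density is fixed across scans up to ties.
    Zero-distance pairs are never edges (a weight of 0 is no edge);
    tau = 0 therefore keeps all N(N-1)/2 edges whenever all distances are
    positive.
    """
    if not (0.0 <= tau < 1.0):
        raise ValueError(f"tau must be in [0, 1), got {tau}")
    n = A.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    d = A.values[iu, ju]
    q = float(np.quantile(d, tau)) if d.size else 0.0
    keep = (d >= q) & (d > 0)
    feats = _feature_values(node_features) if node_features is not None else None
    return BrainGraph(
        n_nodes=n, edge_i=iu[keep], edge_j=ju[keep], edge_weight=d[keep],
        tau=float(tau), metric=A.metric, scan_id=A.scan_id,
        node_features=feats,
    )


def build_graph(X: FeatureLike, metric: str, tau: float,
                scan_id: str = "") -> BrainGraph:
    """Feature matrix -> thresholded graph with the features attached as
    node attributes (the standard end-to-end step)."""
    A = build_adjacency(X, metric, scan_id=scan_id)
    return threshold_graph(A, tau, node_features=X)


# ---------------------------------------------------------------------------
# Serialization: TSV edge list + TSV node features + JSON sidecar.

def serialize_graph(G: BrainGraph, prefix) -> None:
    """Write ``<prefix>.edges.tsv``, ``<prefix>.nodes.tsv`` (if features
    present) and ``<prefix>.json``; weights keep 17 significant digits so
    the round-trip is lossless."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(f"{prefix}.edges.tsv", "w") as fh:
        fh.write("i\tj\tweight\n")
        for i, j, w in zip(G.edge_i, G.edge_j, G.edge_weight):
            fh.write(f"{i}\t{j}\t{w:.17g}\n")
    if G.node_features is not None:
        with open(f"{prefix}.nodes.tsv", "w") as fh:
            ncol = G.node_features.shape[1]
            fh.write("node\t" + "\t".join(f"f{c}" for c in range(ncol)) + "\n")
            for n in range(G.n_nodes):
                row = "\t".join(f"{v:.17g}" for v in G.node_features[n])
                fh.write(f"{n}\t{row}\n")
    meta = {
        "n_nodes": G.n_nodes, "tau": G.tau, "metric": G.metric,
        "scan_id": G.scan_id, "n_edges": G.n_edges,
        "has_node_features": G.node_features is not None,
    }
    Path(f"{prefix}.json").write_text(json.dumps(meta, indent=2))


def _parse_tsv(path, n_fields: int):
    rows = []
    with open(path) as fh:
        header = fh.readline()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_fields:
                raise ValueError(
                    f"{path}: line {lineno}: expected {n_fields} fields, "
                    f"got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric field"
                ) from None
    return rows


def deserialize_graph(prefix) -> BrainGraph:
    prefix = Path(prefix)
    meta = json.loads(Path(f"{prefix}.json").read_text())
    edges = _parse_tsv(f"{prefix}.edges.tsv", 3)
    if edges:
        arr = np.asarray(edges)
        ei, ej, w = arr[:, 0].astype(int), arr[:, 1].astype(int), arr[:, 2]
    else:
        ei = ej = np.zeros(0, dtype=int)
        w = np.zeros(0)
    feats = None
    if meta.get("has_node_features"):
        feats = _parse_node_tsv(f"{prefix}.nodes.tsv")
    return BrainGraph(
        n_nodes=int(meta["n_nodes"]), edge_i=ei, edge_j=ej, edge_weight=w,
        tau=float(meta["tau"]), metric=meta["metric"],
        scan_id=meta.get("scan_id", ""), node_features=feats,
    )


def _parse_node_tsv(path) -> np.ndarray:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_fields = len(header)
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_fields:
                raise ValueError(
                    f"{path}: line {lineno}: expected {n_fields} fields, "
                    f"got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts[1:]])
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-numeric field") from None
    return np.asarray(rows)
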