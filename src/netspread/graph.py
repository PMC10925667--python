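"""Connectome graphs: validation, thresholding, Laplacian, summary statistics.

A structural connectome arrives as a symmetric non-negative weight matrix
``W`` (e.g. streamline counts scaled by ROI volume).  Dynamics run on the
binary graph obtained by thresholding ``W`` at a weight ``S_w``: nodes *i*
and *j* are connected iff ``W_ij >= S_w`` (inclusive).  The graph Laplacian
used throughout is ``L = A - K`` with ``K`` the diagonal degree matrix, so
``L`` is symmetric, has zero row sums and is negative semidefinite —
exactly the generator of conservative diffusion on the graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components, shortest_path

from .errors import ValidationError

#: relative tolerance for accepting W as symmetric
SYMMETRY_RTOL = 1e-12


def _as_labels(labels: Sequence[str] | None, n: int) -> tuple[str, ...]:
    if labels is None:
        return tuple(f"node_{i:03d}" for i in range(n))
    labels = tuple(str(x) for x in labels)
    if len(labels) != n:
        raise ValidationError(
            f"expected {n} node labels, got {len(labels)}"
        )
    if len(set(labels)) != n:
        raise ValidationError("node labels must be unique")
    return labels


@dataclass(frozen=True)
class WeightedConnectome:
    """Raw weighted connectome: symmetric non-negative ``W`` with zero diagonal.

    Parameters
    ----------
    weights
        ``N x N`` array of connection strengths (dimensionless).
    labels
        Ordered node identifiers (ROI names); defaults to ``node_###``.
    """

    weights: np.ndarray
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValidationError(f"W must be square, got shape {W.shape}")
        if not np.all(np.isfinite(W)):
            i, j = np.argwhere(~np.isfinite(W))[0]
            raise ValidationError(f"non-finite weight at entry ({i}, {j})")
        neg = np.argwhere(W < 0)
        if neg.size:
            i, j = neg[0]
            raise ValidationError(
                f"negative weight W[{i},{j}] = {W[i, j]!r}; weights must be >= 0"
            )
        scale = W.max() if W.size else 0.0
        asym = np.abs(W - W.T)
        if scale > 0 and asym.max() > SYMMETRY_RTOL * scale:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise ValidationError(
                f"W is not symmetric: W[{i},{j}]={W[i, j]!r} vs W[{j},{i}]={W[j, i]!r}"
            )
        diag = np.argwhere(np.diag(W) != 0)
        if diag.size:
            i = int(diag[0][0])
            raise ValidationError(
                f"nonzero diagonal entry W[{i},{i}] = {W[i, i]!r}; "
                "self-loops are not allowed (use fix_diagonal=True at load "
                "to zero the diagonal)"
            )
        object.__setattr__(self, "weights", W)
        object.__setattr__(self, "labels", _as_labels(self.labels or None, W.shape[0]))

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class BinaryGraph:
    """Unweighted graph the dynamics run on: adjacency, degrees, provenance."""

    adjacency: np.ndarray
    threshold_used: float | None = None
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValidationError(f"A must be square, got shape {A.shape}")
        vals = np.unique(A)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValidationError("adjacency entries must be exactly 0 or 1")
        if not np.array_equal(A, A.T):
            raise ValidationError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValidationError("adjacency diagonal must be zero")
        object.__setattr__(self, "adjacency", A.astype(np.int64))
        object.__setattr__(self, "labels", _as_labels(self.labels or None, A.shape[0]))

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        """Degree vector k_i = sum_j A_ij."""
        return self.adjacency.sum(axis=1)

    def sparse_adjacency(self) -> csr_array:
        return csr_array(self.adjacency.astype(float))


@dataclass(frozen=True)
class GraphSummary:
    """Counts, connectivity and per-node mean BFS distances of a BinaryGraph."""

    n_nodes: int
    n_links: int
    is_connected: bool
    max_degree_node: tuple[int, int]  # (index, degree)
    min_degree_node: tuple[int, int]
    mean_shortest_path_from: Mapping[int, float] | None


def threshold_adjacency(W: WeightedConnectome, s_w: float) -> BinaryGraph:
    """Binarize ``W`` at threshold ``s_w``: an edge exists iff ``W_ij >= s_w``.

    The boundary is inclusive; the diagonal is forced to zero.
    """
    if not np.isfinite(s_w) or s_w <= 0:
        raise ValidationError(f"threshold S_w must be a positive scalar, got {s_w!r}")
    A = (W.weights >= s_w).astype(np.int64)
    np.fill_diagonal(A, 0)
    return BinaryGraph(adjacency=A, threshold_used=float(s_w), labels=W.labels)


def laplacian(G: BinaryGraph) -> np.ndarray:
    """Graph Laplacian ``L = A - K`` (integer-exact, negative semidefinite)."""
    A = G.adjacency
    L = A.astype(np.int64).copy()
    L[np.diag_indices_from(L)] = -G.degrees
    return L


def is_connected(G: BinaryGraph) -> bool:
    """True iff every node is reachable from node 0 (single component)."""
    if G.n_nodes <= 1:
        return True
    n_comp, _ = connected_components(
        csr_array(G.adjacency), directed=False, return_labels=True
    )
    return n_comp == 1


def mean_shortest_paths(G: BinaryGraph) -> dict[int, float]:
    """Per-node mean BFS hop distance to the other ``N - 1`` nodes.

    Raises on a disconnected graph, where hop distances are undefined.
    """
    if not is_connected(G):
        raise ValidationError(
            "mean shortest paths are undefined on a disconnected graph"
        )
    n = G.n_nodes
    if n == 1:
        return {0: 0.0}
    D = shortest_path(csr_array(G.adjacency), method="D", unweighted=True)
    means = D.sum(axis=1) / (n - 1)
    return {i: float(means[i]) for i in range(n)}


def summarize(G: BinaryGraph) -> GraphSummary:
    """Node/link counts, connectivity, extremal-degree nodes, mean BFS paths.

    Extremal nodes break degree ties by lowest index.  Mean shortest paths
    are reported only when the graph is connected.
    """
    k = G.degrees
    connected = is_connected(G)
    return GraphSummary(
        n_nodes=G.n_nodes,
        n_links=int(k.sum()) // 2,
        is_connected=connected,
        max_degree_node=(int(np.argmax(k)), int(k.max())),
        min_degree_node=(int(np.argmin(k)), int(k.min())),
        mean_shortest_path_from=mean_shortest_paths(G) if connected else None,
    )


def largest_connecting_threshold(
    W: WeightedConnectome, candidates: Sequence[float]
) -> float:
    """Largest candidate threshold that still yields a connected graph.

    Reproduces the threshold-selection rationale ("as sparse as possible
    while staying fully connected") on any weight matrix.  ``candidates``
    must be sorted ascending and positive.
    """
    cand = [float(c) for c in candidates]
    if not cand:
        raise ValidationError("candidate list is empty")
    if any(c <= 0 for c in cand):
        raise ValidationError("all candidate thresholds must be > 0")
    if any(b < a for a, b in zip(cand, cand[1:])):
        raise ValidationError("candidate thresholds must be sorted ascending")
    for s in reversed(cand):
        if is_connected(threshold_adjacency(W, s)):
            return s
    raise ValidationError(
        "no candidate threshold yields a connected graph; "
        "extend the candidate list toward smaller values"
    )
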