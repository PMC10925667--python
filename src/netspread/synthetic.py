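"""Synthetic connectome generator and small deterministic test graphs.

The generator emulates the summary statistics of a thresholded human
structural connectome — 379 parcels, about 1,738 supra-threshold links, a
single high-degree hub (degree ~36), at least one pendant (degree-1) node,
and full connectivity at the calibration threshold — without any
anatomical realism.  The topology is synthetic: a degree sequence targeted
at those statistics is realized by Havel-Hakimi construction, made
connected by degree-preserving cross-component edge swaps, and randomized
by connected double-edge swaps.  Supra-threshold edge weights are drawn
from a shifted log-normal above the threshold; a sprinkling of
sub-threshold noise weights sits below it, so thresholding behaves like it
does on real weighted connectomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import GenerationError, ValidationError
from .graph import BinaryGraph, WeightedConnectome, is_connected, threshold_adjacency


@dataclass(frozen=True)
class GeneratorSpec:
    """Targets for the synthetic connectome.

    Defaults reproduce the reference graph statistics: 379 nodes, 1,738
    links at threshold 0.034, hub degree 36, one pendant node.
    """

    n_nodes: int = 379
    target_links: int = 1738
    hub_degree: int = 36
    n_pendants: int = 1
    weight_scale: float = 1.0
    default_threshold: float = 0.034
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.target_links < self.n_nodes - 1:
            raise ValidationError(
                "target_links must be >= n_nodes - 1 for connectivity to be possible"
            )
        if not (0 < self.hub_degree < self.n_nodes):
            raise ValidationError("hub_degree must lie in (0, n_nodes)")
        if self.n_pendants < 0 or self.n_pendants + 1 > self.n_nodes:
            raise ValidationError("invalid number of pendant nodes")
        if not (self.default_threshold > 0):
            raise ValidationError("default_threshold must be > 0")


def _degree_sequence(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    """Degree sequence with one hub, the requested pendants, lognormal bulk."""
    n_rest = spec.n_nodes - 1 - spec.n_pendants
    total = 2 * spec.target_links
    rest_sum = total - spec.hub_degree - spec.n_pendants
    if n_rest <= 0:
        return np.array([spec.hub_degree] + [1] * spec.n_pendants)
    mean_rest = rest_sum / n_rest
    lo, hi = 2, max(3, spec.hub_degree - 4)
    sigma = 0.45
    mu = np.log(max(mean_rest, lo + 0.5)) - sigma**2 / 2
    rest = np.clip(np.round(rng.lognormal(mu, sigma, size=n_rest)), lo, hi).astype(int)
    # nudge random entries until the handshake sum is exact
    diff = rest_sum - int(rest.sum())
    while diff != 0:
        idx = rng.integers(n_rest)
        step = 1 if diff > 0 else -1
        if lo <= rest[idx] + step <= hi:
            rest[idx] += step
            diff -= step
    return np.concatenate(
        [[spec.hub_degree], np.ones(spec.n_pendants, dtype=int), rest]
    )


def _connect_preserving_degrees(G: nx.Graph, rng: np.random.Generator) -> None:
    """Merge components with 2-edge swaps; degrees are left untouched.

    Replacing edges (a, b) and (c, d) from two different components with
    (a, c) and (b, d) always merges them: even if removing (a, b) splits
    its component, both halves reattach through the other component.
    """
    while True:
        comps = list(nx.connected_components(G))
        if len(comps) == 1:
            return
        comps.sort(key=len, reverse=True)
        big, small = comps[0], comps[1]
        e1 = _random_edge_within(G, big, rng)
        e2 = _random_edge_within(G, small, rng)
        if e1 is None or e2 is None:
            raise GenerationError(
                "cannot connect the graph: a component has no internal edge "
                "(isolated node with degree 0 in the sequence)"
            )
        (a, b), (c, d) = e1, e2
        G.remove_edges_from([(a, b), (c, d)])
        G.add_edges_from([(a, c), (b, d)])


def _random_edge_within(G, nodes, rng) -> tuple | None:
    edges = [e for e in G.edges(nodes) if e[0] in nodes and e[1] in nodes]
    if not edges:
        return None
    return edges[rng.integers(len(edges))]


def _build_topology(spec: GeneratorSpec, rng: np.random.Generator) -> nx.Graph:
    degrees = _degree_sequence(spec, rng)
    if not nx.is_graphical(degrees.tolist()):
        raise GenerationError("degree sequence is not graphical")
    G = nx.havel_hakimi_graph(sorted(degrees.tolist(), reverse=True))
    _connect_preserving_degrees(G, rng)
    n_swaps = 2 * G.number_of_edges()
    if G.number_of_edges() > 2 and G.number_of_nodes() > 3:
        nx.connected_double_edge_swap(
            G, nswap=n_swaps, seed=int(rng.integers(2**31 - 1))
        )
    return G


def generate(spec: GeneratorSpec | None = None) -> WeightedConnectome:
    """Generate a weighted synthetic connectome matching ``spec``.

    The returned matrix thresholds (at ``spec.default_threshold``) to a
    connected graph with exactly ``target_links`` edges, max degree
    ``hub_degree`` and ``n_pendants`` degree-1 nodes.  Fully reproducible
    from ``rng_seed``.
    """
    spec = spec or GeneratorSpec()
    rng = np.random.default_rng(spec.rng_seed)
    last_err: Exception | None = None
    for _attempt in range(8):
        try:
            G = _build_topology(spec, rng)
        except GenerationError as err:
            last_err = err
            continue
        if not nx.is_connected(G):
            last_err = GenerationError("topology construction left the graph disconnected")
            continue
        degs = np.array([d for _, d in G.degree()])
        if abs(int(degs.max()) - spec.hub_degree) > 3:
            last_err = GenerationError(
                f"max degree {degs.max()} misses target {spec.hub_degree} +- 3"
            )
            continue
        if int(np.sum(degs == 1)) < spec.n_pendants:
            last_err = GenerationError("too few pendant (degree-1) nodes")
            continue
        return _assign_weights(G, spec, rng)
    raise GenerationError(
        f"could not satisfy generator constraints after bounded retries: {last_err}"
    )


def _assign_weights(
    G: nx.Graph, spec: GeneratorSpec, rng: np.random.Generator
) -> WeightedConnectome:
    n = spec.n_nodes
    s_w = spec.default_threshold
    W = np.zeros((n, n), dtype=float)
    # supra-threshold weights: threshold + lognormal tail, strictly >= S_w
    for u, v in G.edges():
        w_uv = s_w + spec.weight_scale * rng.lognormal(np.log(s_w), 1.0)
        W[u, v] = W[v, u] = w_uv
    # sub-threshold noise on as many non-edges, strictly < S_w
    available = n * (n - 1) // 2 - G.number_of_edges()
    n_noise = min(G.number_of_edges(), available)
    placed = 0
    while placed < n_noise:
        u, v = rng.integers(n, size=2)
        if u == v or W[u, v] != 0.0:
            continue
        w_uv = rng.uniform(0.0, s_w * (1.0 - 1e-9))
        W[u, v] = W[v, u] = w_uv
        placed += 1
    labels = tuple(f"ROI_{i + 1:03d}" for i in range(n))
    return WeightedConnectome(weights=W, labels=labels)


def make_small_fixtures() -> dict[str, BinaryGraph]:
    """Deterministic small graphs used as dynamics fixtures throughout.

    ``P2`` (single edge), ``K3`` (triangle), ``S4`` (star: hub + 4 leaves),
    ``random_20`` (connected Erdos-Renyi-style 20-node graph, fixed seed)
    and ``hub_pendant_20`` (20 nodes with one dominant hub and exactly one
    pendant).
    """
    out: dict[str, BinaryGraph] = {}

    def from_nx(name: str, G: nx.Graph) -> None:
        A = nx.to_numpy_array(G, nodelist=sorted(G.nodes()), dtype=int)
        out[name] = BinaryGraph(adjacency=A)

    from_nx("P2", nx.path_graph(2))
    from_nx("K3", nx.complete_graph(3))
    from_nx("S4", nx.star_graph(4))

    rng_seed = 1234
    G = nx.gnp_random_graph(20, 0.22, seed=rng_seed)
    while not nx.is_connected(G):
        rng_seed += 1
        G = nx.gnp_random_graph(20, 0.22, seed=rng_seed)
    from_nx("random_20", G)

    # hub node 0 wired to 1..12, ring among 1..18, node 19 pendant off node 9
    H = nx.Graph()
    H.add_nodes_from(range(20))
    H.add_edges_from((0, i) for i in range(1, 13))
    ring = list(range(1, 19))
    H.add_edges_from(zip(ring, ring[1:] + ring[:1]))
    H.add_edge(9, 19)
    from_nx("hub_pendant_20", H)
    return out
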