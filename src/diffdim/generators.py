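"""Synthetic graph generators: lattices, Delaunay meshes, random ensembles.

Lattices use 4-neighbour connectivity (the standard discretization of 2-D
diffusion); meshes triangulate points in the unit square with inverse-length
edge weights so that diffusion on the mesh approximates diffusion in the
plane; the random-graph ensemble reproduces the Erdős–Rényi /
Watts–Strogatz / Barabási–Albert families used for graph classification.
All stochastic generators are seeded and reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .graph_core import Graph

logger = logging.getLogger(__name__)

__all__ = [
    "MeshSpec",
    "EnsembleSpec",
    "line_graph",
    "ring_graph",
    "grid_graph",
    "torus_graph",
    "closest_factor_pair",
    "delaunay_mesh",
    "random_graph_ensemble",
]


def line_graph(n: int) -> Graph:
    """Unit-weight path on n nodes — a discretization of an interval."""
    if n < 2:
        raise ValueError("line graph needs at least 2 nodes")
    coords = np.column_stack([np.linspace(0, 1, n), np.zeros(n)])
    return Graph.from_networkx(nx.path_graph(n), coordinates=coords)


def ring_graph(n: int) -> Graph:
    """Unit-weight cycle on n nodes — the periodic line."""
    if n < 3:
        raise ValueError("ring graph needs at least 3 nodes")
    theta = 2 * np.pi * np.arange(n) / n
    coords = np.column_stack([np.cos(theta), np.sin(theta)])
    return Graph.from_networkx(nx.cycle_graph(n), coordinates=coords)


def _lattice(nx_, ny, periodic):
    if nx_ * ny < 4:
        raise ValueError("lattice needs at least 4 nodes")
    if periodic and (nx_ < 3 or ny < 3):
        raise ValueError("periodic lattice needs at least 3 nodes per side")
    g = nx.grid_2d_graph(nx_, ny, periodic=periodic)
    nodes = sorted(g.nodes())
    coords = np.array(nodes, dtype=float)
    return Graph.from_networkx(g, coordinates=coords)


def grid_graph(nx_: int, ny: int) -> Graph:
    """Unit-weight 4-neighbour rectangular lattice."""
    return _lattice(nx_, ny, periodic=False)


def torus_graph(nx_: int, ny: int) -> Graph:
    """Periodic 4-neighbour lattice (every node has degree 4)."""
    return _lattice(nx_, ny, periodic=True)


def closest_factor_pair(n: int) -> tuple[int, int]:
    """Factorization nx × ny = n closest to square (e.g. 500 → (25, 20))."""
    best = (n, 1)
    for a in range(1, int(np.sqrt(n)) + 1):
        if n % a == 0:
            best = (n // a, a)
    return best


@dataclass(frozen=True)
class MeshSpec:
    """Delaunay mesh of a regular grid plus an optional Gaussian point cluster.

    The base grid covers the unit square; ``extra_points`` are sampled from
    an isotropic Gaussian at ``cluster_center`` with variance ``cluster_var``
    (clipped to the square), acting as an added mass that locally densifies
    the mesh.
    """

    base_grid: tuple[int, int] = (40, 40)
    extra_points: int = 0
    cluster_center: tuple[float, float] = (0.5, 0.5)
    cluster_var: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.cluster_var <= 0:
            raise ValueError("cluster_var must be positive")
        if self.extra_points < 0:
            raise ValueError("extra_points must be non-negative")


def delaunay_mesh(spec: MeshSpec) -> Graph:
    """Triangulate the point set; edge weight = 1 / Euclidean edge length.

    Degenerate (collinear) point sets are retried with a small logged jitter.
    """
    from scipy.spatial import Delaunay, QhullError

    gx, gy = spec.base_grid
    xs, ys = np.meshgrid(np.linspace(0, 1, gx), np.linspace(0, 1, gy))
    points = np.column_stack([xs.ravel(), ys.ravel()])
    rng = np.random.default_rng(spec.seed)
    if spec.extra_points:
        extra = rng.normal(
            loc=spec.cluster_center,
            scale=np.sqrt(spec.cluster_var),
            size=(spec.extra_points, 2),
        )
        points = np.vstack([points, np.clip(extra, 0.0, 1.0)])
    for attempt in range(5):
        try:
            tri = Delaunay(points)
            break
        except QhullError:  # pragma: no cover - needs a contrived point set
            logger.warning("degenerate point set; jittering and retrying")
            points = points + rng.normal(scale=1e-9, size=points.shape)
    else:  # pragma: no cover
        raise RuntimeError("Delaunay triangulation failed after jitter retries")
    g = nx.Graph()
    g.add_nodes_from(range(len(points)))
    for simplex in tri.simplices:
        for a, b in ((0, 1), (1, 2), (0, 2)):
            u, v = int(simplex[a]), int(simplex[b])
            if not g.has_edge(u, v):
                length = float(np.linalg.norm(points[u] - points[v]))
                g.add_edge(u, v, weight=1.0 / length)
    return Graph.from_networkx(g, coordinates=points)


@dataclass(frozen=True)
class EnsembleSpec:
    """Random-graph ensemble for the classification experiment.

    Node counts are drawn from ``n_bins`` equal bins spanning ``n_range`` so
    the three classes share the same size distribution.  Family parameters
    are sampled uniformly from the stated ranges: ER edge probability
    0.03–0.1, BA edges-per-node 1–20, WS rewiring 0.1–0.7 with 5–10 ring
    neighbours.
    """

    families: tuple[str, ...] = ("ER", "WS", "BA")
    graphs_per_class: int = 600
    n_range: tuple[int, int] = (100, 1000)
    n_bins: int = 10
    er_p: tuple[float, float] = (0.03, 0.1)
    ba_m: tuple[int, int] = (1, 20)
    ws_p: tuple[float, float] = (0.1, 0.7)
    ws_k: tuple[int, int] = (5, 10)
    seed: int = 0


def _largest_component(g: nx.Graph) -> nx.Graph:
    if nx.is_connected(g):
        return g
    logger.info("sampled graph disconnected; taking the largest component")
    return g.subgraph(max(nx.connected_components(g), key=len)).copy()


def _sample_graph(family: str, n: int, spec: EnsembleSpec, rng: np.random.Generator) -> Graph:
    s = int(rng.integers(0, 2**31))
    if family == "ER":
        p = rng.uniform(*spec.er_p)
        g = _largest_component(nx.erdos_renyi_graph(n, p, seed=s))
    elif family == "WS":
        k = int(rng.integers(spec.ws_k[0], spec.ws_k[1] + 1))
        p = rng.uniform(*spec.ws_p)
        # rewiring can disconnect the ring; resample with incremented seed
        g = nx.connected_watts_strogatz_graph(n, k, p, tries=200, seed=s)
    elif family == "BA":
        m = int(rng.integers(spec.ba_m[0], min(spec.ba_m[1], n - 1) + 1))
        g = _largest_component(nx.barabasi_albert_graph(n, m, seed=s))
    else:
        raise ValueError(f"unknown family {family!r}")
    return Graph.from_networkx(g)


def random_graph_ensemble(spec: EnsembleSpec) -> tuple[list[Graph], list[str]]:
    """Seeded labelled ensemble; returns (graphs, family labels)."""
    if spec.graphs_per_class % spec.n_bins:
        raise ValueError("graphs_per_class must be divisible by n_bins")
    rng = np.random.default_rng(spec.seed)
    edges = np.linspace(spec.n_range[0], spec.n_range[1], spec.n_bins + 1)
    graphs: list[Graph] = []
    labels: list[str] = []
    per_bin = spec.graphs_per_class // spec.n_bins
    for family in spec.families:
        for b in range(spec.n_bins):
            for _ in range(per_bin):
                n = int(rng.integers(int(edges[b]), int(edges[b + 1]) + 1))
                graphs.append(_sample_graph(family, n, spec, rng))
                labels.append(family)
    return graphs, labels
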