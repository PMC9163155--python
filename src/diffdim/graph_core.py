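"""Graph data model, normalized Laplacian, spectral gap and source masses.

The diffusion generator throughout the package is the random-walk
(degree-normalized) Laplacian ``L = K^{-1}(K - A)``, where ``A`` is the
weighted adjacency matrix and ``K`` the diagonal matrix of weighted degrees.
Its continuum limit is Euclidean diffusion, which is what makes peak times
and amplitudes of the heat kernel interpretable in terms of a spatial
dimension.  Spectral computations go through the similarity-transformed
symmetric operator ``K^{1/2} L K^{-1/2} = I - K^{-1/2} A K^{-1/2}``, which
shares the eigenvalues of ``L``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.linalg as sla

logger = logging.getLogger(__name__)

__all__ = [
    "Graph",
    "LaplacianOperator",
    "MassVector",
    "load_graph",
    "normalized_laplacian",
    "source_masses",
]


def _sort_key(label: Hashable):
    # stable total order over possibly mixed label types
    return (str(type(label).__name__), label) if not isinstance(label, str) else ("str", label)


@dataclass(frozen=True)
class Graph:
    """Validated undirected weighted graph with a fixed node ordering.

    Node ordering is the sorted order of labels, fixed at construction, so
    that every matrix produced downstream is reproducible bit-for-bit.

    Attributes
    ----------
    node_ids : tuple
        Node labels in the fixed (sorted) order.
    adjacency : ndarray of shape (n, n)
        Dense symmetric weighted adjacency matrix, zero diagonal.
    coordinates : ndarray of shape (n, 2) or None
        Optional planar embedding (kept by the mesh and lattice generators).
    """

    node_ids: tuple
    adjacency: np.ndarray
    coordinates: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def weighted_degree(self) -> np.ndarray:
        """Per-node sum of incident edge weights (k_i)."""
        return self.adjacency.sum(axis=1)

    @property
    def mean_degree(self) -> float:
        """Mean weighted degree k̄."""
        return float(self.weighted_degree.mean())

    def index_of(self, node) -> int:
        try:
            return self.node_ids.index(node)
        except ValueError:
            raise KeyError(f"node {node!r} is not in the graph") from None

    def to_networkx(self) -> nx.Graph:
        g = nx.from_numpy_array(self.adjacency)
        return nx.relabel_nodes(g, dict(enumerate(self.node_ids)))

    @classmethod
    def from_networkx(cls, g: nx.Graph | nx.DiGraph, coordinates=None) -> "Graph":
        """Validate and freeze a networkx graph.

        Directed input is symmetrized by averaging the two directed weights;
        self-loops are dropped; duplicate undirected edges have already been
        collapsed by networkx (multigraphs are collapsed by summing weights).
        Raises ``ValueError`` on non-positive weights or a disconnected graph.
        """
        if isinstance(g, (nx.MultiGraph, nx.MultiDiGraph)):
            flat = nx.DiGraph() if g.is_directed() else nx.Graph()
            flat.add_nodes_from(g.nodes())
            for u, v, data in g.edges(data=True):
                w = data.get("weight", 1.0)
                if flat.has_edge(u, v):
                    flat[u][v]["weight"] += w
                else:
                    flat.add_edge(u, v, weight=w)
            g = flat
        nodes = tuple(sorted(g.nodes(), key=_sort_key))
        if len(nodes) < 2:
            raise ValueError("graph must have at least 2 nodes")
        a = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
        if g.is_directed():
            logger.warning("directed input: symmetrizing edge weights by averaging")
            a = (a + a.T) / 2.0
        if np.any(np.diag(a) != 0):
            logger.warning("dropping %d self-loop(s)", int(np.count_nonzero(np.diag(a))))
            np.fill_diagonal(a, 0.0)
        present = a != 0
        if np.any(a[present] <= 0):
            raise ValueError("all edge weights must be strictly positive")
        n_comp = _n_components(a)
        if n_comp != 1:
            raise ValueError(f"graph must be connected; found {n_comp} components")
        if np.any(a.sum(axis=1) <= 0):
            raise ValueError("every node must have positive weighted degree")
        if coordinates is not None:
            coordinates = np.asarray(coordinates, dtype=float)
        return cls(node_ids=nodes, adjacency=a, coordinates=coordinates)


def _n_components(adjacency: np.ndarray) -> int:
    from scipy.sparse.csgraph import connected_components

    n, _ = connected_components(adjacency != 0, directed=False)
    return int(n)


@dataclass(frozen=True)
class LaplacianOperator:
    """Normalized Laplacian ``L = K^{-1}(K - A)`` with its spectral data.

    The eigendecomposition is of the symmetrized form and is reused for
    every source and every evaluation time, so it is computed exactly once
    per graph.

    Attributes
    ----------
    matrix : ndarray
        Dense ``L``; every row sums to zero.
    eigenvalues : ndarray
        Ascending eigenvalues of the symmetrized form (= eigenvalues of L).
    eigenvectors : ndarray
        Orthonormal eigenvectors (columns) of the symmetrized form.
    degrees : ndarray
        Weighted degrees k_i of the underlying graph.
    mean_degree : float
        k̄, the mean weighted degree.
    """

    matrix: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    degrees: np.ndarray
    mean_degree: float

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def spectral_gap(self) -> float:
        """Second-smallest eigenvalue λ₂ (> 0 on a connected graph)."""
        return float(self.eigenvalues[1])

    @property
    def symmetrized_form(self) -> np.ndarray:
        """``K^{1/2} L K^{-1/2}``, the symmetric operator actually decomposed."""
        s = np.sqrt(self.degrees)
        return self.matrix * s[:, None] / s[None, :]

    def expm_apply(self, t: float, p0: np.ndarray) -> np.ndarray:
        """Evaluate ``exp(-t L) @ p0`` through the spectral decomposition."""
        s = np.sqrt(self.degrees)
        w = self.eigenvectors.T @ (s * p0)
        return (self.eigenvectors @ (np.exp(-t * self.eigenvalues) * w)) / s


def normalized_laplacian(g: Graph) -> LaplacianOperator:
    """Build ``L = K^{-1}(K - A)`` and eigendecompose its symmetrized form."""
    a = g.adjacency
    k = g.weighted_degree
    lap = np.diag(np.ones(g.n_nodes)) - a / k[:, None]
    inv_sqrt = 1.0 / np.sqrt(k)
    sym = np.eye(g.n_nodes) - inv_sqrt[:, None] * a * inv_sqrt[None, :]
    # enforce exact symmetry before eigh; float noise from the triple product
    sym = (sym + sym.T) / 2.0
    try:
        lam, vec = sla.eigh(sym)
    except sla.LinAlgError as exc:  # pragma: no cover - LAPACK failure is exotic
        raise RuntimeError("eigendecomposition of the symmetrized Laplacian failed") from exc
    if not np.all(np.isfinite(lam)):
        raise RuntimeError("eigendecomposition produced non-finite eigenvalues")
    # clip the tiny negative float noise on the zero mode
    lam = np.where(np.abs(lam) < 1e-12, 0.0, lam)
    return LaplacianOperator(
        matrix=lap,
        eigenvalues=lam,
        eigenvectors=vec,
        degrees=k.copy(),
        mean_degree=g.mean_degree,
    )


@dataclass(frozen=True)
class MassVector:
    """Initial condition with mass m_i = k̄/(n k_i) on each of n source nodes.

    This convention makes the stationary state of the diffusion sum to
    unity (every node tends to 1/N) and, for single sources, makes the
    relative-dimension matrix symmetric.
    """

    source_indices: tuple
    values: np.ndarray = field(repr=False)

    @property
    def n_sources(self) -> int:
        return len(self.source_indices)


def source_masses(g: Graph, source_nodes: Iterable) -> MassVector:
    """Masses ``m_i = k̄ / (n k_i)`` for a non-empty source subset."""
    sources = list(source_nodes)
    if not sources:
        raise ValueError("source set must be non-empty")
    idx = tuple(g.index_of(s) for s in sources)
    if len(set(idx)) != len(idx):
        raise ValueError("duplicate source nodes")
    k = g.weighted_degree
    values = np.zeros(g.n_nodes)
    values[list(idx)] = g.mean_degree / (len(idx) * k[list(idx)])
    return MassVector(source_indices=idx, values=values)


def _parse_edgelist(path: Path) -> nx.Graph:
    g = nx.Graph()
    header_skipped = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) == 2:
                u, v, w = parts[0], parts[1], 1.0
            elif len(parts) == 3:
                u, v = parts[0], parts[1]
                try:
                    w = float(parts[2])
                except ValueError:
                    if not header_skipped and g.number_of_edges() == 0:
                        header_skipped = True
                        continue
                    raise ValueError(
                        f"{path}:{lineno}: weight {parts[2]!r} is not a number"
                    ) from None
            else:
                raise ValueError(
                    f"{path}:{lineno}: expected 'source target [weight]', got {line!r}"
                )
            if g.has_edge(u, v):
                g[u][v]["weight"] += w  # duplicate undirected edges sum
            else:
                g.add_edge(u, v, weight=w)
    if g.number_of_nodes() == 0:
        raise ValueError(f"{path}: no edges found")
    return g


def load_graph(path: str | Path, format: str | None = None) -> Graph:
    """Read a graph from an edge list or GraphML file and validate it.

    Parameters
    ----------
    path : str or Path
        File to read.
    format : {"edgelist", "graphml"}, optional
        Inferred from the file suffix when omitted (``.graphml`` / ``.xml``
        map to GraphML, everything else to the edge-list reader).

    The edge list is whitespace- or comma-separated ``source target [weight]``
    with ``#`` comments and an optional header line; missing weights default
    to 1. Duplicate undirected edges are collapsed by summing their weights
    and self-loops are dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "graphml" if path.suffix.lower() in {".graphml", ".xml"} else "edgelist"
    if format == "graphml":
        g = nx.read_graphml(path)
        for _, _, data in g.edges(data=True):
            data["weight"] = float(data.get("weight", 1.0))
    elif format == "edgelist":
        g = _parse_edgelist(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return Graph.from_networkx(g)
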