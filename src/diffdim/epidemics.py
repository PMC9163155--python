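"""SIR spreading on graphs and its correlation with local dimension.

The epidemic model is the standard Markovian SIR: every infected node
recovers at rate γ, and transmits along each susceptible contact at rate β,
all waiting times exponential.  The final outbreak size is sampled exactly
through the percolation representation of that process: draw the source
node's infectious period T_u ~ Exp(γ), then each contact u→v transmits iff
an independent Exp(β) clock rings before T_u (probability 1 − e^{−β T_u});
the removed set is everything reachable from the seed through transmitting
contacts.  This reproduces the final-size distribution of the event-driven
simulation while only ever touching the edges the outbreak explores.

A node's *infectiousness* is its mean final removed count over many
realizations; β_crit is the smallest grid rate at which the population mean
reaches N/2.
"""

from __future__ import annotations

import math
import random
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dimension import LocalDimensionField
from .graph_core import Graph

__all__ = [
    "SIRConfig",
    "InfectiousnessTable",
    "CorrelationSurface",
    "simulate_sir",
    "node_infectiousness",
    "dimension_infectiousness_correlation",
    "default_beta_grid",
    "linear_beta_grid",
]


@dataclass(frozen=True)
class SIRConfig:
    """Transmission-rate grid, recovery rate and Monte-Carlo effort.

    γ defaults to 1, fixing the time unit to the infectious period so β is
    the single control parameter; 500 realizations per seed node is the
    default Monte-Carlo effort.
    """

    beta_grid: np.ndarray = field(default=None)  # type: ignore[assignment]
    gamma: float = 1.0
    n_realizations: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.beta_grid is None:
            raise ValueError("beta_grid is required (see default_beta_grid)")
        object.__setattr__(self, "beta_grid", np.asarray(self.beta_grid, dtype=float))
        if np.any(self.beta_grid < 0):
            raise ValueError("transmission rates must be non-negative")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be at least 1")


def default_beta_grid(g: Graph, n_points: int = 20, span: float = 10.0,
                      gamma: float = 1.0) -> np.ndarray:
    """Log-spaced rates bracketing the mean-field estimate γ/⟨k⟩ by ×1/span–×span."""
    center = gamma / g.mean_degree
    return np.logspace(np.log10(center / span), np.log10(center * span), n_points)


def linear_beta_grid(beta_max: float, n_points: int = 15) -> np.ndarray:
    """Linear rate grid (0, beta_max]; the scan used for correlation heatmaps."""
    return np.linspace(beta_max / n_points, beta_max, n_points)


def _neighbor_lists(g: Graph) -> list[list[int]]:
    a = g.adjacency
    return [list(np.nonzero(a[i])[0]) for i in range(g.n_nodes)]


def _final_size(nbrs: list[list[int]], n: int, beta: float, gamma: float,
                seed_idx: int, rng: random.Random) -> int:
    """One exact final-size sample (see module docstring)."""
    if beta == 0.0:
        return 1
    infected = bytearray(n)
    infected[seed_idx] = 1
    stack = [seed_idx]
    count = 1
    expovariate = rng.expovariate
    uniform = rng.random
    while stack:
        u = stack.pop()
        p_transmit = 1.0 - math.exp(-beta * expovariate(gamma))
        for v in nbrs[u]:
            if not infected[v] and uniform() < p_transmit:
                infected[v] = 1
                count += 1
                stack.append(v)
    return count


def simulate_sir(g: Graph, beta: float, gamma: float, seed_node,
                 rng: random.Random) -> int:
    """Final removed count (including the seed) of one SIR outbreak."""
    if beta < 0 or gamma <= 0:
        raise ValueError("need beta >= 0 and gamma > 0")
    return _final_size(_neighbor_lists(g), g.n_nodes, beta, gamma,
                       g.index_of(seed_node), rng)


@dataclass(frozen=True)
class InfectiousnessTable:
    """Mean final removed count per (node, β) and the critical rate.

    ``beta_crit`` is the smallest grid β whose population-mean infectability
    reaches N/2, or None (flagged undefined) when the grid never crosses it.
    """

    betas: np.ndarray
    mean_removed: np.ndarray = field(repr=False)  # (n_nodes, n_betas)
    node_ids: tuple | None = None

    @property
    def population_mean(self) -> np.ndarray:
        return self.mean_removed.mean(axis=0)

    @property
    def n_nodes(self) -> int:
        return self.mean_removed.shape[0]

    @property
    def beta_crit(self) -> float | None:
        crossed = self.population_mean >= self.n_nodes / 2.0
        if not crossed.any():
            return None
        return float(self.betas[int(np.argmax(crossed))])

    @property
    def beta_crit_index(self) -> int | None:
        crossed = self.population_mean >= self.n_nodes / 2.0
        if not crossed.any():
            return None
        return int(np.argmax(crossed))

    def to_csv(self, path) -> None:
        labels = self.node_ids or tuple(range(self.n_nodes))
        pd.DataFrame(self.mean_removed, index=pd.Index(labels, name="node"),
                     columns=self.betas).to_csv(path)


def _bulk_kernel():
    """Compiled all-(node, β, realization) final-size sampler.

    Same percolation construction as :func:`_final_size`, written over CSR
    neighbour arrays and JIT-compiled; the module-level cache keeps the
    compilation cost to once per process.
    """
    global _BULK
    if _BULK is not None:
        return _BULK
    import numba

    @numba.njit(cache=False)
    def bulk(indptr, indices, betas, gamma, n_real, seed):  # pragma: no cover
        np.random.seed(seed)
        n = indptr.shape[0] - 1
        out = np.zeros((n, betas.shape[0]))
        stack = np.empty(n, dtype=np.int64)
        infected = np.zeros(n, dtype=np.uint8)
        for b in range(betas.shape[0]):
            beta = betas[b]
            for i in range(n):
                total = 0.0
                for _ in range(n_real):
                    if beta == 0.0:
                        total += 1.0
                        continue
                    infected[:] = 0
                    infected[i] = 1
                    stack[0] = i
                    top = 1
                    count = 1
                    while top > 0:
                        top -= 1
                        u = stack[top]
                        t_u = np.random.exponential(1.0 / gamma)
                        p_transmit = 1.0 - np.exp(-beta * t_u)
                        for e in range(indptr[u], indptr[u + 1]):
                            v = indices[e]
                            if infected[v] == 0 and np.random.random() < p_transmit:
                                infected[v] = 1
                                count += 1
                                stack[top] = v
                                top += 1
                    total += count
                out[i, b] = total / n_real
        return out

    _BULK = bulk
    return bulk


_BULK = None


def node_infectiousness(g: Graph, cfg: SIRConfig) -> InfectiousnessTable:
    """Monte-Carlo infectiousness of every node over the β grid."""
    from scipy.sparse import csr_matrix

    adj = csr_matrix(g.adjacency != 0)
    bulk = _bulk_kernel()
    out = bulk(adj.indptr.astype(np.int64), adj.indices.astype(np.int64),
               cfg.beta_grid.astype(np.float64), float(cfg.gamma),
               int(cfg.n_realizations), int(cfg.seed) % (2**31))
    return InfectiousnessTable(betas=cfg.beta_grid.copy(), mean_removed=out,
                               node_ids=g.node_ids)


@dataclass(frozen=True)
class CorrelationSurface:
    """Pearson r between D_i(τ) and infectiousness(i, β) over a (τ, β) grid.

    Rows (scales) with fewer than 3 nodes of defined local dimension, or
    with zero variance on either side, are NaN.  ``tau_star``/``r_star``
    give the per-β best scale and best correlation.
    """

    taus: np.ndarray
    betas: np.ndarray
    correlations: np.ndarray = field(repr=False)  # (n_taus, n_betas)

    @property
    def r_star(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmax(self.correlations, axis=0)

    @property
    def tau_star(self) -> np.ndarray:
        filled = np.where(np.isnan(self.correlations), -np.inf, self.correlations)
        best = filled.argmax(axis=0)
        out = self.taus[best]
        return np.where(np.isinf(filled.max(axis=0)), np.nan, out)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.correlations, index=pd.Index(self.taus, name="tau"),
                     columns=self.betas).to_csv(path)


def dimension_infectiousness_correlation(
    ldf: LocalDimensionField, table: InfectiousnessTable
) -> CorrelationSurface:
    """Correlate the local-dimension field with infectiousness, per (τ, β).

    At each scale the correlation runs over the nodes whose local dimension
    is defined there.  Degenerate combinations (under 3 nodes, or constant
    values) are flagged NaN, never raised.
    """
    if ldf.values.shape[0] != table.n_nodes:
        raise ValueError("local-dimension field and infectiousness table "
                         "must share the node set")
    n_taus = len(ldf.taus)
    n_betas = len(table.betas)
    corr = np.full((n_taus, n_betas), np.nan)
    for s in range(n_taus):
        d = ldf.values[:, s]
        ok = ~np.isnan(d)
        if ok.sum() < 3:
            continue
        x = d[ok]
        sx = x.std()
        if sx == 0:
            continue
        xc = (x - x.mean()) / sx
        y = table.mean_removed[ok]
        sy = y.std(axis=0)
        valid = sy > 0
        if not valid.any():
            continue
        yc = (y[:, valid] - y[:, valid].mean(axis=0)) / sy[valid]
        corr[s, valid] = xc @ yc / len(x)
    return CorrelationSurface(taus=ldf.taus.copy(), betas=table.betas.copy(),
                              correlations=corr)
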