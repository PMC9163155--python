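"""Relative, local and global dimension from transient-response peaks.

The relative dimension of node j with respect to a diffusion source i
inverts the d-dimensional Gaussian Green's function through the peak of the
transient response::

    d_ij = -2 ln p̂_ij / ln(4 e π σ t̂_ij)

where (t̂, p̂) are the time and amplitude of the interior maximum of
p_j(t | i).  Inside this formula the peak time is expressed in the
*diffusive units of the random-walk Laplacian*: t̂_hop = t̂_raw / k̄ with k̄
the mean weighted degree.  On a d-dimensional lattice the walk jumps at unit
total rate split over k̄ = 2d neighbours, so its per-coordinate diffusion
constant is 1/k̄, and this choice makes the Gaussian inversion exact (a
500-node line graph yields a plateau at 1.000; an interior 2-D grid yields
2).  The scale axis τ reported everywhere else stays normalized by the
spectral gap λ₂ so that τ = 1 is the stationarity scale.

"No peak" is a first-class outcome: entries of the relative-dimension
matrix are NaN with an explicit ``defined`` mask wherever the transient
response is monotone (typically boundary-shadowed or far nodes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diffusion import (
    DiffusionParams,
    TimeGrid,
    detect_peaks,
    heat_kernel_trajectories,
    make_time_grid,
)
from .graph_core import Graph, normalized_laplacian, source_masses

__all__ = [
    "RelativeDimensionMatrix",
    "LocalDimensionField",
    "GlobalDimensionCurve",
    "relative_dimension_from_peak",
    "relative_dimension_matrix",
    "local_dimension",
    "global_dimension",
    "fractal_dimension_baseline",
]

FOUR_E_PI = 4.0 * np.e * np.pi


def relative_dimension_from_peak(t_hat, p_hat, sigma: float = 1.0):
    """Invert the Gaussian peak relation into a dimension value.

    ``t_hat`` must already be in diffusive (hop-rate) time units.  Returns
    NaN where the log denominator vanishes (t̂ = 1/(4eπσ)) or inputs are
    not positive — undefined is a flag, never an exception.
    """
    t_hat = np.asarray(t_hat, dtype=float)
    p_hat = np.asarray(p_hat, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.log(FOUR_E_PI * sigma * t_hat)
        out = -2.0 * np.log(p_hat) / denom
        out = np.where(
            (t_hat > 0) & (p_hat > 0) & (np.abs(denom) > 1e-12), out, np.nan
        )
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class RelativeDimensionMatrix:
    """N×N relative dimensions d_ij with peak data and a defined mask.

    The diagonal is undefined.  With single-source masses m_i = k̄/k_i the
    matrix is symmetric (the transient response of j seen from i equals
    that of i seen from j up to the common symmetric kernel).
    """

    dimensions: np.ndarray = field(repr=False)
    peak_times: np.ndarray = field(repr=False)  # normalized τ units
    peak_amplitudes: np.ndarray = field(repr=False)
    taus: np.ndarray = field(repr=False)
    spectral_gap: float = 0.0
    mean_degree: float = 0.0
    sigma: float = 1.0
    node_ids: tuple | None = None

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.dimensions)

    @property
    def n_nodes(self) -> int:
        return self.dimensions.shape[0]

    def to_csv(self, path: str | Path) -> None:
        """Dense CSV, NaN for undefined entries."""
        labels = self.node_ids or tuple(range(self.n_nodes))
        pd.DataFrame(self.dimensions, index=labels, columns=labels).to_csv(path)

    def to_long_dataframe(self) -> pd.DataFrame:
        labels = np.asarray(self.node_ids or tuple(range(self.n_nodes)), dtype=object)
        i, j = np.nonzero(self.defined)
        return pd.DataFrame(
            {
                "source": labels[i],
                "target": labels[j],
                "dimension": self.dimensions[i, j],
                "t_hat": self.peak_times[i, j],
            }
        )


def relative_dimension_matrix(
    g: Graph,
    params: DiffusionParams | None = None,
    rel_tol: float = 1e-6,
    refine: bool = True,
) -> RelativeDimensionMatrix:
    """All-pairs relative dimensions from single-source diffusions.

    One eigendecomposition serves every source: with masses m_i = k̄/k_i the
    transient response is p_j(t|i) = k̄ G_ij(t)/√(k_i k_j) where
    G(t) = V e^{-tΛ} Vᵀ is the symmetric spectral kernel, so all N source
    runs are evaluated by streaming G(t) over the grid once, tracking the
    running maximum and its two neighbouring samples per pair.
    """
    params = params or DiffusionParams()
    lap = normalized_laplacian(g)
    grid = make_time_grid(params, lap.spectral_gap)
    n = g.n_nodes
    taus, raw = grid.taus, grid.raw_times
    T = len(taus)
    V = lap.eigenvectors
    lam = lap.eigenvalues
    k = lap.degrees
    pair_scale = lap.mean_degree / np.sqrt(np.outer(k, k))

    best = np.full((n, n), -np.inf)
    best_idx = np.full((n, n), -1, dtype=np.int32)
    left = np.full((n, n), np.nan)
    right = np.full((n, n), np.nan)
    prev = None
    for s in range(T):
        kern = (V * np.exp(-raw[s] * lam)) @ V.T
        upd = kern > best
        if prev is not None:
            left[upd] = prev[upd]
        best[upd] = kern[upd]
        best_idx[upd] = s
        trail = best_idx == s - 1
        right[trail] = kern[trail]
        prev = kern

    interior = (best_idx > 0) & (best_idx < T - 1)
    x = np.log(taus) if params.spacing == "log" else taus
    idx_safe = np.clip(best_idx, 1, T - 2)
    from .diffusion import _refine_parabola

    if refine:
        y0 = np.where(interior, left, np.nan)
        y2 = np.where(interior, right, np.nan)
        x_star, a_star = _refine_parabola(x, y0, best, y2, idx_safe)
        t_hat = np.exp(x_star) if params.spacing == "log" else x_star
        p_hat = a_star * pair_scale
    else:
        t_hat = taus[idx_safe]
        p_hat = best * pair_scale

    stationary = 1.0 / n
    has_peak = interior & (p_hat > (1.0 + rel_tol) * stationary)
    np.fill_diagonal(has_peak, False)

    t_hop = (t_hat / lap.spectral_gap) / lap.mean_degree
    dims = relative_dimension_from_peak(t_hop, p_hat, params.sigma)
    dims = np.where(has_peak, dims, np.nan)
    t_hat = np.where(has_peak, t_hat, np.nan)
    p_hat = np.where(has_peak, p_hat, np.nan)
    return RelativeDimensionMatrix(
        dimensions=dims,
        peak_times=t_hat,
        peak_amplitudes=p_hat,
        taus=taus,
        spectral_gap=lap.spectral_gap,
        mean_degree=lap.mean_degree,
        sigma=params.sigma,
        node_ids=g.node_ids,
    )


def relative_dimension_row(
    g: Graph,
    source,
    params: DiffusionParams | None = None,
    rel_tol: float = 1e-6,
    refine: bool = True,
):
    """Relative dimensions of every node with respect to one source.

    Runs the single-source pipeline (heat kernel → peak detection →
    Gaussian inversion); equivalent to one row of
    :func:`relative_dimension_matrix`.  Returns ``(dimensions, peaks, grid)``.
    """
    params = params or DiffusionParams()
    lap = normalized_laplacian(g)
    grid = make_time_grid(params, lap.spectral_gap)
    m = source_masses(g, [source])
    fieldv = heat_kernel_trajectories(lap, m, grid)
    peaks = detect_peaks(fieldv, rel_tol=rel_tol, refine=refine)
    t_hop = (peaks.t_hat / lap.spectral_gap) / lap.mean_degree
    dims = relative_dimension_from_peak(t_hop, peaks.p_hat, params.sigma)
    dims = np.where(peaks.has_peak, dims, np.nan)
    return dims, peaks, grid


@dataclass(frozen=True)
class LocalDimensionField:
    """Node × scale matrix of local dimensions D_i(τ).

    D_i(τ) averages d_ij over the targets whose transient-response peak
    occurred before scale τ; it is NaN until the first target peaks.  The
    contributing-target count is non-decreasing in τ by construction.
    """

    taus: np.ndarray
    values: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)
    node_ids: tuple | None = None

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def at_scale(self, tau: float) -> np.ndarray:
        """Local dimension of every node at the grid scale nearest to τ."""
        s = int(np.argmin(np.abs(self.taus - tau)))
        return self.values[:, s]

    def to_csv(self, path: str | Path) -> None:
        labels = self.node_ids or tuple(range(self.values.shape[0]))
        pd.DataFrame(self.values, index=pd.Index(labels, name="node"),
                     columns=self.taus).to_csv(path)


def local_dimension(
    rdm: RelativeDimensionMatrix, taus: np.ndarray | None = None
) -> LocalDimensionField:
    """Scale-dependent local dimension D_i(τ) from the peak table.

    ``D_i(τ) = Σ_{j≠i} d_ij·1[t̂_ij < τ] / Σ_{j≠i} 1[t̂_ij < τ]``, NaN where
    the count is zero.  The default scale grid is the diffusion grid itself
    (peaks are only resolved at grid resolution).
    """
    taus = rdm.taus if taus is None else np.asarray(taus, dtype=float)
    n = rdm.n_nodes
    values = np.full((n, len(taus)), np.nan)
    counts = np.zeros((n, len(taus)), dtype=np.int64)
    for i in range(n):
        defined = rdm.defined[i]
        if not defined.any():
            continue
        t_row = rdm.peak_times[i, defined]
        d_row = rdm.dimensions[i, defined]
        order = np.argsort(t_row)
        t_sorted = t_row[order]
        csum = np.concatenate([[0.0], np.cumsum(d_row[order])])
        cnt = np.searchsorted(t_sorted, taus, side="left")
        counts[i] = cnt
        nonzero = cnt > 0
        values[i, nonzero] = csum[cnt[nonzero]] / cnt[nonzero]
    return LocalDimensionField(taus=taus, values=values, counts=counts,
                               node_ids=rdm.node_ids)


@dataclass(frozen=True)
class GlobalDimensionCurve:
    """Per-scale node average of defined local dimensions, 𝔇(τ)."""

    taus: np.ndarray
    values: np.ndarray

    @property
    def argmax_tau(self) -> float:
        if np.all(np.isnan(self.values)):
            return float("nan")
        return float(self.taus[np.nanargmax(self.values)])

    @property
    def max_value(self) -> float:
        if np.all(np.isnan(self.values)):
            return float("nan")
        return float(np.nanmax(self.values))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"tau": self.taus, "global_dimension": self.values}).to_csv(
            path, index=False
        )


def global_dimension(ldf: LocalDimensionField) -> GlobalDimensionCurve:
    """Average the local dimensions over nodes, per scale.

    Only nodes with a defined local dimension at that scale enter the
    average; a scale where no node is defined yields a NaN point.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # empty-slice means NaN
        values = np.nanmean(ldf.values, axis=0)
    return GlobalDimensionCurve(taus=ldf.taus, values=values)


def fractal_dimension_baseline(g: Graph, node, r_max: int) -> float:
    """Volume-scaling (fractal) dimension estimate at one node.

    Least-squares slope of log M(r) against log r for r = 1..r_max, where
    M(r) counts the nodes within r hops.  r_max beyond the node's
    eccentricity is truncated with a warning; degenerate geometries (fewer
    than two usable radii, or zero volume growth) raise ``ValueError``.
    """
    if r_max < 2:
        raise ValueError("r_max must be at least 2")
    from scipy.sparse.csgraph import dijkstra

    i = g.index_of(node)
    hops = dijkstra((g.adjacency != 0).astype(float), directed=False,
                    indices=i, unweighted=True)
    ecc = int(hops[np.isfinite(hops)].max())
    if r_max > ecc:
        warnings.warn(
            f"r_max={r_max} exceeds the eccentricity {ecc} of node {node!r}; truncating",
            stacklevel=2,
        )
        r_max = ecc
    if r_max < 2:
        raise ValueError("fewer than two usable radii: geometry is degenerate")
    r = np.arange(1, r_max + 1)
    m = np.array([(hops <= rr).sum() for rr in r], dtype=float)
    slope = np.polyfit(np.log(r), np.log(m), 1)[0]
    return float(slope)
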