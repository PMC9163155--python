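# diffdim

**Relative, local and global dimension of networks from diffusion dynamics.**

Dimension is well defined in Euclidean space but ambiguous on graphs, where
boundaries, inhomogeneities and discreteness break the assumptions behind
fractal (volume-scaling) estimates. `diffdim` measures dimension *relative to
a diffusion source*: it runs heat diffusion from a node, locates the peak of
the transient response at every other node, and inverts the d-dimensional
Gaussian Green's function to read off a dimension per node pair. The package
is aimed at network scientists and systems biologists who want a
scale-dependent, geometry-aware notion of node centrality and graph
dimension — e.g. to rank epidemic spreaders, probe mesh-like spatial
networks, or fingerprint random-graph ensembles.

## The method

Diffusion on a weighted graph follows ∂ₜ**p** = −L**p** with the random-walk
normalized Laplacian L = K⁻¹(K − A) (A the weighted adjacency, K the diagonal
matrix of weighted degrees k_i), whose continuum limit is Euclidean
diffusion. From a delta initial condition of mass m_i = k̄/k_i at source i,
the transient response of node j is the heat kernel

    p_j(t | i) = (e^{−tL} p(0))_j .

In d dimensions the free Green's function peaks at amplitude
p̂ = (4eπσ t̂)^{−d/2} at the peak time t̂, so each observed peak inverts to a
**relative dimension**

    d_ij = −2 ln p̂_ij / ln(4eπσ t̂_ij) ,

with the peak time expressed in the walk's diffusive units (t̂_raw/k̄; on a
d-dimensional lattice the walk's per-coordinate diffusion constant is
1/k̄ = 1/(2d), which makes the inversion exact). Nodes whose response rises
monotonically to the stationary value 1/N have **no peak** and no defined
dimension — a first-class outcome caused by boundaries and shadowing.
Averaging d_ij over targets that peaked before scale τ gives the **local
dimension** 𝒟ᵢ(τ); its node average is the **global dimension** 𝔇(τ), whose
maximum over scales recovers the Euclidean dimension of lattice-like graphs.
Scales are normalized by the spectral gap λ₂, so τ = 1 is the stationarity
scale. With the degree-inverse mass convention the matrix d is symmetric.

## Worked example

```python
import numpy as np
import diffdim as dd

g = dd.line_graph(500)                      # unit interval, 500 nodes
est = dd.NetworkDimension().fit(g)          # all-sources analysis

row = est.relative_dimension_[165]          # source at position 0.33
near = row[115:216]
print("defined near-source nodes:", np.sum(~np.isnan(near)))
print("median relative dimension:", round(float(np.nanmedian(near)), 3))

grid = dd.grid_graph(25, 20)                # 500-node 2-D lattice
est2 = dd.NetworkDimension().fit(grid)
core = est2.local_dimension_at(0.1)         # short-scale local dimension
print("grid local dimension (interior):", round(float(np.nanmax(core)), 3))
print("max global dimension:", round(est2.global_dimension_.max_value, 3))
```

Output:

```
defined near-source nodes: 86
median relative dimension: 1.0
grid local dimension (interior): 1.967
max global dimension: 1.83
```

The line graph shows the 1-D plateau at 1 near the source (boundary-shadowed
nodes have no peak and are excluded); the grid's boundary-distant nodes read
just under 2 at short scales, and the global-dimension maximum approaches 2
from below at this finite size.

Command-line equivalents: `diffdim generate`, `diffdim relative-dim`,
`diffdim local-dim`, `diffdim global-dim`, `diffdim epidemic-scan`,
`diffdim classify`, `diffdim converge`.

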