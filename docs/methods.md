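# Methods

## Model

`diffdim` treats a connected, undirected, positively weighted graph as a
discretized space and probes its geometry with heat diffusion. The generator
is the random-walk normalized Laplacian L = K⁻¹(K − A): among the common
graph Laplacians it is the one whose continuum limit is isotropic Euclidean
diffusion, which is what licenses reading dimensions off the heat kernel.
All spectral work happens on the similarity-transformed symmetric operator
I − K^{-1/2} A K^{-1/2} (same spectrum), through one dense eigendecomposition
per graph that is reused for every source and every time.

A source i carries initial mass m_i = k̄/(n k_i) (k̄ the mean weighted
degree, n the number of source nodes). This convention has two consequences
that the package tests directly: the stationary state is uniform at 1/N and
sums to one, and the relative-dimension matrix is symmetric.

For each (source, target) pair, the transient response p_j(τ | i) either
passes through an interior maximum (t̂, p̂) or rises monotonically to 1/N.
In d-dimensional free space the corresponding Green's-function peak obeys
p̂ = (4eπσ t̂)^{-d/2}, so an observed peak inverts to

    d_ij = −2 ln p̂ / ln(4eπσ t̂) .

A node without a peak has no defined relative dimension; this is represented
by NaN plus an explicit mask, never by a sentinel value, because "no peak"
carries geometric information (boundary shadowing) that downstream averages
must exclude rather than absorb.

### Time conventions (the one subtle choice)

Two different time units appear, on purpose:

* **Scale axis τ** — all reporting, peak tables, local-dimension scales and
  grids are in times normalized by the spectral gap λ₂, so τ = 1 is the
  relaxation scale of the slowest mode and curves from different graphs are
  comparable.
* **Inside the inversion formula** — the peak time enters in the walk's
  *diffusive units*, t̂_hop = t̂_raw / k̄. A continuous-time walk under L
  jumps at unit total rate split over its neighbours; on a d-dimensional
  lattice (k̄ = 2d) its per-coordinate diffusion constant is exactly 1/k̄.
  With this unit (and σ = 1) the Gaussian inversion is exact on lattices:
  the 500-node line graph plateaus at 1.000 and the interior of a 2-D grid
  reads 1.96–1.97. Using λ₂-normalized times inside the formula instead is
  not a consistent choice — near-source peaks then sit at τ ≪ 1/(4eπ),
  the log denominator flips sign and the line graph reports large negative
  dimensions. σ is kept as an explicit parameter; rescaling it is equivalent
  to rescaling time.

### Numerical choices

* Default grid: 400 log-spaced points on τ ∈ [10⁻³, 5]. The lower bound
  resolves near-source peaks (nodes within ~8 hops of a 500-node line
  graph's source peak below it and are reported peak-less; the plateau
  statistics are insensitive to them), the upper bound leaves a margin above
  stationarity so late peaks stay interior.
* Peak acceptance: interior grid argmax with amplitude above
  (1 + 10⁻⁶) × 1/N. The margin rejects numerically flat trajectories
  without discarding genuinely shallow peaks.
* Peak refinement: parabola through the three grid samples around the
  argmax, in log τ on log grids (switchable). Transient peaks are very flat
  in log time, so refined peak *times* are reproducible to about one grid
  step under grid doubling while amplitudes converge much faster; the
  dimension value depends on t̂ only through its logarithm and is insensitive
  at this resolution.
* The all-pairs matrix streams the symmetric spectral kernel
  G(t) = V e^{-tΛ} Vᵀ over the grid once, tracking each pair's running
  maximum and its two neighbouring samples, so memory stays at a few N×N
  arrays and the cost is one N×N matmul per time point. A per-source path
  (explicit heat-kernel trajectories + peak detection) exists and is tested
  to agree exactly; the streamed path is the same computation reorganized.
* Local dimension D_i(τ) uses the strict indicator t̂ < τ and averages only
  defined entries; the global curve averages only nodes defined at that
  scale (treating undefined as zero would bias small scales downward).
* Degenerate inputs: disconnected graphs are rejected (λ₂ = 0 makes the
  scale normalization meaningless) with the component count in the error;
  self-loops are dropped, duplicate edges summed, directed input
  symmetrized by averaging with a warning.

## Synthetic data

The generators produce the study systems end-to-end; no external data is
required. They emulate: 1-D/2-D bounded and periodic lattices (line, ring,
4-neighbour grid, torus); planar meshes via Delaunay triangulation of the
unit square with inverse-length edge weights, optionally densified by a
Gaussian cluster (variance 0.05) acting as an added mass; and the three
classic random-graph families with node counts drawn from 10 equal bins
(ER edge probability 0.03–0.1, BA edges-per-node 1–20, WS rewiring 0.1–0.7
with 5–10 ring neighbours). What they do **not** emulate: degree-weight
correlations, community structure, spatial embeddings beyond the plane, or
directed flows — so the benchmark results demonstrate correctness of the
machinery on geometrically controlled inputs, not performance on any
particular empirical network class.

## Epidemic experiment

SIR with exponential rates: recovery at γ (fixed to 1, making β the single
control parameter), transmission at β per susceptible contact. Final sizes
are sampled exactly through the percolation representation (per-node
infectious period Exp(γ); each contact transmits iff an independent Exp(β)
clock beats it), which reproduces the event-driven model's final-size law
while only touching explored edges; the bulk scan is JIT-compiled.
Infectiousness of a node is its mean final removed count; β_crit is the
smallest grid rate whose population mean reaches N/2, taken literally
without interpolation (grid resolution is user-controlled).

The benchmark graph is a Watts–Strogatz ring (n = 100, k = 10, rewiring
0.015, fixed realization) scanned over a 15-point linear β grid bracketing
β_crit. Because node infectiousness on this nearly homogeneous graph varies
by only a few percent across nodes, the Monte-Carlo error of the mean must
be small relative to that spread for the correlation with local dimension
to be measured rather than attenuated: at 500 realizations per seed the
split-half reliability of the infectiousness ranking is only ~0.1–0.35,
capping any observable correlation near 0.5. The benchmark therefore uses
8000 realizations per (node, β), chosen to push the estimator's noise well
below the structural node-to-node spread; the structural correlation itself
is what the bound tests. At this precision the scale-maximized Pearson
correlation exceeds 0.8 for every mid-sub-critical β, with the best scale
sitting at short τ (≈ 0.05, the earliest scale at which local dimensions
are defined). The drift of the best scale toward τ = 1 at criticality is
not resolved at this graph size and Monte-Carlo budget and is not asserted
by the tests — a known limitation of the desk-scale study.

## Classification experiment

180 graphs (60 per family, n ∈ [100, 300] in 10 bins) are each summarized
by the mean, standard deviation and adjusted Fisher–Pearson skewness of
their node local-dimension distribution at the largest computed scale
(where the local dimension has stabilized; all-equal values report
skewness 0 by convention). A random forest with fixed hyperparameters
(100 trees, default depth, all features considered at every split — with
only three features, per-split feature subsampling just adds variance) is
scored by stratified 10-fold cross-validation. Feature importance is
reported both as impurity decrease and as permutation importance; the
spread features (std, skewness) dominate the mean, reflecting the broad,
right-skewed dimension distributions that BA hubs induce. At this scale the
accuracy sits near 0.84–0.91 (about 0.88 on average) depending on the
ensemble seed: ER and WS overlap most, as expected from WS interpolating
toward disorder, and the overlap is widest at small n where the ER
mean-degree range (3–30) brackets the WS range (5–10) and sparse ER graphs
are as degree-heterogeneous as WS ones. Separation grows with graph size;
the full-scale study with n up to 1000 and 600 graphs per class is a
long-running variant of the same pipeline
(`diffdim classify --per-class 600 --n-max 1000`).

## Design decisions that were genuinely open

* **Node ordering** is the sorted label order frozen at load, making every
  matrix bit-reproducible across runs.
* **Scale grid for local/global dimension** defaults to the diffusion grid
  itself — peaks are only resolved at grid resolution, so a finer scale
  grid would be cosmetic.
* **Directed graphs** are symmetrized on load (averaged weights) with a
  warning rather than rejected; the dimension theory used here assumes
  reversible diffusion.
* **Feature scale** for classification is the largest computed τ; exposed
  as a parameter since mid-scale features are equally legitimate.
* **Volume-scaling baseline** (log M(r) / log r least squares from r = 1)
  is kept deliberately literal: its downward bias at small radii — a 30×30
  torus interior reads ≈ 1.72 rather than 2 — is part of why the
  peak-inversion estimator exists.

## Known limitations

* Dense eigendecomposition limits graphs to a few thousand nodes.
* Immediate neighbours of a source (peaks below the grid start) and
  boundary-shadowed nodes report no dimension; statistics must tolerate
  missing entries.
* Weighted graphs use the mean weighted degree in the hop-time conversion;
  on strongly heterogeneous weight distributions the lattice calibration is
  only approximate.
* SIR ignores edge weights (transmission rate β per contact); weighted
  transmission would need a per-edge rate convention.
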