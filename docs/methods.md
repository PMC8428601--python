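# Methods

## Model

A transcript profile is the vector of counts of one gene over the capture
locations `S` of a spatial transcriptomics array. `spotdiff` scores each
profile by how long it takes to homogenize under simulated diffusion.
The premise: a profile whose values are arranged into coherent spatial
structure supports long-wavelength gradients that decay slowly, whereas a
random rearrangement of the same values is dominated by short-wavelength
components that decay quickly. The time to reach an (entropy-defined)
steady state therefore orders profiles by spatial organization, with no
distributional assumptions and no significance machinery.

### Grid topology

Locations are partitioned by saturation. A location's neighbors are the
other locations within a Euclidean ball of radius `d_P` (the platform
spacing); a location with the platform-maximal neighbor count
(`M_P` = 4 rectilinear, 6 hexagonal) is *inner* (saturated), all others
are *boundary*. On unstructured platforms (beads at irregular positions)
the ball is replaced by mutualized k-nearest neighbors (default k = 6;
`q ∈ N(s)` iff each is among the other's k nearest), and saturated means
`|N| = k` — a fixed radius would give wildly uneven neighborhoods at
irregular spacing. When `d_P` is not given it is estimated as 1.05× the
minimum positive nearest-neighbor distance; the 5 % tolerance absorbs
coordinate jitter in real position files. Visium array indices are mapped
to a triangular lattice (`x = col/2`, `y = row·√3/2`) so that interior
spots have exactly six neighbors at unit distance. All tie-breaks
(nearest inner point, ranking ties) resolve to the lowest index /
lexicographically smallest name, so every output is deterministic.

### Normalization

Counts are transformed per gene as `u = log2(y + c) / max(log2(y + c))`,
default pseudocount `c = 2`. The log emphasizes relative structure over
absolute level; max-division puts every gene on [0, 1] so diffusion times
are comparable. `c = 2` rather than 1 dampens the artificial gradients of
sparse profiles (isolated nonzero counts surrounded by zeros), which
otherwise converge slowly despite carrying no organized structure. With
`c = 1` an all-zero gene has `max(log2(y+c)) = 0`; such genes are flagged
and must be filtered out before ranking (the engine refuses them).

### Laplacian stencils

* rectilinear: `(u_E + u_W + u_N + u_S − 4u) / h²`
* hexagonal: `(2 / 3h²)(Σ₆ neighbors − 6u)` — the standard second-order
  7-point hex stencil, fixed by exactness on quadratics (it returns
  exactly 4 for `u = x² + y²` at unit spacing, as the 5-point stencil
  does)
* unstructured: `Δu ≈ (4 / h̄_s²) · mean_{q∈N(s)} (u_q − u_s)` with
  `h̄_s` the mean neighbor distance of `s`. The coefficient `2·dim/h̄²`
  (dim = 2) is fixed by requiring agreement with the rectilinear stencil
  on a perfect lattice with k = 4, which also reproduces the hexagonal
  coefficient at k = 6.

`h` is taken as the mean inner-point neighbor distance (the lattice
pitch), not the padded search radius.

### Boundary handling

Two rules are implemented (`DiffusionParams.boundary`):

* **zero-flux** (default): every point, boundary included, relaxes
  through its own (reduced) neighbor set with the same per-edge weights.
  The operator is symmetric and conservative, forward Euler at the
  default dt is positivity-preserving, the field converges to a uniform
  state, and the inner-point entropy increases essentially monotonically
  to `ln |S_i|` — which is what makes the convergence criterion below
  well-posed.
* **nearest-inner**: each boundary point is updated with the Laplacian
  value of its nearest inner point. This rule mirrors boundary values
  after the interior, but the resulting operator is not conservative:
  boundary values integrate Laplacians decoupled from their own
  neighborhoods, the inner-point entropy rises, peaks and then drifts
  toward a non-uniform harmonic limit, and the stopping rule can fire at
  the transient entropy peak. It is kept for comparison and is exercised
  by the oracle-equivalence tests, but it is not recommended for
  ranking: under it the benchmark orderings below degrade measurably
  (the 50 %- vs 90 %-shuffled ablation comparison becomes unreliable).

In both modes the state is clamped at zero after each step (transcript
concentrations are non-negative); with the zero-flux operator at a stable
dt the clamp is a no-op.

### Convergence and ranking

After each synchronous step the Shannon entropy (natural log,
`0·ln 0 = 0`) of the field normalized over the inner points is computed;
the profile has converged at the first step where
`|H(t) − H(t−dt)| < ϵ·|S_i|`. Defaults: `ϵ = 1e−8` per inner point,
`dt = 0.1·h²/(4D)` (one tenth of the forward-Euler stability bound),
`D = 1`, `max_steps = 100000`. Non-converged profiles are reported with
`t_d = max_steps·dt` and a flag; they stay in the ranking (they are
either maximally structured or pathologically sparse) and can be excluded
by the caller. Diffusion times are minmax-normalized across genes and
converted to dense descending ranks (ties share a rank; output ordering
breaks ties by gene name). Genes are independent, so the engine
propagates them as one batched sparse-matrix iteration and distributes
gene chunks over workers with bit-identical results for any worker count.

The optional top-profile selection heuristic sorts normalized diffusion
times descending and takes the genes above the knee of the curve (the
index maximizing perpendicular distance to the chord between the first
and last point, both axes scaled to [0, 1]). It is deliberately
conservative: a flat curve (range < 1e−6) or a collinear descent selects
nothing.

### Pattern families

The `T` top-ranked genes (by diffusion time) are library-size normalized
(each location's counts divided by the location total over all genes;
zero-total locations stay zero), each gene's profile is centered over
locations, and the matrix is decomposed by uncentered PCA (plain SVD).
Row-centering rather than subtraction of the mean gene is deliberate:
genes whose spatial patterns are proportional then project to
proportional loading vectors, so the angle metric groups them exactly
regardless of expression magnitude (and T identical profiles give a
rank-1 decomposition and a single family). The `k` components reaching a
cumulative explained-variance fraction `p` (default 0.8) are kept as
*eigenpatterns*; genes are grouped into `k` families (overridable) by
agglomerative clustering of the loading vectors with cosine distance
`1 − cos θ` and average linkage (both configurable — the exact linkage
used historically for this analysis is not pinned down, so it is
exposed). Family motifs combine the eigenpatterns weighted by the
members' mean loadings.

## Synthetic benchmarks

* **Mixed sets**: for each structured parent `p_i`, include `p_i` and,
  for each multiplier `m_j ∈ {0.5, 1, 2}` and `n_offspring = 3` draws,
  the vector `round(p_i·m_j)` randomly permuted over locations. Ten
  parents give 100 profiles. Multiplied parents are rounded to the
  nearest integer so profiles stay count-like; every offspring is an
  exact multiset rearrangement of its rounded source.
* **Ablation sets**: a single structured profile with `n ∈ {0, 100, 500,
  900}` locations chosen uniformly without replacement and their values
  permuted among themselves — an innate internal ordering of structure.
* **Turing seeds**: a Gray–Scott reaction–diffusion system (`F = 0.0545`,
  `kill = 0.062`, `Du = 0.16`, `Dv = 0.08`, `dt = 1`, 5000 steps,
  spot-forming regime) run on the grid's zero-flux unit-weight graph
  Laplacian from random initial perturbations with a few nucleation
  patches; the activator field is shifted, scaled to a count-like
  amplitude (50) and rounded. Any pattern-forming system serves the
  purpose (structured profiles of stochastic origin); Gray–Scott is the
  choice here.
* **Image seeds**: a binary raster sampled onto the grid bounding box,
  white → high count (default 10), black → low (default 0), optional
  Poisson jitter. `binary_image_bank()` provides ten procedurally
  generated masks (half-planes, disc, ring, bands, blobs) as synthetic
  stand-ins for hand-drawn region images.

What the generators emulate — and what they do not: profiles are
spatially structured versus exactly permuted, with exactly conserved
value multisets and known ground truth. Real data adds library-size
variation across spots, overdispersed counts, partially overlapping
expression domains and tissue-boundary effects, none of which the
generators model. Passing the benchmarks therefore shows the ranker
separates structure from its own absence under controlled conditions; it
does not certify performance on any particular tissue.

## Validation quantities (recomputed by `scripts/acceptance.py`)

* Mixed-set recovery on a 40×40 grid with 10 Turing seeds: the number of
  parents whose diffusion time strictly exceeds every offspring's (ties
  count as failure). The chance probability of a perfect result is the
  exact rational `10!·90!/100! ≈ 5.78e−14`.
* Ablation ordering on a 32×32 (1024-location) grid with the ten image
  seeds and stages 0/100/500/900: the number of sets ranked strictly in
  order of increasing perturbation; chance `(4!)⁻¹⁰ ≈ 1.58e−14`.

Both probabilities are computed in exact big-integer arithmetic
(`fractions.Fraction`). The grid sides (40 and 32) keep each full
benchmark under a few seconds on one CPU while respecting the benchmark
definitions (100 profiles; ≥1000 locations so the literal shuffle stages
fit). The Spearman correlation between diffusion time and per-gene total
counts is available via `rank_expression_correlation` for real datasets;
on synthetic nulls (1000 genes, independent times and totals) its
magnitude stays below 0.1.

## Numerical notes and limitations

* Forward Euler only; no implicit or Crank–Nicolson solver, no GPU path,
  no spatially varying `D`.
* The entropy uses the natural log; the base only rescales `H` and `ϵ`
  jointly.
* `dt` quantizes diffusion times to multiples of itself; ties between
  nearly identical profiles are possible and are surfaced as shared
  ranks.
* Degenerate geometries are handled explicitly: fewer than 2 points and
  all-coincident points are errors; a grid with no saturated point warns
  and every profile converges at the first step.
* 3-D coordinates, multi-resolution grids, functional enrichment of
  families, and H&E image registration are out of scope. Gene filtering
  is a generic threshold/regex filter (defaults: ≥10 locations, total
  ≥20, drop `mt-*`/`Rps*/Rpl*` names); thresholds are configurable and
  deliberately conservative.
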