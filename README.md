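# spotdiff

Rank spatially variable genes in spatial transcriptomics data by
**simulated diffusion time**, and group the top-ranked transcript
profiles into **pattern families**.

## Who this is for

Spatial transcriptomics platforms (ST arrays, 10x Visium, Slide-seq and
other bead-based assays) measure transcript counts at fixed capture
locations across a tissue section. A recurring analysis question is which
genes show *organized* spatial expression — stripes, gradients, islands —
rather than noise. `spotdiff` addresses this without hypothesis testing:
it assigns every gene a physically interpretable score and a rank.

## The idea

Treat the normalized expression profile `u_g` of gene *g* as the initial
condition of the heat equation on the capture grid:

```
∂u/∂t = D Δu
```

and propagate it with explicit forward-Euler steps,

```
u(x, y, t+dt) = u(x, y, t) + D Δu(x, y, t) dt ,
```

where the Laplacian `Δu` is approximated by a topology-specific stencil:
the 5-point stencil on rectilinear arrays, the 7-point stencil
`(2/3h²)(Σ neighbors − 6u)` on hexagonal (Visium) arrays, and a
distance-scaled graph Laplacian over mutual k-nearest neighbors on
unstructured platforms. After each step the Shannon entropy
`H = −Σ û ln û` of the field over the saturated (inner) capture locations
is monitored; the simulation stops when the entropy change per step falls
below `ϵ·|S_i|`. The elapsed simulated time — the **diffusion time
`t_d`** — is the ranking metric: a random spatial arrangement homogenizes
quickly, an organized one persists. Diffusion times are minmax-normalized
across genes and converted to ranks.

Counts enter the simulation after `u = log2(y + c) / max(log2(y + c))`
with pseudocount `c = 2` (robust against sparse profiles). Top-ranked
profiles can then be grouped into pattern families: library-size
normalization, PCA into spatial *eigenpatterns*, and agglomerative
clustering of the gene projections with the angle between loading vectors
as distance.

The package also ships the synthetic benchmark generators used for
validation: *mixed sets* (structured parents plus multiplied-and-shuffled
offspring), *ablation sets* (one profile at increasing degrees of
in-place shuffling), Gray–Scott reaction–diffusion (Turing) seeds and
binary-image seeds — so the entire pipeline is testable without any
download.

## Worked example

Build a 100-profile mixed set (10 Turing-pattern parents, 90 shuffled
offspring) on a 40×40 grid and rank it:

```python
import numpy as np
import spotdiff as sd

grid = sd.build_grid(sd.rectilinear_lattice(40, 40), "rectilinear", spacing=1.0)
rng = np.random.default_rng(0)
seeds = [sd.turing_seed(grid, seed=int(rng.integers(2**31))) for _ in range(10)]
mixed = sd.assemble_mixed(seeds, grid, seed=int(rng.integers(2**31)))

result = sd.rank_by_diffusion(mixed.profiles, grid)
print(sd.result_table(result).head(12).to_string(index=False))
report = sd.parent_recovery(result, mixed.labels)
print("parents on top:", report.n_parents_on_top, "/", report.n_parents)
print("chance probability: %.2e" % float(report.chance_probability))
```

Output:

```
              gene   t_d  t_d_normalized  rank  converged  steps
          parent_2 8.000        1.000000     1       True    320
          parent_7 7.725        0.958175     2       True    309
          parent_1 7.475        0.920152     3       True    299
          parent_0 7.350        0.901141     4       True    294
          parent_8 7.200        0.878327     5       True    288
          parent_9 7.075        0.859316     6       True    283
          parent_4 6.875        0.828897     7       True    275
          parent_6 6.650        0.794677     8       True    266
          parent_3 6.575        0.783270     9       True    263
          parent_5 6.550        0.779468    10       True    262
offspring_2_m0.5_1 2.250        0.125475    11       True     90
offspring_4_m0.5_2 2.050        0.095057    12       True     82
parents on top: 10 / 10
chance probability: 5.78e-14
```

All ten structured parents occupy the top ten ranks, separated from their
shuffled offspring by a wide diffusion-time margin; the probability of
that happening under a random ranking is 10!·90!/100! ≈ 5.78×10⁻¹⁴.

## Command line

```bash
spotdiff simulate --kind mixed --side 40 --n-seeds 10 --seed 1 -o sim/
spotdiff run --input sim/mixed_counts.tsv --transpose -o out/ \
    --min-locations 0 --min-total 0
spotdiff analyze --input sim/mixed_counts.tsv --transpose \
    --results out/diffusion_times.tsv --top 20 -o families/
spotdiff evaluate --counts sim/mixed_counts.tsv \
    --labels sim/mixed_labels.tsv --out report.json
```

`run` accepts ST-style TSV matrices with `XxY` coordinate headers
(`--format st`), Visium-style directories (`--format visium`) and generic
x/y tables (`--format table`).

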