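# spotdec

Cell-type deconvolution of spatial barcoding-based transcriptomics (ST)
with reference scRNA-seq data. Capture spots in ST platforms (Spatial
Transcriptomics arrays, 10x Visium and kin) cover several cells each, so
every measured expression profile is a mixture over unknown cell types.
`spotdec` estimates the per-spot cell-type composition for researchers who
have a genes×spots UMI matrix with spot coordinates plus an annotated
scRNA-seq reference of the same tissue type, and want composition maps
that respect three facts about such data: the reference and the spatial
measurement come from different platforms, only a few cell types are
present in any one spot, and neighboring spots tend to have similar
composition.

## Model

The pipeline has two steps plus an optional imputation stage.

**1. Platform-effect removal.** A conditional variational autoencoder
(CVAE) treats the measuring platform as its condition (scRNA-seq = 0,
ST = 10). Training data are the real ST spots, the reference cells, and
*pseudo-spots* — averages of randomly drawn reference cells (the number of
pseudo-spots defaults to min(100·N·K, 500,000) for N spots and K types) —
so both conditions span a comparable spectrum of mixtures. After training,
an ST profile encoded under the ST condition and decoded under the
scRNA-seq condition is a platform-corrected count vector; the reference is
encoded/decoded under its own condition for denoising.

**2. Regularized Poisson regression.** For spot *i* and gene *j* the
(corrected) count follows

    Y_ij | λ_ij ~ Poisson(N_i · λ_ij)
    log λ_ij = α_i + log( Σ_k θ_ik μ_kj ) + ε_ij

with N_i the spot's total UMI count, μ the K×genes signature matrix of
marker-gene means from the reference, θ_i the composition on the
probability simplex, α_i a spot fixed effect, and ε_ij a zero-mean error
with a heavy-tailed (Cauchy–Gaussian-mixture approximation) density that
is marginalized numerically, making the fit robust to gene-level outliers.
The objective

    Σ_i [ ℓ_i(θ_i, α_i) + λ_r Σ_k q_ik |θ_ik| ] + λ_l · tr(θᵀ L θ)

adds an adaptive LASSO (weights q_ik = reciprocal base-model MLEs) for
within-spot sparsity and a graph-Laplacian penalty (L from the spot
adjacency graph) for spatial smoothness. It is minimized in two ADMM
stages — per-spot cell-type selection (presence cutoff 0.001), then a
joint spatially smoothed fit on the selected supports — with (λ_r, λ_l)
chosen by five-fold gene-wise cross-validation.

**3. Imputation.** Composition and expression at unmeasured locations on a
finer grid come from a one-step nearest-neighbor random walk with a
Gaussian kernel (cutoff φ, bandwidth τ), and X_imputed = θ_imputed θ⁺ X
via the Moore–Penrose pseudoinverse.

The package also ships the evaluation framework used to test all of this:
a coarse-graining simulator that grids single-cell-resolution spatial data
into ground-truthed pseudo-capture-spots, scenario generators (platform
distortion, density scaling, rare types, mismatched references), and
per-spot metrics (RMSE, Jensen–Shannon divergence, Pearson correlation,
per-spot FDR, ARI/purity of dominant-type maps).

## Worked example

```python
import numpy as np
from spotdec import simulation, metrics
from spotdec.pipeline import DeconvConfig, deconvolve

# simulate a small layered tissue and coarse-grain it into capture spots
sc, ref, annot = simulation.make_fixture(n_types=3, n_cells=600, n_genes=80, seed=7)
sim = simulation.coarse_grain(sc, grid_size=100.0)
print(f"{sim.counts.shape[1]} spots, {sim.cells_per_spot.mean():.1f} cells/spot on average")

config = DeconvConfig(no_cvae=True, lambda_r=1.0, lambda_l=10.0, seed=7)
result = deconvolve(sim.counts, sim.coords, sc.counts, sc.labels, config)
print(result.theta.round(3).head())

per_spot = metrics.evaluate(result.theta, sim.truth)
agg = metrics.aggregate(per_spot)
print(f"median RMSE {agg['rmse']['median']:.3f}, "
      f"median JSD {agg['jsd']['median']:.3f}, "
      f"median per-spot FDR {agg['fdr']['median']:.3f}")
```

Output:

```
100 spots, 6.0 cells/spot on average
          type0  type1  type2
spot_0_0  0.680  0.000  0.320
spot_0_1  0.886  0.114  0.000
spot_0_2  1.000  0.000  0.000
spot_0_3  0.420  0.580  0.000
spot_0_4  0.000  0.877  0.123
median RMSE 0.002, median JSD 0.000, median per-spot FDR 0.000
```

Each θ row is a spot's estimated composition (rows sum to 1; exact zeros
come from the sparsity stage). Here the estimates are compared against the
coarse-graining ground truth: a median RMSE of 0.002 over K=3 proportions
means near-exact recovery, and a median per-spot FDR of 0 means no absent
cell type was called present in the typical spot.

The same pipeline is available from the shell:

```bash
spotdec simulate --out data --grid-size 51.5
spotdec run --st data/st_counts.csv --coords data/st_coords.csv \
    --ref data/ref_counts.csv --annot data/ref_annotation.csv --out run1
spotdec evaluate --estimated run1/proportions.csv \
    --truth data/truth_proportions.csv --out eval1
spotdec impute --proportions run1/proportions.csv \
    --coords data/st_coords.csv --resolutions 160,114,80 --out imp1
```

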