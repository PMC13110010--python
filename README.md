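# spicegcn

Spatial inference of cell-cell communication effects from single-cell
spatial transcriptomics, with Gaussian-mixture graph convolutional networks.

## What it does

Imaging-based spatial transcriptomics (MERFISH, Xenium) measures per-cell
gene expression together with cell positions. If a response gene is
regulated by cell-cell communication (CCC), its expression should be partly
predictable from the ligand/receptor expression of *neighboring* cells.
`spicegcn` quantifies that by model selection:

1. Build tissue graphs: cells are nodes; bidirectional edges connect cells
   strictly closer than a neighborhood radius r (µm); each directed edge
   carries polar pseudo-coordinates e_ij = (distance, angle).
2. For each radius r in a sweep, train a graph convolutional network f_r to
   predict all response genes jointly from log1p ligand/receptor expression
   (and optional cell-type annotations). Three hidden layers combine a
   Gaussian-mixture graph convolution with a residual dense transform,

       H⁽ˡ⁺¹⁾ = ReLU( GMMConv(H⁽ˡ⁾) + H⁽ˡ⁾W⁽ˡ⁾ + b⁽ˡ⁾ ),
       GMMConv_i = agg_{j∈N(i)} (1/K) Σ_k w_k(e_ij) Θ_k x_j,
       w_k(e) = exp(−½ (e−μ_k)ᵀ Σ_k⁻¹ (e−μ_k)),

   with K = 10 learnable Gaussian kernels per layer. At r = 0 the graph has
   no edges and the same architecture reduces exactly to a dense network on
   each cell's own features — the spatially ignorant baseline H₀.
3. Estimate the per-gene test MSE σ̂²_{r,g} on held-out tissues and rank
   genes by the loss reduction 100·(σ̂²_{0,g} − σ̂²_{r,g})/σ̂²_{0,g}.
   A one-sided cluster bootstrap on the paired per-cell squared-error
   differences (clustered by tissue, Benjamini–Hochberg corrected across
   genes) guards against reading noise as spatial signal.

Semi-synthetic generators with a planted interaction radius (r* = 30 µm) are
first-class parts of the package, so every claim is testable without any
download. Reference regressors (ridge, lasso, elastic net, LightGBM) on
mean-aggregated neighborhood features are included for comparison.

See `docs/methods.md` for the model, its assumptions, and design choices.

## Worked example

```python
from spicegcn import (SimulationConfig, simulate, preprocess,
                      split_by_group, radius_sweep, rank_genes)

# 20 tissues, planted thresholded-sum signal at r* = 30 µm, gene_1 causal
cfg = SimulationConfig(n_cells=2000, n_slices=20, extent=(100., 100.),
                       model="thresholded_sum", seed=7)
cells, roles = simulate(cfg)
cells = preprocess(cells, roles)                     # log1p on predictors
split = split_by_group(cells, "slice_id", seed=7)    # whole tissues per fold

sweep = radius_sweep(cells, roles, split, radii=[0, 30], model_spec="spice",
                     model_params={"hidden_dim": 32, "max_epochs": 30}, seed=7)
print(sweep.to_frame())
print(rank_genes(sweep, r=30).head(1))
```

Output:

```
         gene  radius       mse
0  response_0     0.0  0.824729
1  response_0    30.0  0.148928
         gene  mse_baseline  mse_informed  loss_reduction_pct  rank
0  response_0      0.824729      0.148928           81.942146     1
```

Reading: at r = 0 the model can only use the cell's own expression, and its
test MSE ≈ 0.82 is the variance of the response — the generator's response
depends exclusively on neighbors, so the spatially ignorant model can do no
better than predict the mean. At the true radius the network recovers most
of the planted neighbor-sum signal (MSE 0.15), an 82% loss reduction, which
is the evidence that this gene is spatially regulated.

The same pipeline is available from the shell:

```bash
spice simulate -o sim/ --model thresholded-sum --n-cells 2000 --n-slices 20 \
      --extent 100x100 --seed 7
spice sweep --cells sim/cells.csv --roles sim/roles.tsv -o out/ \
      --radii 0,30 --model spice --split by-animal --group-key slice_id --seed 7
spice rank --sweep out/ --radius 30 --baseline 0
```

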