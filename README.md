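# gwtgnn

Severity-score regression for Parkinson's disease from tabular
protein–peptide descriptors, using graph-wavelet feature extraction and a
message-passing neural network.

## The problem

Given a table with one row per patient sample and ~30 mixed-type
descriptor columns (peptide/receptor sizes, interface areas, molecular
weights, aromaticity, instability, isoelectric points, cluster flags,
plus identifier and sequence columns), predict continuous disease
severity scores in the style of the MDS-UPDRS Part III motor examination
("motor" score) and the overall scale ("total" score).

The descriptor columns are correlated but arrive in an arbitrary column
order, so a sample's feature vector x̄ ∈ ℝᴺ looks like noise when read
left to right. The core idea of the pipeline is to *recover a smooth
arrangement of the features before extracting frequency-domain features*:

1. **Feature graph.** Build the complete weighted graph G = (V, E, Dis)
   over feature columns, with `Dis[i, j] = ‖x₋,ᵢ − x₋,ⱼ‖₂` the Euclidean
   distance between standardized columns. The diagonal is +∞ when
   searching for the most similar neighbour and −1 when searching for the
   least similar one, so a feature never matches itself.
2. **Greedy similarity paths.** Starting from an extremal feature, walk
   to the nearest unvisited feature until all are visited, giving the
   smoothest permutation `U_min`; walking to the farthest unvisited
   feature gives the most oscillatory permutation `U_max`.
3. **Multilevel wavelet decomposition.** Each sample's vector — in
   original, `U_min`, and `U_max` order — is decomposed with an
   orthonormal discrete wavelet transform (Haar by default, periodic
   boundary, J = 3 levels): cA₁/cD₁ from filter-and-downsample, deeper
   levels recursing on the running approximation. The transformed sample
   is x̄′ = [cD₁, …, cD_J, cA_J] concatenated over the three orderings.
4. **Message passing.** Samples become nodes of a k-nearest-neighbour
   similarity graph (Gaussian edge weights). Each layer updates every
   edge, `g_e = φ_E(ρ_E(g_e, {h_u : u ∈ N(e)}))`, then every node,
   `h_v = φ_V(ρ_V(h_v, {h_u : u ∈ N(v)}))`; a per-node readout
   `ŷ_v = φ_G(ρ_G(h_v, {g_e : e ∋ v}))` yields the score. Training
   minimizes MAE = (1/P) Σ|yᵢ − yᵢ′|; evaluation reports MAE, MSE,
   RMSE = √MSE, and a tolerance accuracy. Test samples receive messages
   but never send them (inductive evaluation).

A five-arm ablation harness (`gwt+gnn`, `gwt+nn`, `gnn`, `dwt+gnn`,
`ft+gnn`) attributes performance to the feature transform and the
network separately, on identical seeded 70/30 splits.

Because no public accession exists for the original descriptor table,
the package ships a synthetic generator whose tables have the same
shape and a *known* latent feature ordering (a Gaussian process on a
latent line, hidden column shuffle, smooth-signal targets plus noise),
so every stage is testable end to end without any download.

## Worked example

```python
import gwtgnn as gw

table, truth = gw.standard_benchmark()        # 600 x 36 frozen table
X, targets, _ = gw.encode_numeric(gw.clean_table(table))
u_min, u_max = gw.min_max_orderings(X)
print(gw.order_recovery_spearman(u_min.permutation, truth, X.feature_names))
# 1.0  -- the greedy min path recovers the hidden feature order exactly

report = gw.run_ablation(table, seeds=(0, 1, 2, 3, 4))   # ~5 min on 1 CPU
print(report.mean_metric("gwt+gnn", "motor_updrs", "mse"))  # 0.16630503418295632
print(report.mean_metric("gnn", "motor_updrs", "mse"))      # 0.17365800447060885
```

The Spearman value says the greedy nearest-neighbour walk sequences the
hidden feature line perfectly despite the shuffle and the nuisance
columns; the MSE pair says the graph-wavelet features beat raw features
for the motor score under the same network and the same splits (scores
are on the generator's standardized target scale; the two closest arms
sit within seed noise of each other, as the per-seed cells in
`report.cells` show).

The same stages are available from the shell:

```sh
gwtgnn simulate --out scratch/toy.csv --samples 200 --features 16 --seed 3
gwtgnn preprocess --data scratch/toy.csv --schema scratch/toy.schema.yaml --out-prefix scratch/prep
gwtgnn transform  --data scratch/toy.csv --schema scratch/toy.schema.yaml --out-prefix scratch/tf
gwtgnn train      --data scratch/toy.csv --schema scratch/toy.schema.yaml --out-prefix scratch/fit --arm gwt+gnn
gwtgnn ablate     --benchmark standard --out-prefix scratch/abl
```

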