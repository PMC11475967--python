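# Methods

## The model

The package predicts continuous disease-severity scores y ∈ ℝ from a
sample × feature table X ∈ ℝ^{M×N} of protein–peptide descriptors. The
pipeline has two learned-free stages (feature ordering, wavelet
decomposition) followed by a learned regressor (message passing on a
sample graph). The premise: descriptor columns are mutually correlated
with an underlying one-dimensional arrangement, but arrive in arbitrary
order; once re-sequenced so that adjacent features are similar, a
sample's feature vector becomes a smooth "signal" whose energy a
discrete wavelet transform compacts into few approximation
coefficients, giving the regressor a better-conditioned input.

### Feature ordering

`Dis[i, j] = ‖x₋,ᵢ − x₋,ⱼ‖₂` over standardized columns defines a
complete weighted graph on features. The diagonal is set to +∞ for the
nearest-neighbour (minimum-distance) search and −1 for the
farthest-neighbour search, so the current feature can never be selected
again. The greedy walk appends, from the current feature, the unvisited
feature at minimum (U_min) or maximum (U_max) distance, until all
features are visited. Ties break to the lowest feature index, making
the walk fully deterministic.

**Start vertex.** A greedy walk from a fixed vertex is fragile: started
mid-way along the features' latent arrangement, it runs to one end and
then teleports back, folding the recovered order in half. The default
therefore runs the walk from *every* start vertex and keeps the path of
smallest total length (min mode) or largest total length (max mode) —
the multi-start approximation to a shortest/longest route through the
feature graph. This costs O(N³) (negligible at N ≈ 30), is
deterministic (ties to the lowest start index), and on benchmark-style
synthetic data recovers the hidden feature order with |Spearman| = 1.0,
where fixed or eccentricity-based starts reach only ≈ 0.5 when
uncorrelated nuisance columns are present. An explicit `start_vertex`
bypasses the scan.

No exact Hamiltonian-path search is attempted (it is NP-hard); the
greedy walk itself is the specified operation.

### Wavelet features

Each sample's vector, in original, U_min and U_max order, is decomposed
with an orthonormal discrete wavelet filter pair (H low-pass, G
high-pass): level 1 filters and dyadically downsamples the vector;
level j recurses on the running approximation cA_{j−1} (standard
pyramid scheme — the textbook multiresolution recursion; detail
coefficients are not re-decomposed). The transformed sample
concatenates [cD₁, …, cD_J, cA_J] per ordering; a block layout records
which columns belong to which (ordering, level).

Defaults and their reasons:

* **Filter family: Haar** (`db4` selectable). Feature "signals" here are
  length ≈ 30; short filters avoid boundary dominance.
* **Depth J = min(3, ⌊log₂ N⌋)**. Three levels already separate smooth
  and oscillatory content at N ≈ 30; deeper levels carry ≤ 4
  coefficients each.
* **Boundary: periodic wrap-around** (`symmetric` selectable). It keeps
  coefficient counts dyadic and the transform exactly orthonormal, so
  reconstruction is exact and Parseval's identity holds — but only when
  the length is even at every level (the implementation pads odd
  lengths by repeating the final sample, which adds that sample's
  energy once). The energy-identity tests therefore use lengths
  divisible by 2^J; reconstruction is exact for every length because
  the padding is truncated on inversion.
* One fixed convolution/downsampling phase convention (that of the
  underlying PyWavelets `periodization` mode) is used everywhere; the
  test oracle implements the same convention directly.

Ablation transforms: `dwt_only_features` (original order only) and
`fourier_features` (magnitude of the non-redundant DFT half) share the
same container so every arm feeds the same network code.

### Sample graph and message passing

Nodes are samples; each connects to its k nearest *training* samples
(Euclidean distance in transformed-feature space), k = 10 by default;
edges between training samples run in both directions, edges into test
samples only point train → test. Test samples therefore never send
messages: fitted parameters and training-node predictions are
unchanged by the presence of test data (inductive evaluation). Edge
features are Gaussian similarities exp(−d²/(2σ²)) with σ defaulting to
the median pairwise training distance.

A layer updates all edges, then all nodes:

    b_e = [g_e^{l−1}, mean of endpoint states]  ; g_e^l = ReLU(W_E b_e + c_E)
    a_v = [h_v^{l−1}, mean of in-neighbour states]; h_v^l = ReLU(W_V a_v + c_V)

with all layer-l updates completed before layer l+1 (the implementation
is vectorized per layer, so this holds by construction). Aggregation is
a mean over the neighbourhood multiset (sum selectable); empty
neighbourhoods aggregate to zero. The readout is per node —
ŷ_v = W_R [h_v^L, mean of incident edge states] + c_R — because the
task needs one score per sample, not one per graph.

Training minimizes MAE over training nodes with adaptive-moment
gradient descent (full batch, lr 10⁻³, 200 epochs, L = 2 layers,
hidden width 32). When at least 20 training samples are available, 15%
are held out for early stopping (patience 20, best parameters
restored); below that the full training set is optimized for the full
epoch budget. All computation is float64 numpy, single-threaded, and
seeded, so loss histories are bitwise reproducible. The network and its
gradients run on a small reverse-mode automatic-differentiation tape
(`_autograd.py`) supporting exactly the required operations.

The feed-forward baseline (`gwt+nn` arm) is the same affine+ReLU stack
without the graph; with zero hidden layers it degenerates to linear
regression fitted by the same optimizer.

### Metrics and the ablation harness

MAE = (1/P) Σ|yᵢ − yᵢ′|, MSE = (1/P) Σ(yᵢ − yᵢ′)², RMSE = √MSE (both
MSE and its square root are always reported), and tolerance accuracy =
100 × fraction of |yᵢ − yᵢ′| ≤ τ. Regression has no native "accuracy
%"; τ defaults to half the training-target standard deviation and is
printed with every report, so the definition is explicit and auditable.

The harness runs five arms — `gwt+gnn`, `gwt+nn`, `gnn` (raw
standardized features), `dwt+gnn`, `ft+gnn` — with, per seed, one
70/30 split (train size = round(0.7·M)) shared by every arm and both
targets. Column standardization, greedy orderings, target scaling and
the kNN bandwidth are all fitted on the training split only and applied
to the test split, avoiding leakage. Targets are z-scored for training
and mapped back before metrics, which are reported on the original
target scale. An arm failure aborts only that (arm, seed) cell, with
the reason logged in the report.

## The synthetic generator

Real protein–peptide descriptor tables with paired severity scores are
not redistributable, so tests run on a generator whose statistical
structure matches what the method exploits, with known ground truth:

* N numeric features are a zero-mean Gaussian process on a latent line:
  cov(fᵢ, fⱼ) = exp(−(pᵢ − pⱼ)²/(2ℓ²)) with unit latent spacing; the
  columns are then hidden-shuffled, so the observable order is
  uninformative and the latent permutation is the recovery target.
* Two targets ("motor", "total") share the smooth latent drivers with
  distinct slowly-varying weight profiles, plus an
  `oscillatory_fraction` share of variance from an alternating-sign
  (high-frequency) functional of the latent field, plus Gaussian noise
  of sd `signal_noise_sd`. With noise and oscillatory fraction at zero,
  targets are exactly linear in the latent field (the identifiability
  check).
* Nuisance columns (categorical labels, peptide-like text), missing
  numeric cells and exact duplicate rows are injected at configurable
  rates; missing cells are punched before duplication so duplicates
  stay exact.

The frozen benchmark is M = 600 samples, N = 30 numeric features
(matching the descriptor schema's size), ℓ = 3, noise sd 0.3,
oscillatory fraction 0.2, 2 categorical + 2 text columns, 1% missing
cells, 1% duplicates, generator seed 20240929. These sizes keep a full
five-arm, five-seed, two-target ablation run to a few minutes on one
CPU while leaving each test split ~178 samples.

What the generator does *not* emulate: mass-spectrometry measurement
physics, peptide binding energetics, realistic UPDRS score
distributions (integer items, floor effects), longitudinal repeated
visits, or feature distributions with heavy tails. Passing tests
demonstrate that the pipeline recovers structure it is designed for
when that structure is present — not clinical performance on real
cohorts.

## Numerical choices and degenerate inputs

* Ties in greedy argmin/argmax and in the multi-start scan break to the
  lowest index; splits use a seeded permutation; all seeds are plain
  integers below 2³¹.
* Zero-variance columns are removed before standardization; a training
  column that is constant within a split standardizes to zero (its sd
  is treated as 1).
* k ≥ n_train clamps to n_train − 1 with a warning; a bandwidth of zero
  (identical training rows) falls back to 1.
* Non-finite activations abort the forward pass naming the layer;
  non-finite losses abort training naming the epoch and learning rate.
* Duplicate rows keep their first occurrence; a missing target value
  always drops its row; missing features are median-imputed by default
  (`drop_row` selectable).

## Known limitations

* The greedy walk approximates, but does not solve, the
  shortest/longest-path ordering; adversarial distance matrices can
  defeat it.
* Energy preservation of the periodic transform requires
  dyadic-friendly lengths (see above); `assemble_features` itself
  accepts any N ≥ 2.
* The kNN sample graph is built in transformed-feature space with a
  single global bandwidth; strongly anisotropic feature blocks would
  warrant per-block scaling.
* Training is full-batch; the implementation targets tables of
  hundreds-to-thousands of samples, not millions.
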