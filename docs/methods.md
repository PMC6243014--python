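# Methods

## Featurization

A peak list is reduced to a fixed-length fingerprint by discarding
retention time, rounding each peak's m/z to an integer and keeping, per
(integer m/z, polarity) cell, only the largest peak area. The grid is
half-open, `[100, 900)` per polarity — 800 integer bins per ionization
mode, 1600 features in total, positive-mode block first. "100–900" is
ambiguous about endpoint inclusivity; the half-open convention is the one
that yields exactly 800 bins and is fixed here. Rounding is
half-away-from-zero (150.5 → 151): banker's rounding would shift ties
between platforms depending on parity. Peaks rounding outside the grid are
dropped and counted, never an error.

Rare classes with fewer than `min_samples_per_class = 20` samples are
pooled into one *negative* class that trains and scores like any other
class (winner-takes-all). The threshold is configurable.

Two scaling conventions coexist deliberately: the Bayesian-network and
subspace paths consume raw areas (binarization and non-negative
factorization are scale-tolerant), while the autoencoder path uses
per-sample max normalization into [0, 1], compatible with sigmoid/ReLU
activations and a Huber loss whose quadratic/linear breakpoint is at 1.
No between-sample (e.g. total-ion-current) normalization is applied; that
is a declared choice, not a reconstruction of any published protocol.

## Synthetic data generator

The generator emulates the statistical structure the classifiers rely on,
not chromatography. Each species owns a set of marker (m/z, polarity)
slots drawn without replacement across the library — so any two species
differ in every marker bin by construction — plus a background peak set
shared by all species. Peak areas are log-normal: mean log-areas are
centered at 11 for markers and 10 for background (natural-log scale, so
median areas around e¹¹ ≈ 6·10⁴ with roughly an order-of-magnitude spread
across compounds, typical of electrospray peak areas), with log-sd 0.4
scaled by `area_cv`. Peaks drop out independently with probability
`dropout`; m/z jitter is uniform within ±0.3 of the bin center, bounded
below 0.5 so binning recovers markers exactly; retention times are uniform
nuisance values. A platform shift models re-acquisition on different
hardware: a global intensity factor, extra dropout, and a smooth
exponential tilt of response across the m/z range.

The default test condition is 10 species × 30 replicates at 10% dropout
(plus 3 rare species × 5 replicates to exercise negative-class pooling).
What passing tests show is that the algorithms recover class structure of
exactly the kind they assume (stable marker sets with multiplicative
noise). Real extracts add correlated compound families, adducts and
isotopes, retention-dependent ion suppression, and between-batch drift,
none of which the generator produces — results on it bound correctness,
not field performance.

## Discrete Bayesian network

Per sample, the ⌈0.3 · n⌉ largest of its n strictly positive peaks are set
to 1 (zeros are absences, not small peaks; the fraction is taken per
sample, not from a dataset-wide ranking). Ties at the cutoff keep the
lower feature index, making masks deterministic.

Structure learning is Chow-Liu: plug-in mutual information (nats, Laplace
pseudocount α = 1 on joint cells) between all pairs of the 1600 binary
variables and the identity variable, then a maximum-weight spanning tree
(Kruskal; equal weights break toward the lexicographically smallest edge).
The tree is rooted at the identity variable, matching its empirical role
as the hub, so scoring a mask is one product per class state — at 59
states × 1600 factors exact evaluation is cheap and no message passing is
needed. CPTs use the same pseudocount. With α = 0 a fully-zero-probability
evidence configuration returns the class prior with a warning rather than
NaNs. The learned structure exports to `.sif` (edge list) and the CPTs to
JSON.

## Autoencoder

Mirrored widths shrinking by factor 4 per encoding layer
(1600 → 400 → 100 → 25 and back), sigmoid on all layers except a final
ReLU, biases in every layer. Training minimizes the summed-per-sample
Huber loss (threshold fixed at 1, exactly the smoothed-l1 form) with Adam
(lr 1e-3, β = 0.9/0.999, batch 32), 200 epochs per stage with early stop
after 20 epochs without improvement. Layer-wise pretraining: the depth-1
model trains first; each deeper model warm-starts all previously learned
encoder and decoder layers and fine-tunes everything end to end (nothing
frozen). The ReLU output layer's biases start at 0.1 so no output unit is
born dead (a zero-gradient trap for ReLU under Glorot-uniform weight
initialization); all other biases start at zero. Epochs, learning rate,
batch size, and initialization are declared defaults — no published values
exist for them — and all randomness (init, shuffling) derives from one
seed, so runs are bitwise reproducible.

The first-layer weight-column norms double as variable-importance scores:
prefix curves (accuracy of l1 logistic regression on the top-k raw
variables) use them for ranking, with the prefix models trained on raw
(unencoded) variables.

## Sparse non-negative Tucker / NMF subspace models

Each class is modeled independently — adding a class never re-estimates
existing ones. For SNTD the class subtensor (samples × 800 × 2) is
factorized with the sample-mode factor pinned to the identity, so the core
G carries per-sample coefficients while B (m/z × 25) and C (polarity × 2)
are shared class descriptors. The objective is the squared Frobenius
residual plus l1 penalties on G, B, C under non-negativity.

The optimizer is exact block-coordinate descent in HALS style: each factor
column's subproblem (non-negative, l1-penalized least squares given all
other columns) has the closed-form solution
`max(0, (numerator − λ/2) / ‖h‖²)`, so every update weakly decreases the
objective — the code asserts non-increase at 1e-9 resolution per sweep and
stops at `n_iter` (200) or relative change < `tol` (1e-6). Initialization
is uniform non-negative random scaled to the data magnitude,
seed-controlled. Penalties default to 0.1 × mean absolute data magnitude
(no published values exist); all-zero factor columns are pruned with a
warning. SNMF applies the same two-block scheme to `X ≈ S Mᵀ` on the
unfolded 1600-feature matrix, rank 25 by default. The identity
`unfold(T) = G₍₁₎(C ⊗ B)ᵀ` ties the two forms together and is asserted to
1e-10.

Classification: a query is reshaped to 800 × 2, multiplied by `C⁻ᵀ`
(pseudoinverse with a warning beyond condition number 1e8), and the
distance from its column space to `span(B)` is computed per class; classes
are ranked ascending, ties broken by class id. Two metrics:

- *Principal angle* (default): chordal aggregation `√Σ sin²θᵢ` over the
  min-rank principal angles. It is evaluated through the projection
  residual `‖(I − P)Q‖_F` of the smaller-rank orthonormal basis rather
  than `√Σ(1 − σᵢ²)` from the cosine SVD: the two are algebraically
  identical, but the cosine form loses half the floating-point digits near
  containment, where this distance must be exactly zero.
- *Distance correlation*: `1 − dCor` between the whitened query and B,
  with rows (m/z bins) as paired observations; the estimator is the
  standard double-centered V-statistic. The operand pairing is a
  convention of this package (no published definition of the operands
  exists); note the V-statistic for independent data decays slowly
  (≈ 0.1 at 800 rows), so the metric never reaches 1 on finite data.
  Degenerate constant inputs define the distance as 1 with a warning.

## Cross-validation and scoring

Stratified 5-fold splits repeated 5 times (25 fitted evaluations), one
fold plan shared by all methods for comparability, class fractions per
fold within one sample of the global fractions. Every feature extractor —
binarization statistics, autoencoder, factor models — refits inside each
training fold; anything else would leak test information through the
representation. Reported values are medians across the 25 runs. Weighted
F1 uses test-split supports; classes with no true or predicted samples get
F1 = 0 with a warning. Top-N accuracy ranks by descending posterior for
probabilistic methods and ascending subspace distance otherwise. Neighbor
tables count, per true class, the labels landing in the Top-N across its
samples. Switching from species to organ identification is purely a label
column selection (`build_dataset(label_by="organ")`); no classifier code
changes.

## Problem sizes

Unit tests use reduced dimensions (40–320 features, ranks 3–5, tens of
samples) chosen so each mathematical property is exercised in well under a
second; the end-to-end recovery check runs the full 1600-feature pipeline
on the 10 × 30 default condition with a fixed 80/20 split. The acceptance
script's quantities are desk-scale by design: the published ~2200-run
dataset lives in external repositories and its headline accuracies are not
recomputable from synthetic data, so they are not asserted anywhere.

## Known limitations

- The generator's independence assumptions (peaks drop out and vary
  independently) make classification easier than on real co-regulated
  metabolomes; accuracy thresholds in tests are meaningful only under the
  stated condition.
- Binarization keeps a per-sample fraction; a dataset-wide abundance
  ranking is a plausible alternative reading and would change masks for
  samples with unusual peak counts.
- The SNTD optimizer guarantees monotone descent, not global optimality;
  planted-factor recovery is verified at λ = 0 where the problem is
  well-posed up to scaling/permutation of the factors.
- `GaussianNB`'s variance floor is applied as an absolute post-fit clamp;
  with very tight clusters the floor (1e-9) dominates and posteriors
  saturate.
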