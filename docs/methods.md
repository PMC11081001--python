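# Methods

This note records the models implemented in `fepfa`, the parameter choices
that matter, what the synthetic data does and does not emulate, and the
numerical decisions taken where the design was genuinely open. It states no
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Problem setting

The pipeline targets four-stage dementia grading from brain MRI. Deep
features extracted from a convolutional backbone arrive as an *N* × 2,048
real matrix; most columns are redundant or noisy, and the scientific task
is to find the subset that supports accurate staging. The package
implements the surrounding stages (augmentation, contrast enhancement,
attention-based extraction, hyperparameter search, metrics) and the core
contribution: a two-stage feature selector — a pathfinder-algorithm
wrapper search followed by fuzzy-entropy refinement (FEcPFA).

## Synthetic study data

`make_gaussian_feature_data(n_per_class, n_classes, d, d_informative,
effect_size, seed)` emulates the post-extraction form of the study data:
balanced classes, a minority of informative columns, independent N(0, 1)
noise elsewhere. Informative columns are assigned round-robin to classes;
the mean vector of class *c* is `effect_size` times the **unit-norm**
indicator pattern over its owned columns. Geometrically the class means
are vertices of a regular simplex of radius `effect_size`, so every class
pair is separated by `effect_size·√2` and difficulty is symmetric. The
unit normalization matters: it spreads the signal across the owned columns
so that each individual column carries only a fraction of it, giving
subset search a real error gradient. (If instead every informative column
were shifted by the full `effect_size`, nearest-neighbor accuracy would
saturate at 1.0 even with all noise columns included, and the wrapper cost
would degenerate to a pure feature-count penalty whose optimum is the
*smallest* accurate subset — feature recovery would be meaningless.)

The default study conditions used throughout the tests are 4 classes × 50
samples, d = 200, 20 informative columns, effect size 3, generator seed 1.
At these settings a 5-NN classifier on a stratified 50:50 split reaches
≈ 0.95 accuracy on the informative columns alone, ≈ 0.65 on all 200
columns, and chance (0.25) on the noise columns — an informative-but-
diluted regime.

What the generator does **not** emulate: spatial structure, inter-feature
correlation (real CNN activations are strongly correlated), heavy tails,
or class imbalance. Passing recovery tests therefore demonstrate that the
selector finds axis-aligned independent signal, not that it handles
correlated redundancy.

`make_phantom_image` produces a centered disc or square with a corner
marker pixel; the marker breaks all dihedral symmetry so flips and
rotations are detectable. The phantom is noise-free, hence seed-independent.

## Preprocessing

Augmentation uses only lossless pixel permutations — horizontal/vertical
flips and 90°-multiple counterclockwise rotations — so the intensity
histogram is exactly preserved; `augment_to_count` pads a class to a
target count (e.g. a 64-image minority class to 3,200) by a seeded random
choice of source image and operator, always retaining the originals. The
operator mix per class is a free choice; a uniform random mix is used.

Enhancement is a fixed two-stage chain. First a Laplacian-pyramid detail
remap: a 3-level pyramid (Gaussian blur σ = 1, 2× decimation, bilinear
expand), band-pass coefficients with |c| < `sigma` (default 0.1) scaled by
`alpha` (default 2), then exact pyramid collapse and clipping to [0, 1].
Because synthesis uses the same expand operator as analysis, `alpha = 1`
reconstructs the input to float precision. This is a deterministic
simplification of edge-aware local Laplacian filtering — it boosts
small-amplitude detail without the full O(N log N) machinery, whose
parameters are not specified for this pipeline anyway. Color images are
taken to YUV and only luma is remapped. Second, a combined morphological
step `clip(I + tophat(I) − bottomhat(I), 0, 1)` with a disc structuring
element (default radius 5 px, unspecified upstream and exposed as
configuration): the white top-hat lifts small bright structures, the black
bottom-hat suppresses small dark ones; constant images are fixed points.

## Self-attention head and backbone

The head follows the standard query/key/value algebra: P = X Yᵀ with X, Y
∈ R^{T×T}, row softmax SM(P)ᵢⱼ = e^{Pᵢⱼ}/Σⱼ e^{Pᵢⱼ} computed with per-row
max subtraction (the bare form overflows for |P| ≳ 700), and AM = SM(P) V
with V ∈ R^{T×J}. A flattened input vector is projected by Wq, Wk, Wv into
X, Y, V; the attended map flattens to a `feature_dim`-length vector.
T defaults to 32 and J = feature_dim / T, so the default head emits 2,048
features. The three projections are user-supplied or drawn once from a
seeded N(0, 1/input_dim); the head is exercised untrained — its role in
this artifact is wiring and shape fidelity, not learned representation.

`build_resnet_self` assembles the full extraction network in forward-only
NumPy: 7×7/2 stem, 3×3/2 max pool, bottleneck stages [3, 4, 6, 3] with 1×1
reduce/expand convolutions and projection skips (stride 2 at each stage
entry), global average pooling to 2,048 channels, then the attention head.
Convolutions are im2col matrix products in float32; normalization layers
standardize with batch statistics (the network is untrained, so there are
no running averages — a forward pass is still deterministic for fixed seed
and input). Weights are He-initialized. A 2-image 224×224×3 batch runs in
a few seconds on one CPU. Training, transfer weights, and reproduction of
trained-feature values are out of scope.

## Pathfinder wrapper selection

Positions live in [0, 1]^d, one coordinate per feature; `binarize`
thresholds at 0.5 (strict), with an argmax fallback so masks are never
empty. Fitness is the weighted wrapper cost

    cost = φ_α · (1 − accuracy) + φ_β · n_selected / d,
    φ_α = 0.94, φ_β = 0.014,

with accuracy from a 5-NN classifier on a seeded stratified 50:50
holdout (5-fold CV available). The split is fixed per run so fitness is a
deterministic function of the mask.

Swarm dynamics per iteration k (of k_max):

- leader: x ← x + 2 r₃ ⊙ (x − x_prev) + u₂ e^{−2k/k_max}, r₃ ~ U[0,1]^d,
  u₂ ~ U[−1,1]^d. The fluctuation term A is not operationally defined in
  the source description; the standard exponentially decaying form is
  used.
- followers: x_i ← x_i + αr₁ ⊙ (x_j − x_i) + βr₂ ⊙ (x_p − x_i) + ε with a
  seeded random neighbor j, α, β ~ U[1,2] per iteration, and vibration
  ε = (1 − k/k_max) · u₁ ⊙ |x_i − x_j| (componentwise distance). The
  attraction terms use the difference form x_j − x_i; the additive form
  sometimes printed for this update is non-contractive and contradicts
  the follower behavior it is meant to describe.
- all positions clipped to [0, 1]; a member keeps its move only if it
  lowers its cost (greedy acceptance, as in the canonical algorithm); the
  leader is re-elected as the current minimum-cost member (roles can
  swap); an elitist best-so-far record is kept, so the best-cost history
  is non-increasing.

Numerical choice worth stating: the vibration amplitude uses the
componentwise distance |x_i − x_j| rather than the scalar Euclidean norm
‖x_i − x_j‖. In d = 200 the norm between two random box points is ≈ √(d/6)
≈ 5.8 box widths, so a scalar-norm vibration drowns both attraction terms
for most of the run and the swarm cannot contract; the componentwise form
is bounded by the box width per coordinate and preserves the intended
decaying-perturbation role. Measured on the default recovery problem, the
componentwise form roughly halves the best cost reached and lifts planted-
feature recall from 0.70–0.85 to 0.80–0.90 across five optimizer seeds.

At the default study conditions (swarm 20, 30 iterations ⇒ 620 fitness
evaluations) a run takes ≈ 2 s on one CPU.

## Fuzzy-entropy refinement

Each feature surviving the wrapper search is scored independently.
One-dimensional fuzzy C-means with one cluster per class alternates the
center update C_j = Σ μ_ij^e u_i / Σ μ_ij^e and the membership update
μ_ij = 1/Σ_m (D_ij/D_im)^{2/(e−1)} until max |Δμ| < tol (1e−5) or 300
iterations; fuzziness e = 2 (the printed exponents e and g are taken as
one coefficient, as in standard FCM); points coinciding with a center get
full membership there; a constant feature is returned flagged degenerate
rather than raised. The alternating scheme never increases the objective
Σ μ^e D², which the tests assert per iteration.

The feature score uses the **class degree of membership**: for cluster j,
λ_{c|j} is the fraction of the cluster's fuzzy mass contributed by class
c, and

    Fe = Σ_j (mass_j / Σ mass) · ( −Σ_c λ_{c|j} ln λ_{c|j} ) ∈ [0, ln C].

Fe ≈ 0 when every cluster is dominated by one class (the feature's axis
separates the classes); Fe ≈ ln C when cluster membership is unrelated to
the labels; degenerate features score ln C by convention. An alternative
label-free summary (entropy of the mean membership profile) was evaluated
and rejected: on the default study data it does not separate informative
from noise features at all (mean crispness 0.8351 vs 0.8334), whereas the
class-degree score ranks all 20 planted features within the top third.
Natural log throughout; base configurable for reporting.

`refine_selection` keeps the ⌈ρ · n_selected⌉ lowest-Fe features
(crispness — mean max-membership — descending as tie-break), never
returning an empty mask. The default ρ = 1467/2048 mirrors the reported
2,048 → 1,467 reduction of the original pipeline; whether that number came
from a threshold or a rank cut is not stated upstream, so ρ is plain
configuration.

## Bayesian hyperparameter search

`run_bo` minimizes an arbitrary callable over a named box; the default box
is the published training ranges (L2 1e−10–1e−2 and learning rate
1e−4–1 in log₁₀ space, momentum 0.7–0.98, integer section depth 1–3 by
continuous relaxation + rounding). Five Latin-hypercube seeds initialize a
Matérn 5/2 Gaussian process (unit-cube coordinates, standardized targets);
each round maximizes expected improvement over a fresh 2,048-point
quasi-random candidate set. Stopping is max_evals or a wall-clock budget
(default 54,000 s, the published limit; tests always pass seconds-scale
budgets). NaN objectives are recorded as +inf and excluded from the
surrogate. The true upstream objective — validation error of a trained
network — is GPU-scale and not run here; the shipped demo objective is the
analytic quadratic (log₁₀ lr + 2)², minimized at lr = 0.01.

## Metrics

All metrics are computed from the confusion matrix: accuracy = trace/total;
per-class precision/recall with 0/0 := 0, macro-averaged; macro F1 as the
mean of per-class harmonic means; Cohen's κ = (p_o − p_e)/(1 − p_e); and
the multiclass (Gorodkin) MCC
(c·s − Σ t_k p_k)/√((s² − Σ p_k²)(s² − Σ t_k²)). Macro averaging is a
documented choice (the upstream description never states its averaging),
as is the Gorodkin form for four-class MCC. κ is reported as 0 when
p_e = 1 and MCC as 0 when its denominator vanishes, with a degeneracy
flag. scikit-learn's implementations serve as an independent oracle in the
tests, never as the implementation. Final-stage classifiers (KNN, RBF-SVM,
one-hidden-layer MLP standing in for the named neural-network presets) are
deliberately off-the-shelf; the bespoke content lives upstream in the
selector.

## Problem sizes and determinism

Test and demonstration problem sizes are chosen for single-CPU
verification: recovery experiments at 200 samples × 200 features,
refinement counts at d = 2,048 with small N, optimizer checks at 25
evaluations × 20 seeds, and 2-image forward passes through the backbone.
Every stochastic component takes an explicit seed (`numpy.random.
default_rng`; no global state), and end-to-end reruns with the same
configuration are bit-identical, which the pipeline tests assert.

## Known limitations

- The backbone is untrained; its features verify wiring and shape, not
  representation quality. Reported headline accuracies of the original
  study (≥ 99.9%) require its private trained model and image corpus and
  are out of scope here.
- Per-feature (univariate) fuzzy-entropy scoring cannot credit features
  that are informative only jointly; multivariate FCM is deliberately out
  of scope.
- The wrapper search is stochastic; at the default budget its recall of
  planted features is 0.8–0.9, not 1.0, and like any wrapper it inherits
  the variance of its internal classifier split.
- The two mutually inconsistent "best" hyperparameter sets quoted in the
  source material are data-dependent training artifacts; neither is a
  target of this package.
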