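# Methods

This note documents the model implemented by `frbain`, the choices made
where the design was genuinely open, and what the synthetic test substrate
does and does not establish.

## Model

The classifier operates on multichannel time-varying records
`X ∈ R^{n×T}` (record lengths may differ). Its pipeline is

```
X ── DTW distances to kernel centers ── fuzzy RBF memberships ── simplex
normalisation ── per-class pooling ── product-rule layer (K^K rules) ──
simplex normalisation ── affine map + softmax ── class probabilities
```

**Distance.** Dynamic time warping with the Euclidean frame metric across
channels, symmetric step pattern {(1,0),(0,1),(1,1)}, no slope constraint
and no band by default. The distance is the plain minimum cumulative frame
distance (no path-length normalisation); an optional normalised variant
(divide by path length) and an optional Sakoe–Chiba band are exposed
because kernel widths otherwise scale with record length and because the
band bounds runtime on long records. Backtracking breaks ties toward the
diagonal step, which fixes a unique reported path without affecting the
distance. The Euclidean frame metric satisfies identity of indiscernibles,
so `d(X,Y) = 0` iff the records are equal, and symmetry of the step
pattern makes the distance symmetric.

**Membership function.** Each fuzzy radial basis neuron stores one kernel
center `Z_j` (a verbatim training record) and emits

```
μ_j(X) = clip( sigmoid(a_j − d²(X, Z_j)/σ_j²) − c_j , 0, 1 )
```

`σ_j > 0` is a smoothing width in distance units, initialised to the
median DTW distance from center `j` to the other centers (1.0 when there is
no other center) so every neuron starts sensitive at the scale of its
neighbourhood; `a_j` (init 1.0) shifts the sigmoid and `c_j ∈ [0, 1)`
(init 0) is a cutoff subtracted before clamping, which can zero out weak
memberships entirely. The exact sign grouping of the printed formula in
this literature is ambiguous; the adopted form is the unique reading that
is a decreasing sigmoid-shaped radial kernel maximal at the center, clamped
to a valid membership.

**Inference layers.** Memberships are normalised jointly over all `m`
neurons onto the simplex (per-class normalisation variants make the
downstream conservation property inexact). Pattern pooling sums (default)
or maximises the normalised memberships over each class's neurons. Rules
are all `K`-tuples over the `K` pattern nodes in lexicographic order with
product t-norm firing strength; with sum pooling the firing strengths sum
to `(Σ_k q_k)^K = 1` exactly, so the second normalisation is a numerical
no-op but is kept for the max-pooling path. The head maps the `L = K^K`
activation intensities affinely to `K` scores and applies softmax. A
single-output variant with an undefined multiclass decoding was rejected in
favour of the standard softmax head; ties at the argmax go to the earlier
class in the stored class order. The rule layer is capped at 10^6 nodes
(`K ≤ 7`); beyond that the architecture is refused rather than silently
truncated.

## Kernel-center selection (DTW + dynamic fuzzy clustering)

Averaging warped series is ill-defined, so clustering runs in relational
(medoid) form on the pairwise DTW matrix: memberships
`u_ij = 1/Σ_h (d(i,j)/d(h,j))^{2/(f−1)}` given medoids (fuzzifier
`f = 2.0`; crisp assignment on zero distance), medoids re-chosen per
cluster as the sample minimising the fuzzy-weighted distance sum, kept
distinct greedily. Alternating optimisation is monotone but prone to local
optima on relational data, so each restart refines its start and its
converged set by PAM-style greedy single-medoid swaps scored with
memberships optimal for the candidate set; problems with at most 2000
candidate medoid sets are solved by exact enumeration instead. Five
seeded restarts (first: farthest-point spread; rest: random) are the
default.

**Cluster-count selection.** The validity index `GD(c) = α·Cd(c) +
(1−α)/Sd(c)` combines the coupling degree `Cd` (fuzzy-weighted mean
distance to medoids, divided by N) with the separation degree `Sd`
(minimum inter-medoid distance); the scanned count with minimal GD wins,
ties toward the smaller count. `Cd` carries distance units and `1/Sd`
inverse ones, so the sum is only meaningful on a dimensionless scale: the
scan rescales the distance matrix by its mean off-diagonal entry (the
clustering itself depends only on distance ratios and is unchanged). The
coupling weight defaults to `α = 0.8`, calibrated by structure recovery on
generator data with known subclass counts: the separation term's role is
to veto over-segmentation — `Sd` collapses by an order of magnitude as
soon as the scan exceeds the true count — while the compactness term
discriminates under-segmentation, and recovery held for any `α` in roughly
(0.6, 0.99) on the calibration sweep. `Sd` is undefined for a single
cluster; forced single-cluster banks bypass the scan. Classes smaller than
the requested range are clamped; a one-record class contributes its lone
record as a center with a warning.

## Training

Trainable parameters: `(σ, a, c)` per neuron and the head `(W, r)`. The
kernel centers are frozen, so all record-to-center DTW distances are
computed once and every epoch works on the cached table; no gradients flow
through DTW. The loss is mean categorical cross-entropy (natural log,
probabilities clipped at 1e-12) paired with the softmax head; gradients
are fully analytic (the product-rule layer uses the multiplicity form
`∂z_t/∂q_k = n_tk q_k^{n_tk−1} Π_{k'≠k} q_{k'}^{n_tk'}`) and verified
against central finite differences to ~1e-10 relative. The clamp in the
membership function uses a zero subgradient outside its interior.

Defaults: Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8), initial learning rate
0.5 divided by 10 every 50 epochs (so 0.5 / 0.05 / 0.005 at epochs
0/50/100), at most 500 epochs, 50 mini-batches per epoch (ragged last
batches tolerated; seeded shuffling), stop when the epoch mean loss falls
below 0.005. Plain SGD is available via `optimizer="sgd"`, and a slower
flat regime (e.g. rate 0.25, tolerance 0.05, 3000 epochs) is reachable
purely through `TrainingConfig`.

**Constraint projections.** After every optimiser step, `σ` is floored at
1e-6 and `c` clipped to [0, 1). Two further projections keep the problem
well-posed, because the clamped membership region has a *zero* subgradient
and is therefore absorbing — a large adaptive step that strands a neuron
there would leave no restoring force:

* *kernel liveness*: each neuron's membership at its own center,
  `sigmoid(a_j) − c_j`, may not fall below 0.05 (first `c_j` is pulled
  down; if the sigmoid itself has saturated, `a_j` is raised to the
  boundary). Without this, whole class groups of neurons die early in
  training under the aggressive initial rate and the classifier collapses
  to chance with no way back.
* *record feasibility*: every training record must retain at least one
  positive membership; otherwise the cutoff of its best-matching neuron is
  lowered just enough. At prediction time a record with all-zero
  memberships is still reported as unclassifiable rather than silently
  assigned.

**Metrics.** One-vs-rest precision, recall and F1 per class, macro
averages, accuracy, and the K×K confusion matrix; zero-support or
zero-predicted classes score 0 with a warning rather than an error.

## Synthetic generator

The generator emulates the target regime — small, possibly imbalanced
record collections in which each class contains several shape modes — not
any particular physiological morphology. Templates are sums of three
seeded random-phase sinusoids per channel (amplitudes U[0.5, 1.5],
frequencies U[1, 4] cycles) plus a class-specific baseline offset;
records are drawn by a random monotone time warp (duplicate/delete up to
`warp_strength` of the timepoints, identical across channels, since
physiological channels share a time base) followed by i.i.d. Gaussian
noise. A separation contract is enforced with bounded retries: the minimum
inter-template DTW distance must exceed `template_separation` (default 4)
times a Monte-Carlo estimate of the intra-template perturbation scale.
Class counts come from largest-remainder rounding of the requested
proportions (exact total, deterministic); subclass templates are used
round-robin within a class. Defaults describe a modest three-class
problem: 2 subclasses per class, 3 channels, 64 timepoints, 10% warping,
noise at 10% of unit template amplitude, 300 records — separable but not
trivial.

What passing tests show, and what they do not: recovery of subclass counts
and ≥0.95 held-out accuracy on this substrate demonstrate that the
pipeline's stages compose correctly and that the model can exploit
well-separated subclass structure under warping and noise. Real
physiological data have overlapping classes, baseline drift, artefacts and
label noise that the generator deliberately omits, so these results bound
implementation correctness, not clinical performance.

## Numerical choices and degenerate inputs

* DTW inner loop compiled with numba (pure-Python fallback); frame
  distances via `scipy.spatial.distance.cdist`.
* Fuzzy-clustering convergence: objective decrease < 1e-6, ≤ 200
  iterations; validity ties broken toward the smaller count (parsimony);
  degenerate separation (duplicate medoids) scores GD = +∞.
* Cross-entropy probability clip 1e-12; softmax computed shift-stable.
* Model archives store all scalars in JSON (floats round-trip exactly) and
  bank records at 17 significant digits, so reloaded models reproduce
  forward passes bitwise.
* Seeds: every stochastic operation takes an explicit seed; scans derive
  per-count seeds deterministically; nothing is time-seeded.

## Known limitations

* Training requires sum pooling (max pooling is available for inference
  only; its subgradient routing is not implemented).
* The pairwise DTW stage is quadratic in the number of records and
  dominates pipeline runtime; no lower-bounding accelerations are
  implemented.
* The non-extended rule wiring (one rule node per subclass combination,
  exponential in the bank size) is not assembled; only the `K^K`
  pattern-layer architecture is.
* First-order (input-dependent) T-S consequents are out of scope; the head
  is zeroth-order affine.
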