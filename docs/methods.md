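# Methods

## Objective and discretization

The package maximizes the between-class variance J(T) of the normalized
gray-level histogram over k real thresholds in [1, L−1] (L = 256 for
8-bit input). The histogram is discrete, so J is evaluated on the floors
of the thresholds: any real threshold strictly between two integer bins
induces the identical partition, which makes flooring exact rather than
approximate. Class i covers bins (⌊t_{i−1}⌋, ⌊t_i⌋]; class 1 starts at
bin 0 and class k+1 ends at L−1. After sorting, thresholds whose floors
coincide leave an empty class that contributes exactly 0 to J (the
agent's continuous position is left untouched). Empty classes get a mean
of 0 purely to avoid 0/0; the term is skipped.

Evaluation uses cumulative tables of p_j, j·p_j and j²·p_j, so a
k-threshold evaluation costs O(k) lookups after an O(L) precomputation,
and whole populations are scored as one vectorized batch. The detailed
scalar path (`otsu_objective`) also returns the within-class variance
computed independently from the j² table, so the variance decomposition
J + within = total is a real cross-check, not an identity by
construction.

### Plateau-canonical threshold bins

J is piecewise-constant, and over zero-probability bins it forms exact
plateaus: sliding a threshold left across empty bins changes no pixel's
class. Wherever a single integer representative of a found partition is
needed (reports, recovery comparisons), each threshold is mapped to the
smallest bin with the same cumulative probability — the left edge of its
plateau. The exhaustive oracle breaks ties by the lexicographically
smallest vector, so oracle and optimizer share one deterministic
convention and "did the optimizer find the optimal partition?" has a
well-defined answer even when the optimum is a wide plateau (as it
always is between well-separated histogram modes).

## The hybrid optimizer

Phase split: T_SCSO = ⌊λ·T_max⌋ exploration iterations, then
T_WOA = T_max − T_SCSO exploitation iterations. Defaults follow the
standard protocol: N = 30 agents, T_max = 100, λ = 0.6 (60/40 split).

**SCSO phase** (default "equation" mode): each agent flips a fair coin
between the directional-hunting move X ← X + r₁X* − r₂X and the
difference-attraction move X ← X + r₃(X* − X), with r₁, r₂, r₃ ~ U(0,1)
drawn per agent (scalar coefficients applied to all coordinates). The
selection rule between the two moves is not uniquely pinned down by
their usual presentation; a per-agent fair coin is the simplest
symmetric reading and is the package's choice. An alternative
"mean_attraction" mode implements the other circulating form,
X ← X + r₁(μ − X) + r₂(X* − X) with μ the population mean; both are
selectable so the discrepancy is exposed rather than silently resolved.
An orientation angle θ_i is advanced each iteration by
α·sin(ω t + φ) (defaults α = 1, ω = 0.2 rad/iter, φ = 0). No standard
coupling of θ to the position update exists, so by default θ is tracked
and logged only; with `scso_theta_enabled` the attraction draw r₃ is
modulated by |sin θ_i| as a documented extension.

**Handoff**: the exploration best seeds one agent of a freshly
randomized WOA population; the remaining N−1 agents are new uniform
draws. The carried-over best also initializes the incumbent, so the
best-so-far trace cannot regress across the phase boundary.

**WOA phase** (default "canonical" mode): per agent, a coin p ~ U(0,1)
selects the spiral move (p ≥ 0.5): X ← |X* − X|·e^{bl}·cos(2πl) + X*
with l ~ U(−1,1) and spiral constant b = 1; otherwise the A-branch with
A = 2a·r − a, C = 2r′ (scalar per agent): encircling
X ← X* − A·|C·X* − X| when |A| < 1, else search around a uniformly
chosen random agent. The coefficient decays linearly across the phase,
a = a₀(1 − t/T_WOA) with a₀ = 2, reaching 0 at the phase end. A
"pseudocode" mode drops the spiral and branches on |A| alone with a
single shared r, matching the plainest loop formulation; the canonical
mode is the default because it is standard WOA.

**Shared contracts.** Best updates on strict improvement only (ties keep
the incumbent — determinism). Positions are hard-clamped to [1, L−1]
after every move; non-finite excursions clamp, NaN fitness raises. One
`numpy` Generator per run, seeded from the config, drives every draw;
`log_draws=True` records all draws per iteration so a test can replay a
step by hand. Evaluation budget: N at initialization plus N per
iteration = N·(T_max + 1) exactly, for the hybrid and every baseline.
The WOA-phase re-seeding costs no extra evaluations because the fresh
agents move before they are ever scored (the carried best provides the
attractor). The one exception is the degenerate λ = 0 split, where the
exploration phase collapses to a single random best-solution draw
(budget 1 + N·T_max); this follows the literal degenerate-phase
handling and is asserted as its own contract.

**Baselines.** PSO (w = 0.5, c₁ = c₂ = 2, zero initial velocities,
per-dimension uniform draws, personal/global bests), GWO (three leaders,
a: 2 → 0 linear, per-dimension draws, update = mean of the three
leader-attraction terms), standalone WOA (canonical branch structure,
a: 2 → 0 over T_max), and standalone SCSO (the exploration dynamics run
for all T_max iterations). SCSO is sometimes described with an
additional externally scheduled sensitivity parameter; the standalone
baseline here deliberately uses the same two-move dynamics as the
hybrid's first phase so that the ablation isolates the phase-switching
mechanism itself.

## Preprocessing and reconstruction

RGB inputs are converted to luminance (0.299 R + 0.587 G + 0.114 B),
resized to 256×256 by bilinear interpolation, rescaled to [0,1] and
quantized back to 0..255 with round-half-to-even. A pixel of value v
gets label i when ⌊t_i⌋ < v ≤ ⌊t_{i+1}⌋ (labels non-decreasing in
intensity). For metric computation each class is replaced by its mean
intensity from the image's own histogram — the paper-standard
"segmented image" for thresholding evaluation and the unique rule that
makes reconstruction MSE equal the within-class variance, hence PSNR a
monotone transform of the Otsu criterion (asserted numerically in the
tests). Means are rounded half-to-even to 8 bits for the written image;
the unrounded means are kept on the result object. Empty classes take
their bin-range midpoint. Binarizing a multilevel result for overlap
metrics requires choosing which classes are foreground; that mapping is
an explicit argument (`mask_from_labels`), not a hidden convention.

## Metrics

* **PSNR** = 10·log₁₀(255²/MSE), capped at 100 dB for identical images
  so tables stay finite.
* **SSIM**: mean local SSIM with an 11×11 Gaussian window (σ = 1.5,
  truncated at 3.5σ), K₁ = 0.01, K₂ = 0.03, dynamic range 255,
  population covariances, border of one filter radius excluded from the
  mean. Implemented directly from the definition; the test suite checks
  agreement with scikit-image's implementation to 1e−6.
* **FSIM**: S(x) = S_PC(x)·S_G(x) pooled with weight max(PC₁, PC₂),
  with T₁ = 0.85 on the phase-congruency term and T₂ = 160 on the
  gradient term (Scharr 3×3, /16 normalization). Phase congruency uses a
  log-Gabor bank (4 scales, 4 orientations, minimum wavelength 6,
  scale multiplier 2, σ_onf = 0.55) with Rayleigh noise compensation
  (k = 2) and sigmoidal frequency-spread weighting. No reference FSIM
  implementation ships in the dependency set, so correctness is
  established by properties: identity = 1, symmetry, range, monotone
  degradation under increasing distortion, and closed-form degenerate
  cases. For a featureless pair (both phase-congruency maps identically
  zero, e.g. two constant images) the documented fallback is the
  unweighted mean of S, which is 1.0 for identical inputs.
* **Overlap**: Dice 2|A∩B|/(|A|+|B|), Jaccard |A∩B|/|A∪B|, symmetric
  Hausdorff distance between foreground pixel sets (SciPy's directed
  Hausdorff both ways). Two empty masks are defined as identical
  (1, 1, 0); with exactly one empty mask Dice/Jaccard are 0 and the
  Hausdorff distance is an error unless explicitly disabled.
* **Correlations**: Pearson and Spearman (average ranks for ties)
  between the flattened original and segmented images; neighbor
  variants over horizontally adjacent pixel pairs of the segmented
  image (vertical pairs pooled in on request — the neighborhood
  definition is a documented default, since single-scalar "neighbor
  correlation" reports never specify one). Constant inputs yield NaN
  with a warning rather than an arbitrary number.

## Synthetic fixtures

The generator emulates what matters about histopathology histograms at
desk scale: multimodal intensity mixtures (nuclei / cytoplasm /
background-like modes) with known generating parameters. Pixels draw a
component from the mixture weights, then an intensity from the
component's normal truncated to [0, 255] **by rejection** — clipping
would pile mass into spurious spikes at 0/255 and corrupt the
analytic-density comparisons the tests rely on. The fixed suite
(256×256, one derived seed per fixture):

| fixture  | structure                                   | role |
|----------|---------------------------------------------|------|
| bimodal  | modes (60, 10, 0.5), (180, 10, 0.5)         | threshold recovery |
| trimodal | (50, 12, 0.35), (120, 15, 0.35), (200, 10, 0.30) | general optimization |
| fivemode | five modes, 30..220, sd 8–12, equal weights | high-k stress |
| blob     | disks at 60 on background 200, noise sd 5, exact mask | overlap metrics |
| twopoint | half 50 / half 200                          | closed-form objective (J* = 5625) |
| constant | all 128                                     | degenerate-input handling |

The written suite carries a manifest with generating parameters, image
checksums and brute-force optima (k = 1, 2). What these fixtures do not
emulate: spatial texture, stain-color covariation, resolution artifacts
— passing tests demonstrate correct optimization and measurement on
histograms of realistic shape, not segmentation quality on real tissue.

## Problem sizes and numerical choices

The exhaustive oracle enumerates integer combinations (cap 10⁶,
vectorized in chunks); oracle-vs-optimizer comparisons use k ≤ 2 at
L = 256 and k ≤ 4 after rebinning to L = 32, where enumeration is
thousands of combinations. Validation runs use the full study protocol
(N = 30, T_max = 100) with 10 seeds per condition; the ablation
stability property (hybrid's across-seed std of J at k ∈ {10, 12} not
exceeding standalone SCSO's or WOA's) is evaluated as the mean of
per-(fixture, k) standard deviations across the suite, since with 10
seeds the per-cell estimate is itself noisy. Sample standard deviations
(n−1) throughout. Benchmark tables report both pooled and
per-image-first aggregation, and wall-clock time is reported but never
asserted.

## Known limitations

* The SCSO exploration phase implements the two-move dynamics as
  published for the hybrid; it is not a re-implementation of the
  original SCSO paper's full roulette-wheel angle machinery.
* FSIM is validated by properties and degenerate closed forms, not
  against an external implementation.
* The phase-congruency noise threshold is estimated per orientation
  from the smallest-scale filter response; on very small images
  (< 32 px) the estimate is unreliable, so FSIM rejects them.
* Hausdorff distance is the exact maximum (no percentile variant).
* Thresholding is single-channel by design; no stain deconvolution.
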