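# Methods

## The estimation problem

A wrist-and-finger wearable with small (8×8 mm) dry electrodes measures
upper-body impedance at 50 kHz. Two obstacles separate that raw reading from
a percent-body-fat (PBF) estimate:

1. **Contact settling.** The narrow skin contact adds a large parasitic RC,
   so the reading drifts toward its stabilized value over tens of seconds.
   The device samples for only five seconds (five samples at 1 s intervals),
   and the settled value must be extrapolated from the initial transient.
2. **Information deficit.** The wrist–finger path excludes the lower body and
   includes a large index-finger impedance (≈585 ± 103 Ω), so the classical
   cylinder model PBF ∝ f(H²/R50) cannot be applied directly. The pipeline
   instead *estimates* the whole-body cylinder index H²/R50 from upper-body
   impedance plus anthropometrics, then maps features to PBF with either
   linear regression or a small feed-forward network.

## Settling-value extrapolation

A first-order contact transient is modelled as

    y(t) = b + c·exp(−a·t),

with settled impedance `b` (Ω), signed amplitude `c` (Ω) and decay rate `a`
(1/s, the reciprocal of the parasitic RC time constant). Consecutive-sample
differences Δᵢ = yᵢ − yᵢ₊₁ cancel `b`; on a pure exponential each ratio
Δᵢ/Δᵢ₊₁ equals exp(a·δ) independent of amplitude, where δ is the sampling
interval. The estimator regresses ln|Δᵢ| on tᵢ by ordinary least squares: the
slope gives −a, the intercept gives ln|c·(1 − e^(−aδ))|, and `b` follows as
the mean of y − c·e^(−at). On noise-free exponentials this inversion is exact
to floating-point precision and matches a 3-parameter nonlinear least-squares
fit to ≈1e−11 Ω.

A decision cascade guards the estimator:

1. last gap ≤ 5 Ω → the series is treated as already settled (last sample
   returned). The 5 Ω gate is the device's stability criterion between the
   4 s and 5 s samples; it deliberately trades ≤5 Ω-scale residual transient
   for robustness, so the exactness property above is stated for the
   extrapolation path itself.
2. zero or sign-changing deltas → no single exponential fits; last sample
   returned (the field protocol would re-measure).
3. all delta ratios inside [0.95, 1.05] → the transient is indistinguishable
   from linear drift; extrapolating a near-zero decay rate would amplify
   noise, so the last sample is returned.
4. otherwise → log-linear extrapolation. A non-positive fitted decay rate
   (growing deltas, possible under noise) also falls back to the last sample.

Feasibility screening precedes everything: a series that increases at every
step has not begun to converge, and a final value outside 500–2000 Ω
indicates poor contact; both earn a re-measurement flag and the subject is
excluded from downstream fitting.

Under 2 Ω Gaussian sample noise, the extrapolated estimate halves the median
error of the naive last-sample readout (the acceptance script measures both
medians); this is the mechanism by which calibration improves agreement with
reference impedance.

## Feature sets and models

Feature identifiers: height (cm), age (yr), gender (female = 1, male = 0 —
chosen so the published positive gender coefficient aligns with the higher
female PBF), weight (kg), calibrated upper-body impedance R50_prop (Ω),
H²/Imp = height²/R50_prop, H²/R50 (reference or estimated cylinder index,
cm²/Ω), hip and waist circumference (cm), waist/hip ratio.

* **H²/R50 estimation ("Network 1")** — inputs are upper-body only. Variants:
  an OLS regression on (H, A, G, W, R50_prop), and networks with the same
  five inputs (Model I), plus H²/Imp (Model II), plus waist/hip (Model III,
  7 inputs, 3 hidden layers × 128 ReLU nodes).
* **PBF estimation ("Network 2")** — conventional features
  (H, A, G, W, H²/R50) or proposed features adding hip, waist and waist/hip
  (8 inputs, 3 hidden layers × 256 ReLU nodes). Four regimes are compared:
  linear/network × conventional/proposed. Network regimes consume the
  Model III H²/R50 estimate; linear regimes consume the regression estimate,
  keeping each chain's methodology uniform and upper-body-only at inference.
  PBF predictions are clipped to [0, 60] % as a physiologic guard.

OLS fitting and coefficient t-tests (p-values with n − p − 1 degrees of
freedom) are delegated to statsmodels. Exactly rank-deficient designs (e.g. a
single-gender cohort making the gender column constant) are rejected;
near-collinear anthropometric designs (waist, hip and their ratio) are
legitimate and fitted as given.

## Network training

The networks are implemented directly on numpy: ReLU stacks with He
initialization, Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8, learning rate 1e−3 —
the standard Adam default; no rate is part of the printed recipe), MSE loss,
at most 2000 epochs. Choices the recipe leaves open were fixed as follows,
with units and rationale:

* **Minibatch size 8, seeded shuffling per epoch.** Full-batch training at
  cohort scale (~130 rows) takes too few, too-smooth steps: validation loss
  bottoms within ~40 epochs at a badly underfit state. Small minibatches add
  the gradient noise that regularizes and explores.
* **Input *and* target standardization** by training-set mean/sd (inverted at
  prediction). Feature scales span Ω (~1200) to ratios (~0.8); targets span
  ~3–50 %. Without target standardization Adam at 1e−3 cannot traverse the
  output bias in the epoch budget.
* **Early stopping: patience 100 epochs, restore best-validation weights.**
  Training is stopped when a held-out split has not improved for 100 epochs.
  `train_mlp` holds out a 10 % validation fraction.
* **Cross-validation ensembling.** At n ≈ 143 a single 10 % holdout (≈14
  rows) makes early stopping close to random model selection, and a single
  wide network is a high-variance estimator. The pipeline therefore trains a
  5-fold cross-validation ensemble: each member early-stops on its own
  disjoint fold (so every row trains 4 of 5 members) and predictions average
  the members. This is the package's variance control; it preserves the
  printed per-network recipe (architecture, optimizer, loss, early stopping)
  and is deterministic given the seed.

Training is bit-reproducible: the spec seed drives the validation/fold
splits, initialization and shuffling, and there are no other entropy sources.
A NaN loss raises a divergence error naming the epoch.

## Evaluation protocol

Cohorts are split into 143 training and 20 test subjects (10 male, 10
female) by a seeded shuffle. Metrics on the test set: Pearson r, r², and the
standard error of estimate SEE = √(Σ(ref − pred)²/(n − 2)) in PBF percentage
points — the n − 2 convention of the body-composition validation literature;
an explicit degrees-of-freedom argument allows n − p − 1. All regimes in a
comparison consume identical splits and identical calibrated impedances.

## The synthetic cohort generator

No measurement data accompany the study design, so the generator emulates its
population and measurement structure:

* **Anthropometrics**: 12 sport/gender groups with the published means, SDs
  and head counts (102 M + 61 F = 163). Draws are normal, truncated at ±3 sd
  and clipped to physiologic bounds; weight, waist and hip share a latent
  factor giving 0.6 pairwise correlation.
* **Ground-truth PBF**:
  `clip(pbf_mean_g + 0.8·(BMI − 24) + k·25·(whr − whr_mean_g)³ + ε, 3, 50)`,
  a within-group BMI slope plus a cubic waist-to-hip term plus noise
  ε ~ N(0, 1.5²). The cubic term is the *designed* nonlinearity that
  separates network from linear regression. Its scale (k = 58, giving the
  term ≈3.1 PBF points of spread) and the noise sd were calibrated once from
  the study's reported error decomposition: a linear SEE near 4 and a network
  SEE near 2.9 imply ≈√(4² − 2.5²) ≈ 3.1 points of linear-inaccessible but
  learnable structure over ≈2.5 points of irreducible spread (generator noise
  plus the group-level intercepts that no observed feature encodes).
* **Impedance**: reference whole-body R50 = 1.167·H²/FFM·(1 + η),
  η ~ N(0, 0.03²), the cylinder relation with FFM = weight·(1 − PBF/100);
  the constant puts a 175 cm / 65 kg-FFM subject near 550 Ω, inside the valid
  screening range. The upper-body transient settles at 1.10·R50 + finger,
  finger ~ N(585.06, 102.67²) Ω, with per-subject decay rate ~ U[0.2, 1.2]
  and amplitude ~ U[50, 400] Ω, and 2 Ω sample noise.

What the generator does **not** emulate: real electrode physics (motion
artifacts, posture, skin hydration), multifrequency impedance, reference
device error, and any anthropometry–impedance dependence beyond the cylinder
relation. Group membership is intentionally unobservable, leaving a floor of
irreducible between-group variance. Passing tests therefore demonstrate that
the pipeline's machinery is correct and that its qualitative model ordering
holds under the stated generative assumptions — not that the printed
real-data accuracies transfer.

## Numerical and degenerate-input choices

* Delta sign convention is earlier-minus-later, so decay from above yields
  positive deltas and positive amplitude.
* A zero delta in a ratio denominator raises a degenerate-delta signal in the
  standalone operation; inside the cascade such series take the fallback
  path with NaN diagnostic ratios of the defined length.
* Fewer than 3 usable deltas on the extrapolation path raise an
  insufficient-samples error (5 samples give 4).
* CSV floats are written with 9 significant digits; repeated runs are
  byte-identical.
* Series constructors validate length ≥ 3, positivity, finiteness and
  uniform spacing to 1e−9 s.

## Known limitations

* The network-vs-linear advantage on synthetic cohorts is modest and
  seed-dependent at n = 163 with 20-subject test sets: the paired median
  r² gain is ≈+0.04 and the paired median SEE reduction ≈+0.5 points over
  ten cohorts, but individual cohorts exist where the linear model wins —
  a wide network remains a higher-variance estimator than OLS when the
  nonlinear payoff in a small test sample is low.
* The H²/R50 stage's network variant beats its regression variant on most
  but not all cohorts, mirroring the same variance trade-off.
* The generator's PBF rule is one stated nonlinear mechanism; real
  anthropometry–adiposity relationships are richer, so model rankings here
  are illustrative of the method contrast, not of clinical performance.
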