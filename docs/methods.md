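# Methods

This note records the modelling assumptions, the parameter defaults and the
numerical/design choices behind the package, and what the synthetic test
beds do and do not demonstrate.

## Kernel Extreme Learning Machine

The classifier is kernel ridge regression onto one-hot class targets: with
Ω the RBF Gram matrix of the training set, the coefficient matrix solves
(Ω + I/C)·B = T, and a query is scored by its kernel row against the
training points.  Conventions and numerics:

- **Regularization is I/C**, so larger C means weaker shrinkage and tighter
  interpolation of the targets.  As C → ∞ on distinct points the training
  scores converge to T (asserted to 1e−6 at C = 1e12 in the tests).
- **RBF parameterization** is exp(−‖x−y‖²/2γ²); γ is a length scale in the
  units of the features.  The alternative exp(−γ‖x−y‖²) convention is not
  used anywhere.
- **One-hot coding is 1/0** rather than ±1; under argmax decoding the two
  are affinely equivalent, and 1/0 keeps the coefficient matrix directly
  interpretable as class-membership scores.
- The system matrix is symmetric positive definite for any C > 0 (Ω is
  PSD), so the solve uses a Cholesky factorization with a least-squares
  fallback reserved for numerically singular Gram matrices at extreme γ.
- Ties in the argmax go to the lowest class index in sorted-label order,
  making predictions deterministic.
- Defaults C = 32, γ = 0.5 match the configuration used for the fused
  classifier; both are also searchable (below).

A linear-kernel mode exists so that the dual solve can be checked against
the explicit primal ridge solution (X'X + I/C)⁻¹X'T; the two agree to
1e−8 on random instances up to N = 50.

## GA, GWO and G-GWO

All optimizers minimize; maximization problems pass a negated objective.

- **GWO update.**  Per leader ℓ ∈ {α, β, δ}: Y_ℓ = |Q_ℓ∘M_ℓ − M|,
  candidate M_ℓ − N_ℓ∘Y_ℓ, with fresh N ∈ [−a, a] and Q ∈ [0, 2] drawn per
  leader, per wolf, per iteration; the new position is the mean of the
  three candidates.  The absolute value in the distance follows the
  canonical formulation of the encircling step.
- **Control schedule** a = 2(1 − t/T), linear from 2 (exploration) to 0
  (pure exploitation).
- **Leaders are best-ever** (elitist): the board keeps the three best
  positions over the whole run, not of the current generation, so the
  best-so-far history is non-increasing by construction.
- **Bounds** are enforced by clamping each coordinate after the update.
- **Evaluation accounting is exact**: pop·(T+1) for GWO, plus
  pop·(generations+1) for the GA phase of G-GWO.  The equal-budget
  comparison below relies on this.
- **GA seeding**: 16 bits per gene decoded affinely onto the search box,
  rank-based roulette weights (best rank P … worst 1) to avoid
  negative/zero-sum fitness pathologies on minimization problems,
  crossover rate 0.8, mutation rate 0.01, single-member elitism,
  10 generations by default.
- Defaults population 8, 200 iterations.

**Known limitation.**  On 5-D Rastrigin over 30 paired seeds at exactly
equal evaluation budgets (plain GWO receives 11 extra iterations to offset
the GA phase's 88 evaluations), the GA-seeded run's median final fitness
was *worse* than plain GWO's (≈3.3 vs ≈2.2).  The seeding comparison is
therefore treated as a soft, reported property — the test suite asserts
the budget accounting exactly and emits a warning when the median ordering
is violated — rather than a guaranteed improvement.

## Wrapper feature selection and tuning

- The search space is the box [−1, 2]^N; a position coordinate above a
  fresh uniform draw selects its feature, so coordinates ≥ 1 always select
  and ≤ 0 never do.  The asymmetric box biases the swarm toward inclusion,
  which keeps early packs away from the empty mask.
- Fitness α·P + (1−α)·(N−L)/N with α = 0.99.  P is **validation accuracy**
  on a stratified holdout (train fraction 0.7; the split seed is separate
  from the optimizer seed so splits are stable across a seed sweep); a
  configuration switch substitutes macro one-vs-rest precision for P.
- An all-zero mask is assigned a sentinel worst fitness instead of raising,
  so a wandering pack can recover mid-run.
- Hyperparameters are searched as (log₂C, log₂γ) over C ∈ [2⁻⁵, 2¹⁵],
  γ ∈ [2⁻¹⁰, 2⁵]: the log scale makes the usual multiplicative grid a
  linear box compatible with GWO's arithmetic updates.  Joint mode appends
  the two coordinates to the N feature coordinates.
- `svd_reduce` projects onto the top right-singular directions of the
  column-centered matrix and stores the means with the components, so the
  identical affine projection applies to new data.

**A non-property worth knowing.**  Adding an exact duplicate column can
change — even raise — the optimal fitness: the parsimony term is
normalized by the table's total feature count, and an *included* duplicate
doubles that feature's weight inside the RBF distance.  What does hold,
and is tested, is that subsets excluding the duplicate score identically
on pure accuracy and that the enlarged space cannot lower the
pure-accuracy optimum.

## Architecture search

The encoder-decoder hyperparameter vector has 22 named fields in fixed
order (conv blocks 1–2, pool 1, dropout 1, conv blocks 3–4, pool 2,
dropout 2, upsample 1, transposed-conv blocks 1–2, upsample 2,
transposed-conv blocks 3–4).  Decoding rounds-and-clamps counts to
[20, 200], snaps sizes to the nearest allowed value ({3,5} or {2,3}, exact
ties to the smaller), and clamps dropout to [0.2, 0.4]; decode∘encode is
the identity on valid configurations and decode is idempotent.

- **ε is fixed per run** (default 1.0) rather than redrawn randomly: a
  stochastic smoothing constant would randomize the objective itself,
  which is pathological for any optimizer comparison.  ε only matters for
  empty-mask stability; the ε → 0 limit recovers the classical Jaccard
  coefficient.
- The topology is fixed at 4 conv / 4 transposed-conv layers, which is
  what the 22-element encoding presumes; variable layer counts are out of
  scope.

**The surrogate evaluator** stands in for training the actual network so
the search loop is testable in seconds.  It is deterministic: for a task
with hidden optimum hp\*, a fraction d²/4 of each truth mask is removed
and an equal number of background pixels added, where d is the normalized
encoded-space distance from hp\* (d = 1 at the far corner of the box).
The quadratic decay gives the response surface the usual flat-near-optimum
shape, and the 1/4 scale sets the half-width so a single flipped discrete
choice (which alone contributes ≈0.21 to d) costs about one Jaccard point
instead of collapsing the score; with this construction, 50-iteration
searches reach within 0.05 of the optimal fitness in ≥ 90% of seeds.
Passing against the surrogate demonstrates that the encoding, fitness and
search loop are wired correctly — it says nothing about segmentation
quality of real trained networks, which is explicitly out of scope.

## Imaging pipeline

- Preprocessing order: bilinear resize → median filter (3×3) → CLAHE
  (clip 2.0, 8×8 tiles, per channel).  The target size is configurable
  (the pipeline default is 256×256); resizing is skipped when shapes
  already match, so the identity configuration is exact.
- The catalogue holds exactly 30 operations: sharpen and emboss at levels
  0.5/1/1.5/2, Gaussian blur at scales 0.25/0.5/1/2, rotation at
  45/90/135/180°, edge enhancement at 0.25/0.5/0.75/1.0, skew
  left/right/forward/backward, flips on four sides, and shear at 10° along
  each axis.  Intensity levels are blend weights between the identity
  image and the unit-strength filtered image (level 2 over-drives and
  clips); skew magnitudes borrow the shear's stated 10°.
- Rotations by multiples of 90° use exact array rotation where the canvas
  permits, so double-180° and four-fold-90° identities hold bit-exactly;
  other angles interpolate with reflection padding on the same canvas.
- Sevenfold expansion: each source image contributes itself plus six
  catalogue operations sampled without replacement, per image, seeded — so
  2055 sources yield exactly 14,385 images and per-class counts scale by
  exactly 7.
- Split accounting: test = ⌊0.3·count⌋ by default; explicit per-class test
  overrides reproduce a published split exactly.  Note the published
  per-class test counts sum to 4,315 while the printed total says 4,316;
  the per-class values are treated as authoritative.

## Metrics

All seven statistics (ACC, SEN, SPC, PRE, MCC, ER, F1) are computed on the
fraction scale; percent is a formatting concern.  A zero denominator marks
the metric as missing (`None`) rather than 0, and macro averages are taken
over the classes where the metric is defined — silently zeroing undefined
precision would deflate macro scores on imbalanced reports.

The error rate has two modes because the two published conventions
conflict: `complement_accuracy` (ER = 1 − ACC, the default — it matches
reported headline rows such as ACC 0.986 / ER 0.014) and `balanced`
(ER = 1 − (SEN + SPC)/2).  Neither convention reproduces every published
row (e.g. one baseline row pairs ACC 88.5% with ER 0.112); the discrepancy
is documented here rather than resolved.

## Synthetic data

- **Feature tables**: class centers are distinct equal-magnitude sign
  patterns (the antipodal pair for two classes) scaled so the minimum
  pairwise center distance is `class_sep`, with unit within-class noise —
  so *every* informative column carries signal, which is what makes
  recovery scoring meaningful.  Noise columns are standard normal.  The
  recovery experiment uses n = 200, 5 informative + 15 noise,
  class_sep = 3.5 (Bayes accuracy ≈ 0.96), generator seed 42.
- **Segmentation tasks**: truth masks are unions of random disks
  (guaranteed nonempty); images are two-level intensity (0.15/0.85) plus
  smooth texture (amplitude 0.1) and optional pixel noise, so at zero
  noise a 0.5 threshold recovers the truth exactly.
- What these do **not** emulate: anatomical structure (optic disc,
  vessels), inter-feature correlation of real CNN embeddings, label noise,
  or class imbalance (available as a parameter but not default).  Passing
  tests demonstrate correctness of the algorithms under known ground
  truth, not clinical performance.

## Problem sizes

The test suite and the acceptance script run every experiment at desk
scale: 30-seed medians for the selection and recovery experiments
(n ≤ 200, ≤ 20 features, 40–60 optimizer iterations), 20–30 seeds for the
optimizer benchmarks at the default population 8 / 200 iterations, and
10-seed success rates for the 50-iteration surrogate architecture search.
These sizes were chosen so the full suite completes in about half a minute
while keeping the medians stable across reruns.
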