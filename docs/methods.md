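# Methods

This note documents the models implemented in `coastniche`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
landscape does and does not emulate.

## Synthetic coastal landscape

The generator stands in for the GIS stack a coastal niche-modelling study
assembles (bioclimatic layers, harmonized soil attributes, elevation,
a sea-level-rise surface), co-registered on a grid of 1-km square cells.

* **Fields.** Each continuous layer is Gaussian-smoothed white noise
  (correlation length in cells, default 5) mapped through the normal CDF
  into a plausible physical range (e.g. mean diurnal range 4–16 °C, topsoil
  pH 4.5–9). Smoothing-then-rescaling is the simplest controllable
  generator of spatially autocorrelated fields; length 0 gives i.i.d.
  values. Categorical soil layers (drainage class, soil unit) are
  quantile-binned smoothed fields with 4 levels coded 1..4.
* **Coast.** Elevation is a linear ramp from 0 m at the seaward column to
  `elevation_max` (default 10 m) at the landward edge, plus smoothed noise
  (default sd 1 m). Cells below 0 m are sea, carried as a nodata mask
  rather than a value; sea-level rise subtracts from elevation and grows
  the mask (inundation = loss of land, and the mask can only grow).
* **Scenarios.** Climate change adds configured offsets (optionally scales)
  to climate layers only; sea-level rise changes elevation and the mask
  only; the combined scenario applies both. Because the two operations act
  on disjoint layers they commute, which the tests exercise.
* **Truth.** The planted suitability is a cloglog of a linear predictor
  over z-scored layers, by default +6·z(Bio02) − 6·z(Elevation) − 14. The
  strength was set so that suitable habitat (suitability > 0.5) covers
  roughly 5% of land cells: an intertidal fringe species occupies a narrow
  band of a 50-km coastal buffer, and this prevalence makes the planted
  signal cleanly separable (the truth's own best-achievable AUC is ≈ 0.96)
  without being a single-cell needle. Presences are drawn with probability
  proportional to suitability, i.e. sampling effort is assumed unbiased.

What the generator does **not** emulate: real coastline geometry and
projections, correlated climate–soil gradients (layers are generated
independently), dispersal limitation, observation bias in occurrence data,
and spatial heterogeneity of sea-level rise. Tests that pass on this
landscape therefore demonstrate the estimators and the plumbing, not the
ecology of any particular coast.

## Occurrences

Thinning keeps the first record per thinning cell (deterministic and
idempotent); the cell size is a parameter defaulting to one raster cell.
Region splitting is a y-threshold in v1, ties assigned to the northern
side. Point-to-cell mapping uses half-open cells `[edge, edge+cell)` with
row 0 at the grid origin corner, so results are bit-stable. Records on sea
cells or outside the grid are dropped with a logged count.

## Maximum-entropy model

The implementation follows the standard presence–background MaxEnt
formulation: a Gibbs distribution over the training background with an L1
penalty per feature, fitted by minimizing the convex objective

    f(λ) = −(1/m) Σ_presences λ·f(x_i) + log Z_bg(λ) + Σ_j β_j |λ_j|.

* **Features.** Linear and quadratic transforms are min–max scaled to
  [0,1] on the training background (the quadratic is the square of the
  scaled linear); hinge features use `n_hinge_knots` (default 50) evenly
  spaced interior knots per direction per layer; categorical layers get one
  indicator per observed level regardless of the feature-class string.
  Constant layers are skipped with a warning. On projection, features are
  clamped to [0,1] — the standard behaviour when transferring to novel
  conditions.
* **Penalties.** β_j = rm·√(s²_j/m) with s²_j the feature variance over the
  presences and m the presence count (floored at s² = 10⁻⁴ to keep β
  positive for near-constant features). This is a deliberate simplification
  of the version-dependent interpolation tables of the reference
  implementation; the regularization multiplier `rm` scales all penalties
  and is tuned by AICc anyway.
* **Optimizer.** L-BFGS-B on the split λ = u − v, u,v ≥ 0, which makes the
  L1 term smooth under bound constraints. The contract is the objective
  value (tested against a brute-force grid oracle), not the algorithm.
  `convergence` (default 10⁻⁵) is the relative objective-decrease
  tolerance; `max_iter` defaults to 1,000. Defaults for background size
  (10,000), prevalence τ (0.5, used only by the optional logistic output)
  follow common practice for this model family.
* **Outputs.** raw scores sum to 1 over the training background (asserted
  to 10⁻⁹ in tests); cloglog = 1 − exp(−e^H·raw) with H the entropy of the
  raw distribution; cloglog is monotone in raw, so rankings (and AUC) are
  identical between the two.
* **AICc** uses the normalized raw likelihood of the presences with k = the
  number of nonzero coefficients; combinations with n − k − 1 ≤ 0 are
  undefined and excluded. Ties break toward fewer parameters, then smaller
  rm, then feature-class order.

## Screening

The Spearman screen iterates over correlated pairs in descending |ρ|
(thresholds |ρ| > 0.8, p < 0.001) and drops the member with the larger mean
absolute correlation to everything else — a deterministic version of
standard collinearity pruning. The relevance screen is a simplified
shadow-feature procedure: each round appends a permuted copy of every
column, fits a random forest, and scores a real column a hit when it beats
the best shadow; confirmation is a one-sided binomial test against a fair
coin at α = 0.01 over 20 rounds. Full tentative-resolution logic of the
original wrapper algorithm is out of scope. In the pipeline both screens
apply to the bioclimatic layers only — soil and elevation always enter the
model — mirroring how such studies screen their (many, collinear) climate
candidates but keep their few soil/terrain layers.

## Extended FAST

Each factor in turn carries the high frequency ω_max (default 416) along a
resampled search curve of N_s = 2·M·ω_max + 1 points (M = 4), with random
phases per block; the other factors get distinct low frequencies. S_F reads
the variance at harmonics p·ω_max (p ≤ M); S_T is one minus the share below
the ω_max/2 cutoff. Indices are averaged over `n_repeats` phase draws
(default 5) and the standard deviation over repeats is reported as the
spread.

* **Complementary frequencies** are distinct integers spread evenly across
  the admissible band 1..⌊ω_max/2M⌋. Spreading matters: packing them at
  1, 2, … makes the complementary curves strongly correlated and inflates
  the estimator variance several-fold. When the factors fit into half the
  band, only 1..⌊band/2⌋ is used so complementary harmonics up to order 2M
  stay below the read-out cutoff; when there are more factors than the band
  holds, frequencies cycle with an explicit warning (some aliasing between
  complementary factors — their individual indices are unaffected because
  each gets its own block).
* **Input marginals** are fitted per layer by chi-square goodness of fit on
  20 equiprobable bins (α = 0.01) over uniform, normal and lognormal
  families, with an empirical-quantile fallback and exact frequency tables
  for categorical layers; constant layers are flagged degenerate and score
  0. Factors are sampled independently from these marginals — the spatial
  correlation between layers is deliberately ignored, as in the classic
  Simlab workflow; indices therefore describe the fitted response surface
  over the factor hyper-box, not over the landscape's joint distribution.
* **Accuracy.** The tests hold the estimates on the Ishigami benchmark at
  ω_max = 416 to within 0.05 of the closed-form indices, and an additive
  model to max |S_T − S_F| ≤ 0.03. An independent Monte-Carlo pick-freeze
  estimator cross-checks both at the same tolerance.
* **Ranks** in reports use competition ("min") ranking so tied values share
  the smallest rank, the convention of published sensitivity tables.

## Thresholds and evaluation

AUC is the rank-sum probability that a presence outscores a background
point (ties half). TSS = sensitivity + specificity − 1 at a threshold.
Three cloglog threshold rules are computed over the observed scores: MTSS
(maximize sens+spec, smallest maximizer on ties), PTSS (10th percentile of
presence scores, linear interpolation), ETSS (minimize |sens − spec|,
smallest on ties). The single working threshold is the TSS-weighted average
Σ t_r·TSS_r / Σ TSS_r — the weighting the phrase "based on the TSS
evaluation" most directly implies; an unweighted mean is available by
option and is the fallback (flagged) if no rule achieves positive TSS.

## Venn attribution

Gains (in the combined future but not the present) are labelled by gain
under the single-driver futures: both → shared, exactly one → that pure
effect, neither → coupling. For losses two conventions exist because the
published equation set is not the mirror image of its gain equations: the
default `as_printed` follows those equations literally (losses classified
by *retention* under the single futures), while `symmetric` mirrors the
gain logic (classified by *loss* under the single futures). The two label
the same four cell sets under the permutation shared ↔ coupling,
pure-climate ↔ pure-sea-level-rise; both are tested cellwise against
hand-enumerated 16-row truth tables. Cells inundated under a scenario count
as unsuitable there (habitat genuinely lost); only cells invalid under
every scenario are nodata in exports. Area percentages are rounded half-up
to 2 decimals; components always sum exactly to the changed total.

## Pipeline

A single master seed is fanned out per stage and region via hashed
`SeedSequence` keys, so any stage can be re-run in isolation and a full
re-run is bit-identical. Every stage writes its artifacts before the next
starts; the YAML manifest records the config echo, per-stage wall-clock and
SHA-256 checksums, and the failure point if a stage raises. Exit codes in
the CLI: 0 success, 2 config error, 3 stage failure.

**Problem sizes.** The default synthetic run uses a 100×200 grid of 1-km
cells, 300 presences, a 4×3 (rm × FC) tuning grid, 10-fold
cross-validation, and eFAST blocks of 257 runs (ω_max = 32) with 5 phase
repeats — sizes chosen so the whole workflow, including tests, completes in
a couple of minutes on a laptop while leaving every estimator comfortably
inside its accuracy envelope. The full-scale design (ω_max = 416, m = 15:
49,935 model runs per repeat) is exercised directly by the sensitivity
module's own tests.

## Known limitations

* The L1 penalty defaults are a simplification of the reference MaxEnt
  release's feature-class-specific tables; absolute coefficient values are
  therefore not comparable to that implementation, though the tuned models
  are (rm absorbs the scale).
* eFAST with more factors than distinct complementary frequencies (the
  ω_max = 32, m = 15 desk-scale default) aliases complementary factors into
  shared bins; per-factor indices remain unbiased in their own blocks, but
  very small total-index differences between factors should not be
  over-interpreted at that setting.
* The attribution is threshold-dependent by construction; the TSS-weighted
  threshold propagates its uncertainty into the area tables, which is why
  the three rule thresholds and their TSS values are reported alongside.
* Independent-marginal sampling in the sensitivity analysis ignores
  correlations between environmental layers; indices answer "what drives
  the fitted response surface", not "what varies on this landscape".
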