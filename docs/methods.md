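# Methods

This note documents the statistical model, the synthetic-data design and
the numerical choices behind the defaults. Notation: units are indexed
i = 1..n (default n = 187), epochs are t0 and t1.

## Pressure–status–response composites

Each component is a weighted sum of min–max-normalized per-unit inputs.
Normalization pools both epochs per variable, so composite changes between
epochs are comparable; a constant column is mapped to 0.5 and flagged with
a warning. Negative-orientation variables (curve number, local climate
regulation measured as a cost) are flipped as (max − x)/(max − min).

Weights for status (6 indicators) and response (4 service-value densities)
come from the entropy method: with shares p_ij = x_ij / Σ_i x_ij,
entropy e_j = −(1/ln n) Σ_i p_ij ln p_ij, and weight
w_j = (1 − e_j) / Σ_k (1 − e_k). A constant column has e_j = 1 and weight
0. Pressure has two inputs (mean DN, artificial-surface ratio) and uses
equal weights; entropy weighting over two near-collinear inputs is
unstable and the equal split is transparent.

## Ecosystem service values

Benefit transfer: ESV = Σ_k A_k · VC_k per unit and service category
(provisioning, supporting, regulating, cultural), with a configurable
coefficient table validated for completeness, non-negativity, and the
sanity constraint that artificial surfaces never out-value vegetated
classes within a category. The operation is exactly linear in both areas
and coefficients, which the tests exploit (additivity under partition
refinement, exact scaling).

## Risk levels and the RBF classifier

K-Means (k = 5) on the t0 (pressure, status, response) triples is
hand-rolled Lloyd iteration with k-means++ initialization, at most 100
iterations, 10 restarts, empty clusters reseeded to the farthest point,
and a per-iteration assertion that within-cluster sum of squares never
increases. Clusters are ranked to levels I–V by the score
s = P − S − R (ties broken by higher pressure, then lower status).

The RBF network uses M = min(160, n) Gaussian kernels with centers from
K-Means over the inputs (the exact points when M = n and they are
distinct), bandwidth σ = d_max / √(2M) with d_max the maximum inter-center
distance — the classical heuristic that scales the kernels to the spread
of the centers — and output weights from ridge-regularized least squares
(λ = 1e−8) against one-hot level targets; prediction is the argmax.
Accuracy is reported on a seeded 80/20 split, then the network is refitted
on all data before predicting t1.

## Spatial statistics

Weights are a 40-km binary distance band over unit centroids (symmetric,
stored as CSR), row-standardized where the statistic requires it. Global
Moran's I = (n/S0)·(z'Wz)/(z'z); local I_i = z_i Σ_j w_ij z_j with z
standardized by the population standard deviation, so the mean of the
local statistics equals the global I under row-standardized weights
(Anselin's identity, asserted in tests). Significance uses conditional
permutation (999 draws, one-sided on |I_i|) and LISA categories
high-high / high-low / low-high / low-low at α = 0.05.

The autologistic model for high-risk membership (levels IV–V) is
logit P(y_i = 1 | rest) = α + x_i'β + γ L_i with L_i the spatial lag of
the observed outcome. Maximum pseudo-likelihood reduces to a logistic ML
fit with the lag as a covariate; we use Newton iterations with
step-halving (tol 1e−8, ≤100 iterations). Under (quasi-)perfect
separation the pseudo-likelihood has no maximizer; the fit is then flagged
non-converged and the reported coefficients come from a weakly
ridge-penalized refit (λ = 1e−2, intercept unpenalized) whose finite
optimum tracks the maximum-margin direction. Unseparated fits match an
independent IRLS oracle to 1e−6. The estimator is validated by simulating
fields from the same model with a Gibbs sampler (systematic scan, 60
sweeps) and recovering γ: median estimates 0.94 / 0.98 / 1.02 for truth
1.0 on 10×10 / 20×20 / 30×30 lattices, with bias shrinking in lattice
size, as pseudo-likelihood theory predicts.

## Synthetic-region design and default rationale

- **Scale.** The default grid is 110×119 cells of 4 km (≈ 440×476 km,
  ≈ 2.1·10⁵ km²) partitioned into 187 county-like units. At this scale the
  40-km distance band gives each unit a handful of neighbors, as it would
  for county centroids in a large metropolitan region; on a 1-km grid the
  same band connected ~50 units and washed out all spatial structure.
- **Urban cores.** Two DN cores with exponential radial decay; artificial
  surface grows between epochs by converting the brightest non-artificial
  cells, calibrated so the artificial-surface ratio increases by ≈1 % of
  the region.
- **Climate gradient.** A mild north–south gradient in the vegetation and
  temperature layers (and a +2 K LST trend in t1) breaks the otherwise
  near-perfect collinearity between status and response (r ≈ 0.93 without
  it), which made the autologistic coefficient signs unidentifiable. Large
  regions spanning several degrees of latitude have such gradients.
- **Stacks.** EVI is a 12-layer monthly stack and LST a 14-layer summer
  stack, composited by nan-mean, so the temporal-compositing code path is
  exercised.

## What the synthetic data shows — and does not

The generator is designed so that the qualitative findings of an
urbanization risk assessment emerge from the mechanics of the methods, not
from hard-coding: service-value density ordered rural > suburban > urban,
pressure rising and response falling between epochs, positive spatial
autocorrelation of risk around the cores, and autologistic signs
(+pressure, −status, −response, +lag). These are properties of any region
with expanding bright cores and vegetation-linked services, and the tests
assert them.

Quantitative magnitudes (composite means, risk-share percentages,
regression coefficients) depend on arbitrary generator constants and carry
no empirical meaning. The per-epoch autologistic fit on observed t0 levels
is well behaved; the t1 fit uses RBF-predicted levels and is often
separable, in which case the flagged ridge fallback is reported.

## Limitations

- Benefit-transfer coefficients are synthetic placeholders; real
  assessments must supply an empirically grounded coefficient table.
- Pseudo-likelihood underestimates uncertainty under strong spatial
  dependence; no standard errors are reported for γ.
- The pipeline models exactly two epochs; trends, not trajectories.
- Conditional-permutation LISA p-values are not corrected for multiple
  testing across units.
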