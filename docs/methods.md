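# Methods

`metstab` analyses balanced multi-environment trials (METs): the same g
genotypes grown in replicated complete-block designs at q locations, one
trait at a time. This note records the models, the conventions and the
numerical choices, and what the simulation-based tests do and do not show.

## Data model

The unit of input is either long-format replicated records
(environment, genotype, replicate, value) or a g x q matrix of cell means.
Only balanced, complete tables are accepted; imbalance and missing cells are
rejected rather than imputed, because every estimator below assumes
balance. When a bare means matrix is supplied there is no within-trial
error stratum, so the combined ANOVA and variance components refuse to run
instead of approximating; all means-level analyses (AMMI, GGE, stability
statistics) proceed.

## Combined ANOVA and variance components

The observation model is

    y_ijr = mu + E_j + R_r(j) + G_i + (GE)_ij + e_ijr

with replicates nested within environments — degrees of freedom
(q-1), q(r-1), (g-1), (g-1)(q-1), q(g-1)(r-1). Sums of squares are
computed directly from group means (exact under balance); the test suite
cross-checks them against a sequential OLS ANOVA and against explicit-loop
summation on tiny tables. Genotype and interaction mean squares are tested
against the pooled error; the environment mean square against the
replicate-within-environment stratum, its error term under nested
blocking. p-values come from the F distribution; no multiplicity
correction is applied.

Variance components use the mean-square estimators

    sigma2_g = (GMS - EMS) / r,   sigma2_e = EMS / r,
    sigma2_p = sigma2_g + sigma2_e,   h2_B = 100 * sigma2_g / sigma2_p.

The divisor is r alone by default. Note that for a trial replicated
across q environments the textbook across-environment estimator divides by
r*q instead; with the r divisor the quantity estimated is q times the
per-environment genotypic variance. Both conventions are exposed
(`divisor="r"` / `"rq"`); the r default matches the convention used for
the packaged rice trial, whose published component table it reproduces
exactly for all six traits. Negative sigma2_g estimates (GMS < EMS) are
reported as-is with a warning, never clamped.

## AMMI

The cell-means table decomposes into additive main effects plus a
multiplicative interaction:

    X_ij = mu + a_i + b_j + sum_k lambda_k gamma_ik delta_jk + eps_ij,

where the doubly-centered residual Z = X - row means - column means +
grand mean is factored by SVD. Axis k explains
EP_k = 100 lambda_k^2 / sum(lambda^2) of the interaction SS. Conventions:

* **Score scaling.** `symmetric` (sqrt(lambda) to both sides) is the
  default and is the scaling the stability statistics are defined on;
  `none` and `full` are available.
* **Signs.** SVD signs are arbitrary; each axis is flipped so the
  genotype entry of largest magnitude is positive, making outputs
  reproducible across BLAS implementations.
* **Axis tests.** On the observation scale SS_k = r lambda_k^2 with
  Gollob degrees of freedom g+q-1-2k, F-tested against the pooled error
  mean square. Fitting on means and rescaling by r is equivalent to
  fitting on replicate-level data for every proportion reported.
* Interaction SS conservation (r sum(lambda^2) = GEN:ENV SS) is asserted
  in the tests at 1e-6 relative.

## Univariate stability statistics

All are "smaller = more stable", computed from the symmetric-scaled scores
s_ik = gamma_ik sqrt(lambda_k):

* **ASV** (stability value): sqrt(((SS1/SS2) s_i1)^2 + s_i2^2), the
  first-axis score inflated by the ratio of the first two interaction sums
  of squares (SS_k = lambda_k^2).
* **ASI** (stability index): sqrt((s_i1 theta_1)^2 + (s_i2 theta_2)^2)
  with theta_k = EP_k/100. Note the two conventions weight the same two
  scores very differently (SS1/SS2 > 1 vs theta_k < 1); published tables
  in this area are not always consistent about which label goes with
  which formula, so both are always reported side by side.
* **Joint regression** b_i: slope of the centered genotype row on the
  environmental index I_j = X.j - X.. (no intercept). The slopes average
  to exactly 1 — asserted at 1e-9.
* **Ecovalence** W2_i: row sums of squares of Z; sum(W2) equals the total
  interaction SS.
* **Shukla's variance**: the unbiased affine rescaling
  [p/((p-2)(q-1))] W2_i - sum(W2)/((p-1)(p-2)(q-1)); it preserves the
  ecovalence ordering, which the tests assert as rank equality.
* **WAAS**: sum_k |s_ik| EP_k / sum_k EP_k over the chosen axes (default:
  all). The axis count is a parameter because conventions differ; pass the
  count of significant axes from the AMMI ANOVA to restrict. Mixed-model
  (BLUP) shrinkage of the interaction — the "WAASB" variant — is out of
  scope; with fixed effects WAAS values differ slightly from BLUP-based
  published values.
* **WAASY**: yield and WAAS are min-max rescaled to 0-100 (yield up,
  WAAS down) and blended as (wy * yield_score + (100-wy) * waas_score)/100.
  wy = 100 reproduces the mean-yield ranking, wy = 0 the WAAS ranking.
  Genotypes are also classed into the four quadrants of (above/below grand
  mean) x (WAAS below/above the median).

Ranks use average-rank tie handling; the b_i rank orders by |b_i - 1|.

## GGE geometry

The GGE model removes only environment main effects (Y = X - column
means) so genotype main effect and interaction stay together, and factors
Y by SVD. No scaling by environment standard deviations is applied.
Rank-2 biplot coordinates depend on the singular-value partitioning
(symmetric / genotype-metric / environment-metric); the PC variance
shares and the rank-2 product G E^T are invariant to it, which the tests
assert across all three modes.

All biplot views are data, not drawings:

* **Which-won-where**: convex hull of the genotype points; sector
  boundary rays through the origin perpendicular to hull edges; each
  environment is won by the genotype maximising the projection onto its
  vector — provably a hull vertex, and equal to the genotype with the
  largest rank-2 centered value in that environment (asserted by brute
  force over random matrices). An environment exactly on a boundary is
  assigned counter-clockwise (documented tie rule). Collinear genotype
  configurations are reported as degenerate (detected at second singular
  value <= 1e-8 of the first).
* **Mean vs stability**: the average-environment axis (AEA) is the unit
  vector along the mean environment coordinate; genotype mean performance
  is the signed projection on the AEA, instability the orthogonal
  deviation magnitude.
* **Discriminativeness vs representativeness**: environment vector length
  and cosine with the AEA, with a median-split quadrant class.
* **Ideal-point rankings**: the ideal genotype sits at the maximal AEA
  projection with zero deviation; the ideal environment at the maximal
  on-axis projection with zero deviation; entries are ranked by Euclidean
  distance in the (AEA, orthogonal) frame.

## Simulator

`simulate_trial` draws y_ijr = mu + g_i + e_j + sum_k w_k gamma_ik
delta_jk + b_r(j) + eps_ijr with Gaussian effects and interaction loading
matrices that are exactly centered and column-orthonormal (QR of Gaussian
draws after projecting out the constant vector). That makes the planted
interaction a true bilinear model: with the noise off, the fitted singular
values equal the planted weights exactly and EP_k = 100 w_k^2 / sum(w^2),
so recovery statements are exact limits rather than approximations.
Optionally the first genotype's loadings are pinned to zero (still
centered/orthonormal on the rest) to create an interaction-free genotype
whose ecovalence has known expectation (g-1)(q-1)/g * sigma_noise^2 / r
under noise alone.

Defaults emulate a country-wide replicated rice yield trial on the kg/ha
scale: g=20, q=12, r=3, mu=6700, sigma_g=300, sigma_env=1800,
sigma_rep=1300, sigma_noise=1150, rank-2 interaction with weights
(5800, 4100). These were set from the magnitude of the packaged trial's
mean squares (error MS ~ 1.3e6 -> sigma_noise ~ 1150; environment MS ~
1.9e8 over g*r=60 -> sigma_env ~ 1800; and so on) and imply a
heritability near 71 on the paddy-yield scale.

What the simulator does **not** emulate: spatial field trend, correlated
or heteroscedastic environments, non-Gaussian effects, missing plots.
Passing recovery tests therefore show correctness of the estimators under
the balanced Gaussian bilinear model, not robustness to real-data
pathologies.

### A caution on heritability recovery

The component estimators themselves are exactly unbiased under the model
(E[(GMS-EMS)/r] = q sigma_g^2, E[EMS/r] = sigma_noise^2/r). The
heritability *ratio*, however, is a concave function of the noisy
genotype mean square, and with only g-1 = 19 genotype degrees of freedom
its Monte-Carlo mean sits about 2-3 points below the value obtained by
plugging expected mean squares into the formula (Jensen bias; at the
default settings the coefficient of variation of sigma2_g-hat is ~0.46).
The recovery suite reports this honestly: the mean estimated h2_B over
200 trials is systematically below the plug-in value by more than twice
its standard error. Users comparing a single trial's h2_B against a
"true" value should expect this downward bias whenever the genotype line
count is small; it vanishes as g grows or as noise shrinks.

## Numerical choices and degenerate inputs

* Tolerances: double-centering and margin identities asserted at 1e-9 of
  matrix scale; SVD/eigen equivalences at 1e-8; interaction SS
  conservation at 1e-6 relative.
* ASV's SS ratio is undefined when lambda_2 = 0 (rank-1 interaction);
  the statistic degrades to |s_i1| with a warning. The rank test uses
  lambda_2 <= 1e-12 lambda_1.
* Min-max rescaling in WAASY fails loudly when all genotypes share the
  same mean or the same WAAS.
* AMMI and GGE require g >= 3 and q >= 3; ecovalence only 2 x 2; Shukla
  needs p >= 3.
* CSV outputs default to 6 significant digits so reruns diff cleanly.

## Known limitations

Balanced complete designs only (no EM imputation, no lattice/alpha
designs); single-trait analyses; fixed-effects AMMI/WAAS rather than
BLUP-based mixed models; no bootstrap confidence regions for biplot
scores; rendering of the geometry is left to the caller.
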