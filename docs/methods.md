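# Methods

## The problem and the model

Brain-wide association studies relate per-edge functional connectivity (the
correlation of resting BOLD signal between two regions of interest, one value
per unordered ROI-pair) to behavioral covariates. Testing every ROI-pair
individually is badly underpowered once the multiple-testing correction
scales with tens of thousands of edges. Enrichment analysis changes the unit
of inference to the *network-pair* `N_ij`: the set of all ROI-pairs with one
ROI in functional network `i` and the other in network `j`. With `k`
networks there are `k(k+1)/2` network-pairs (91 for the default 13-network
atlas), so Bonferroni-level significance is `0.05 / 91 ≈ 1e-4` rather than
`0.05 / 40000`.

### Screening

For each ROI-pair `a`, connectivity is modeled as

    y_a = X1 b1_a + X2 b2_a + e_a

where `X1` holds the intercept and nuisance variables (age, sex, scan-site
dummies) and `X2` the behavioral covariates of interest, all fitted jointly
by OLS. Connectivity is the *response* deliberately: behavioral instruments
produce zero-inflated, floor-effected or long-tailed scores that are awkward
as responses, while connectivity is approximately Gaussian. The screening
statistic is the one-sided t statistic of each `b2` coefficient with
`df = N − (q + K)`. Hits are large positive t values; to probe negative
associations, negate the covariate. No moderated or z-transformed statistics
are used.

### ORA enrichment statistic

Screening statistics are binarized at a threshold quantile `alpha`; the
enrichment statistic of a network-pair is the number of member ROI-pairs
above the cut ("hits"). Two threshold modes exist:

* `theoretical` (default): the `alpha` quantile of the null t(df)
  distribution, so `alpha = 0.5` means "any positive statistic is a hit";
* `empirical`: the nearest-rank `alpha` quantile of the brain-wide screening
  statistics for that covariate (re-estimated per permutation during
  permutation testing).

The theoretical cut is the default because, at `alpha = 0.5`, "any positive
statistic counts" is exactly the distributional reading; the empirical mode
matches the alternative "top (1−alpha) fraction" reading. Ties at the
threshold are misses (strict `>`): counts are integers and determinism
matters more than a measure-zero boundary convention.

### Permutation inference (Freedman–Lane)

The self-contained null — no member ROI-pair is associated with the tested
behavior — is assessed by permutation. For covariate `k` the reduced model
contains `X1` *and every other column of `X2`* (everything controlled stays
controlled). Reduced-model residuals are permuted by one shared subject
reordering across all ROI-pairs (preserving the cross-ROI covariance), the
reduced fit is added back, and the full model is refit; the permutation
distribution of the enrichment count gives the one-sided p-value

    p = (1 + #{permuted count >= observed}) / (1 + P).

The add-one convention makes the test valid without forcing the identity
permutation into the draw; with an exhaustive scheme (all `N!` permutations,
identity included) the exact `#/P` fraction is used instead. Permutations are
drawn uniformly, independently across the `P` draws. Rotation-test variants
are not implemented; published comparisons on this kind of data report no
practical difference from plain permutation matrices.

A precomputation makes each permutation one pass over the data: the reduced
projection, the residualized covariate and an orthonormal basis of the full
design are formed once, and the permuted t columns follow from three batched
tensor contractions. The fast path is tested to agree with naive per-column
refitting to 1e-10 relative.

### Cutoff calibration

Running a permutation test per dataset is the expensive step, so integer
significance cutoffs can be precalibrated per (network-pair, covariate,
alpha): on each of `D` random-pairing null datasets (connectivity matrices
and behavior rows sampled without replacement from their pools and matched
uniformly at random, destroying all connectivity–behavior and
connectivity–nuisance association), the smallest count whose permutation
tail is at or below the target (default 1e-4) is recorded; the nearest-rank
75th percentile of the `D` values is the selected cutoff (25th percentile
available as a liberal alternative). Cutoffs are integers and never
interpolated, and are kept per covariate rather than pooled, since real
behaviors show small but nonzero cutoff variation.

**Attainability.** A network-pair of size `S` has minimum possible null tail
`(1−alpha)^S` (all members hitting at once). When even `count = S` has tail
above the target, the cell is unattainable and carries the sentinel `S + 1`.
The pair-level exclusion rule removes a network-pair from testing when it is
unattainable for *at least one* threshold level in the grid; with the
default grid and target this coincides with excluding pairs below ~50
ROI-pairs (19 of 91 in the default atlas). A resolution guard refuses
calibration when `1/(P+1)` exceeds the target.

### Power simulation

For one network-pair with `R` members:

1. estimate the `R × R` connectivity covariance `Ω` by Ledoit–Wolf shrinkage
   toward the scaled identity (the 2004 estimator; necessary because
   `N ≪ R`), and its Cholesky factor `C`;
2. draw per-ROI-pair coefficients `B ~ N(mu, sigma²)` i.i.d.;
3. draw behavior `X ~ N(0, 1)`;
4. set `f = X B' + Z C'` with `Z` i.i.d. standard normal.

`mu` is the average association strength across member ROI-pairs, `sigma`
its heterogeneity; `sigma > 0` with `mu = 0` means some pairs carry real
effects of either sign. `B` is redrawn for every simulated dataset, so power
estimates average over effect heterogeneity (this is a semantic choice:
power for a *class* of effects, not one fixed effect pattern). Screening
inside the power loop uses the single simulated covariate with intercept-only
nuisance. Power at a grid cell is the fraction of replicates whose ORA count
reaches the calibrated cutoff; `mu = sigma = 0` cells are still simulated
(they estimate the realized false-positive rate of the cutoff).

**Expected R².** For fixed `B`, behavior and connectivity are jointly
Gaussian with `Var(X) = 1`, `Cov(f) = BB' + Ω`, `Cov(f, X) = B`, so the
population multiple-R² of predicting behavior from the network-pair's
connectivity is `g/(1+g)` with `g = B' Ω⁻¹ B` (Sherman–Morrison). This
closed form is verified in the tests against the empirical R² of an actual
OLS at n = 1e5. `expected_r2` averages it over `B` draws. The adopted
definition is the R² of behavior on the member connectivities (regressions
could be read the other way; this one is the decision-relevant quantity for
"variance of behavior explained").

**Univariate comparison.** The power of the one-sided single-edge t test at
a liberal level (default 1e-3) has the closed form `nct.sf(t_{1−p,df}, df,
b√n/√noise_var)` with `df = n − 2`. The noncentrality treats the covariate
as standardized with `Σ(x−x̄)² = n`; the Monte-Carlo cross-check in the
tests conditions on such a design, and with random `N(0,1)` covariates the
formula is accurate to ~0.02 absolute at the sample sizes considered.

## Synthetic data

The generator emulates the statistical shape of a multi-site school-age
neuroimaging study, not its physiology:

* **Atlas**: 13 networks over 230 ROIs, composition
  (45, 40, 30, 27, 20, 18, 14, 8, 7, 7, 6, 4, 4). Per-network sizes of the
  reference atlas are not published; this composition was fixed once so the
  derived topology matches the published counts — 91 network-pairs, exactly
  19 with fewer than 50 ROI-pairs, smallest within-pair of size 6.
* **Connectivity** is simulated directly at the ROI-pair level with an
  exchangeable block covariance: correlation `rho_block = 0.3` within a
  network-pair, `rho_base = 0.05` across, unit variances. The real data's
  correlation magnitudes are not published; these defaults are placeholders
  of plausible magnitude. Sampling uses a three-factor latent construction,
  so the full-brain 26335² covariance is never formed. No time series,
  motion, or scanner artifacts are modeled.
* **Behaviors**: six covariates with Gaussian, uniform, thresholded-Gaussian
  (floor effect), zero-inflated (30% point mass) and log-normal shapes,
  matching the distribution families clinical instruments produce.
* **Nuisance**: age uniform on 8–12 years, sex Bernoulli(0.5), site uniform
  over 4 levels (reference-coded to 3 dummies downstream), N = 105 subjects
  by default (the behavior ∩ imaging overlap of the motivating study).

Because connectivity blocks are exchangeable and Gaussian, passing tests
show correctness of the machinery and calibration under realistic
*correlation scale*, not under real fcMRI dependence structure (spatial
autocorrelation, heavy tails, site-by-covariance interactions are absent).

## Numerical and design choices

* ROI-pair vectorization is row-major over the strict upper triangle,
  0-based internally; network order is first appearance in the atlas file.
  ROIs labelled `excluded` are dropped before pair enumeration.
* Designs are validated by rank; rank-deficient designs are an error naming
  candidate collinear columns. ROI-pairs with numerically zero residual
  variance (relative tolerance 1e-10) are flagged degenerate, carry NaN
  statistics, and count as misses — never silently infinite.
* Quantiles of integer cutoffs use the nearest-rank estimator throughout.
* Covariates are not standardized internally (t statistics are scale-free);
  effect-size conventions live in the simulator.
* Desk-scale defaults — D = 200 null datasets, P = 1e4 permutations, 500
  power replicates — keep a single-core run tractable; production
  calibration at D = 1000, P = 1e6, 5000 replicates is a parameter change.
  The test and acceptance workloads use reduced sizes (e.g. 500–1000 null
  studies at P = 500, cutoff oracles at P = 1e5) chosen as the package's own
  desk-scale reference points.
* All randomness flows from explicit seeds; per-cell power seeds derive from
  the master seed by enumeration order, so single cells reproduce in
  isolation.

## Known limitations

* The permutation scheme is the Freedman–Lane baseline; refinements of it
  exist but their exact modifications are not specified enough to adopt.
* Under a strong *homogeneous* embedded effect (low `sigma`), the effect
  itself inflates the permuted covariance, which depresses the test's
  sensitivity at low `alpha`; high thresholds (`alpha = 0.95`) are the
  robust default, matching the observed threshold recommendations.
* Power is per-network-pair; experiment-wide power aggregation across
  network-pairs is out of scope, as are FCS (continuous) enrichment
  statistics and the competitive null hypothesis.
* Unattainability and cutoff behavior are exact for the independence
  fixture; on strongly correlated data the count null is overdispersed and
  cutoffs shift upward accordingly — that is what calibration is for.
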