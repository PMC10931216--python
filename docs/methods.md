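# Methods

## Scope and model

`pedclim` treats a studbook as a directed acyclic graph of individuals
with sire/dam links, birth dates and birth places, and a weather archive
as daily station records keyed by (place, date).  The analysis chain is:

1. **Pruning** defines the *study set* — individuals with a registered
   birthplace, born in the home country, with weather coverage for their
   birth date, and without a location-inaccuracy flag.  Pruned
   individuals remain in the pedigree as ancestors: genetic parameters
   are always computed on the full historical pedigree, and only the
   analysis rows are restricted.  The four categories are applied in a
   fixed order and each individual is counted once, so the report's
   per-category counts always sum to the discard total.
2. **Diversity parameters** per individual (details below).
3. **Birth-climate join**: by default the single daily record at the
   birth place on the birth date.  A studbook-weather join has no
   canonical definition; alternatives (nearest record within ±k days,
   earlier date winning ties; monthly mean) are selectable policies.
   Records with missing fields propagate missingness; downstream
   analysis is complete-case.
4. **Screening** (VIF, normality, homoscedasticity, ROUT) — recorded,
   and collinearity acted on; normality and homoscedasticity never gate
   the pipeline because inference is by permutation.
5. **RCCA** with all derived quantities and significance machinery.
6. **Ridge-parameter tuning** by k-fold cross-validation.

## Genetic diversity parameters

**Inbreeding** uses the Meuwissen–Luo ancestor-list algorithm: for each
animal the diagonal element of the numerator relationship matrix is
accumulated by tracing its ancestor list once (highest topological index
first), with within-family variance D_j = 0.5 − 0.25(F_s + F_d) and the
convention F = −1 for an unknown parent.  No n×n matrix is formed;
memory is linear in pedigree size.  The independent cross-check in the
tests is Wright's path-counting formula evaluated by exhaustive
enumeration of ancestor paths (valid only for small pedigrees), and the
two agree to 1e−12 on random pedigrees.

**Coancestry** f(i, j) is the memoised tabular kinship recursion;
f(i, i) = (1 + F_i)/2, so 2f(i, i) − 1 = F_i is an internal consistency
identity under test.  **Average relatedness** AR_i is the mean additive
relationship (2f) of i with every individual, self included, computed
from the dense tabular matrix up to a size threshold and by block
evaluation beyond it.  Mean coancestry is AR/2 by definition — hence
exactly collinear with AR, which the screening stage is expected to
flag, mirroring the singularity exclusion reported for coancestry in
studbook analyses.

**Non-random mating degree** α solves (1 − F) = (1 − C)(1 − α).  The
reference coancestry is not standardised in the literature; the default
here is the individual's mean kinship with its birth-year cohort
(whole-population mean selectable).  Cohort reference is the
least-biased per-individual choice when mating opportunity is
structured in time.

**Pedigree depth**: maximum generations (longest known-ancestor path),
complete generations (deepest fully known ancestor layer), equivalent
generations t = Σ(1/2)^g over known ancestor slots, with
complete ≤ t ≤ max always.  **ΔF** = 1 − (1 − F)^{1/(t−1)} uses
equivalent generations by default (complete generations selectable); at
t ≤ 1 the exponent is undefined and ΔF is reported as 0 — one known
generation cannot express a per-generation rate.  ΔC is the pairwise
analogue with the mean of the two depths.

**Founder contributions and GCI.**  Contribution vectors follow the DAG
recursion vector(i) = ½vector(sire) + ½vector(dam).  By default an
unknown-parent slot contributes nothing and the vector is *not*
renormalised, so ΣP < 1 for incomplete pedigrees and GCI = 1/ΣP² is
computed on the raw masses — the formula as conventionally printed.
Under heavy record censoring this inflates GCI without bound (a nearly
unrecorded pedigree has tiny ΣP²); the `phantom_unknown` option instead
treats each unknown slot as a distinct phantom founder, restoring
ΣP = 1 and bounding GCI by the recorded founder count.  The default
stays raw for comparability; analyses of sparsely recorded registers
should prefer phantoms.

GCI is *not* monotone under pedigree truncation when ancestral paths
reconverge: deeper knowledge can concentrate founder mass (raising ΣP²)
rather than split it.  Truncation monotonicity holds for F and
equivalent generations, and for GCI only on non-reconvergent
ancestries; the tests assert exactly that.

## Screening

**VIF** is 1/(1 − R²) from regressing each column on its companions;
removal is iterative, one column at a time by largest VIF ≥ 5 with
recomputation, so the exit state has every VIF < 5 and re-screening is
the identity.  Auxiliary R² > 1 − 1e−10 is reported as singularity,
separately from finite-VIF exclusions.  A redundant *pair* (one column
equal to another plus noise) gives both members statistically
indistinguishable VIFs; near-ties within 15% drop the later column,
since variable sets are conventionally ordered primary-first with
derived columns appended.  This makes the screen deterministic without
pretending the data distinguish the pair.

**Normality** records Shapiro–Wilk and the D'Agostino–Pearson K²
omnibus (skewness + kurtosis z-scores, n ≥ 8).  **Levene's test**
(mean-centred) checks homoscedasticity across a grouping.  Neither
gates the analysis: the permutation test downstream is valid without
those assumptions, which is precisely why it is the primary inference.

**ROUT** (constant model): robust location by IRLS with Lorentzian
weights 1/(1 + (r/RSDR)²); RSDR is the 68.27th percentile of absolute
residuals (linear interpolation) with the n/(n − 1) small-sample
correction; points are tested from the most extreme inward against a
false-discovery-rate ladder (two-tailed t probability below Q·i/n for
the i-th most extreme), stopping at the first failure.  The procedure
is affine-invariant, flags a planted 10-SD point at Q = 1%, and flags
≤2% of clean normal points on average.

## RCCA

Inputs are column-standardised (n − 1 denominator).  The solver whitens
with symmetric inverse square roots of (C_xx + λ₁I) and (C_yy + λ₂I)
(eigenvalue floor 1e−12) and takes the SVD of the whitened
cross-covariance; singular values are the canonical correlations, and
back-transformed singular vectors the coefficients (unit score variance
under the regularized metric).  At λ = 0 this equals the classical
generalized-eigenproblem solution to 1e−8, the dual route kept as a
test oracle.  Signs are arbitrary in CCA; for determinism the X
variable with the largest |loading| per variate loads positively, the
paired Y variate flipping with it so correlations stay non-negative.

Wilks Λ is Π(1 − r_i²) — the squared form; the printed statistics of
the reference analysis are consistent only with squares, not with a
literal product of (1 − r_i).  F approximations: Rao's for Wilks
(per-root sequence included, with the dimension-reduction adjustment
M = N − 1 − (k − 1) − (p′ + q′ + 1)/2 for roots k..s, which reproduces
the published error-df sequence exactly), and the standard s/m/n
parameterisations for Pillai and Hotelling–Lawley.  Roy's root is
reported without an F (upper-bound approximations are not comparable
across software).  Redundancy is Stewart–Love: mean squared loading of
a set on a variate × r²; variates with r ≥ 0.30 (~10% shared variance)
are flagged meaningful.  Reported p-values are floored at 0.001.

**Permutation test**: rows of Y permuted B times; per root,
p_k = (1 + #{r_k^(b) ≥ r_k})/(B + 1).  With B + 1 divisible by 20 the
event {p ≤ 0.05} is exactly level 0.05 under exchangeability, which the
calibration checks use.

**Tuning**: seeded shuffle into k = 10 near-equal folds; per grid cell
the mean held-out first-variate score correlation; ties resolve to the
smaller λ₁ then λ₂.  The default grid is 10×10 log-spaced in
(0.001, 1); a 100×100 grid is supported but adds nothing at the sample
sizes the synthetic studies use.  The gap rule for dimension selection
keeps the dimensions before the largest consecutive drop in the
canonical correlations.

## Synthetic data: what it emulates, what it does not

The pedigree generator breeds discrete generations with configurable
founder count, pair count, Poisson litter sizes and an assortative
probability that draws relatives-first (half sibs or closer by recorded
parents); each parent link is censored with probability 0.08 to emulate
registration gaps, which separates the three depth measures as real
studbooks do.  Birth years advance linearly through 1950–2019 with
jitter; places are uniform over three configured provinces.  Weather is
per-place daily: seasonal sinusoid temperatures with independent
min/max noise (keeping corr(tmin, tmax) ≈ 0.8, matching station data),
zero-inflated gamma rainfall calibrated to a 1.64 mm/day mean, von
Mises wind direction on the tenths-of-degree scale, gamma wind with
gust ≥ wind enforced, sunlight within day length, and pressures with
p_min ≤ p_max.  The end-to-end fixture plants two redundant climate
columns (average temperature ≈ mean of min/max; maximum pressure ≈
minimum plus a positive offset) for the screen to find.

Not emulated: spatial correlation between places, long-term climate
trends, demographic history of any real breed, or any true
diversity–climate coupling.  Passing tests therefore demonstrate that
the machinery is correct and calibrated (null behaviour, planted-signal
recovery, planted-collinearity detection), **not** that any real
population shows these effects.  The planted-correlation generator
solves the noise covariance analytically (Cov = I − ρwwᵀ per block), so
the population first canonical correlation equals ρ exactly and
recovery bands in tests are pure sampling error.

## Numerical and design choices

- Dates are ISO-8601; month-precision dates map to day 15 (1950s
  records often lack day precision).
- Unknown-parent sentinels "", "0", "NA" are normalised to one marker;
  parents referenced without a row become founders with a warning
  (registry exports routinely omit imported ancestors).
- Kinship memoisation is floating point; the oracle tests bound the
  error at 1e−12 on small pedigrees.
- Degenerate cases: empty study set warns rather than errors; Levene
  with zero dispersion in every group returns p = 1 with a warning;
  ΔC at zero combined depth returns 0 with a warning; constant columns
  error in standardisation and are pre-excluded in screening.
- Problem sizes in the drivers and tests (≈2,000-individual pedigrees,
  3 places × 70 years of weather, 10×10 tuning grids, B ≈ 200–500
  permutations, ≤300 calibration replicates) were chosen so a desk
  machine reproduces everything in minutes while keeping Monte Carlo
  standard errors well inside the asserted bands.

## Known limitations

- Province-level place resolution only; no station geolocation or
  interpolation.
- The α reference population and the ΔF depth measure are genuinely
  underdetermined conventions; both are configurable and the defaults
  are stated above.
- ROUT is implemented for the constant model (column-wise screening),
  not for regression curves.
- Redundancy and loadings use the sample (unregularized) correlations
  of scores with variables; under strong regularization score variances
  under the sample metric differ from 1, which is the standard
  convention but worth remembering when comparing software.
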