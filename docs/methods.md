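# Methods

## The cline model and the drift problem

The central question is whether an allele's frequency varies systematically
with cumulative Out-of-Africa migratory distance.  The response is the
distance *y* (km) of each population along inferred migration routes; the
predictor is the arcsine-square-root transformed allele proportion,
x = arcsin√p, which stabilizes the binomial sampling variance of a
proportion and maps [0, 1] to [0, π/2] radians.  The regression

y = β₀ + β·x + ε,  ε ~ N(0, σ²R),

is fitted by full maximum likelihood (not REML), with interactions entered
as element-wise products of transformed predictors.

Populations are phylogenetically related: genetic drift along shared
branches correlates their allele frequencies, and because distance itself
accumulates along the expansion, drift alone produces spurious clines (a
random walk regressed on a monotone trend).  The correction supplies the
GLS error correlation as the pseudo-correlation
R = (max D² − D²)/max D² from a pairwise microsatellite genetic-distance
matrix D²: zero-distance pairs get correlation 1, the most distant pair 0.
This transform does not guarantee positive definiteness; if the smallest
eigenvalue falls below 1e-10 a diagonal ridge of 1e-8 is added and the
matrix rescaled to unit diagonal, with the ridge recorded on the result.
Indefinite matrices that a ridge cannot repair are an error.  `gls_fit`
also accepts an arbitrary SPD covariance (e.g. a simulation's exact drift
covariance); estimates, standard errors and p-values are invariant to its
overall scale.

## Estimation conventions

* β̂ = (XᵀR⁻¹X)⁻¹XᵀR⁻¹y; σ̂² = eᵀR⁻¹e/n (ML n-denominator);
  loglik = −n/2·[log(2πσ̂²) + 1] − ½·log det R;
  AIC = −2·loglik + 2(k+1), counting the k mean parameters plus σ².
* Standard errors are reported on the ML convention,
  √(σ̂²·diag((XᵀR⁻¹X)⁻¹)).
* Per-coefficient p-values use the exact finite-sample pivot
  β̂/SE_unbiased ~ t(n−k) (equivalently, the ML z-statistic rescaled by
  √(n/(n−k)) and referred to the t distribution).  At n ≈ 43 a
  large-sample normal reference on the ML standard error rejects true
  nulls at ≈6% instead of 5%; the t pivot keeps the test, the empirical
  inflation factor, and the calibration properties below exact.  The
  reported per-coefficient p-values also agree with the source analysis's
  printed values where those resolve beyond an order of magnitude.
* Complete-case handling per model; a model needs at least k+2 complete
  rows.  Zero-variance and collinear designs, and zero-residual
  (degenerate) fits, raise errors rather than returning numbers.
* AIC values are used for internal ranking only.  Rescaling the response
  by c shifts every AIC by the same 2n·log c, so the ranking is
  unit-invariant (property-tested for km→m); absolute AIC values are not
  comparable across data conventions, and the bundled table's AICs do not
  (and need not) match any externally printed AIC column.
* Model enumeration: every non-empty subset of main effects, optionally
  augmented with any subset of interactions among its members up to the
  chosen order; `require_main_effects=False` additionally allows dropping
  main effects of interacting markers (hierarchy-violating search).  Ties
  in AIC selection break toward fewer parameters, then term order.

## Multiple testing: the empirical inflation factor

The observed models are not compared to a theoretical null but to fits of
null markers with the same correlation structure: factor =
(proportion of null fits with p < α)/α, and each observed p-value is
replaced by min(1, p·factor).  The null set must carry the same drift
structure as the observed markers — the package's drift-mode generator
does this for simulations, mirroring the use of random genome-wide SNPs in
practice.  A calibration caveat discovered in testing: when the primary
fits ignore drift entirely (identity R on strongly drift-correlated data),
the null p-values pile up near zero so severely that a linear rescaling of
the significance threshold cannot restore the nominal level — the
inflation factor complements the drift correction; it does not substitute
for it.

## Allele orientation of the bundled table

A biallelic frequency column may count either allele; on the arcsine scale
the complement is an exact reflection, arcsin√(1−p) = π/2 − arcsin√p, so
re-orienting a marker flips its slope sign with unchanged magnitude.  For
rs1535882 the bundled column is printed in the orientation complementary
to the one the regression results were reported on (the printed slope is
positive while the printed frequencies fall with distance); analyses that
reproduce the reported table therefore use
`table.complemented(["rs1535882"])`.  The fixture itself stores every
column exactly as printed.

Printed-precision caveat: the bundled frequencies carry two decimals, and
the transform's derivative 1/(2√(p(1−p))) diverges as p→1.  For the two
near-monomorphic markers (rs6074896, rs4814391, with many entries printed
as 1.00) rounding alone moves the recomputed slope 2–3% from the reported
value; the better-conditioned markers reproduce to better than 1%.

## Synthetic data: what it emulates and what it does not

**Drift generator.**  Populations sit along a linear route (default 43
populations spanning 0–28,000 km, matching the real table's span) and form
a serial-founder chain: population *i* accumulates *i* backbone drift
increments plus one private increment, all N(0, drift_sd²) on the arcsine
scale, started from arcsin√p₀ (default p₀ = 0.7, a Table-like ancestral
frequency).  A distance effect adds d/β_true to the arcsine value, so the
distance-on-frequency regression has slope β_true in the noiseless limit.
Values are clipped to [0, π/2] and back-transformed, p = sin²x.  The
default drift_sd = 0.03 per split yields a cumulative dispersion (~0.2
rad) comparable to the real markers' spread while keeping clipping rare
(<1%).  The generator returns the exact drift covariance
(cov(i,j) = drift_sd²·min(i,j), var(i) = drift_sd²·(i+1)) and the implied
D² (unshared branch length), so calibration tests can supply the true
correlation: with it, the null rejection rate is 5% by construction, while
identity-R fits reject the true null the great majority of the time —
the quantitative motivation for the correction.

Because the drift noise lives in the predictor (frequencies drift;
distances are fixed), non-negligible drift attenuates the slope estimate —
a property of the design, not a bug of the estimator.  Unbiased-recovery
tests therefore run in the mild-drift regime (drift_sd = 0.01), where
attenuation is well inside one standard error; the strong-drift default is
used for the type-I-error properties, which are scale-invariant.  Real
data differ from this generator in having irregular route geometry, a tree
rather than a pure chain, and binomial sampling noise on top of drift, so
passing tests demonstrate calibration under the model's own assumptions,
not robustness to those departures.

**Null markers.**  Default mode permutes real marker columns across
populations (destroys any distance association, preserves marginals);
drift mode draws fresh chains with a given drift_sd for drift-structured
nulls.

**Genotypes.**  Subjects are two iid haplotype draws from given
frequencies (Sin-C, Sin-T, Dup-C, Dup-T) with phase erased — exactly the
sampling model the EM estimator assumes (random mating, no genotyping
error).

**4C reads.**  Fragment maps come from digesting a uniform-random sequence
(a GATC site every ~256 bp; real genomes have CpG-depleted, clustered
sites).  Expected weight per valid fragment end is
(1 + |coord − viewpoint|)^(−decay), attenuated by (1 − s·dosage/2) beyond
the insulator; reads are one multinomial draw per library, placed at the
boundary-adjacent base of the drawn end.  Real 4C adds PCR duplicates,
mappability gaps and inter-donor biology that this model omits.

**Ct replicates.**  Ct_T = baseline + noise, Ct_C = Ct_T + log₂(ratio) +
noise, with iid Gaussian cycle noise (default sd 0.1 cycles, 6
replicates) — no plate or efficiency effects.

## 4C pipeline conventions

Coordinates are 0-based half-open.  DpnII cuts are placed at the start of
each GATC occurrence (overlapping occurrences scanned at every position);
blunt-boundary placement only shifts bins, not counts.  A fragment is
*blind* (and removed) if no complete Csp6I GTAC occurrence lies inside
it; "shorter than 40 bp" is a strict inequality (a 40 bp fragment
survives); the viewpoint exclusion removes any fragment overlapping the
closed interval viewpoint ± 10 kb.  Reads map to the fragment end whose
half contains the read start.  The 30-fragment running mean is centered
(for the even default, 15 left/14 right) and shrinks symmetrically at the
edges rather than padding — no signal is fabricated beyond the profile.
Normalization divides by the total smoothed signal within ±2 Mb of the
viewpoint, making in-window weights sum to 1; the asymmetry statistic is
the in-window weight strictly downstream vs upstream of the viewpoint.
The dosage trend uses Spearman correlation with mid-rank ties and an
exact permutation p-value for n ≤ 10 (at the study's n = 6 the normal or
t approximations are untrustworthy), falling back to the t-approximation
for larger n.  The Mann-Whitney test is exact for combined n ≤ 12 without
ties, otherwise normal with tie correction.  With six samples the minimum
attainable exact two-sided Spearman or Mann-Whitney p is bounded well
above 10⁻⁴, so externally printed values below that bound cannot arise
from these test configurations at n = 6; the package reports the exact
enumerated values.

## Haplotype EM

The only latent class is the double heterozygote (Sin-C/Dup-T vs
Sin-T/Dup-C).  E-step weight for the cis configuration is
h₀h₃/(h₀h₃ + h₁h₂); the M-step is gamete counting with fractional double
heterozygotes.  Initialization is the linkage-equilibrium product of
observed allele frequencies, single start (the two-locus likelihood is
unimodal in practice at these sample sizes and a single deterministic
start keeps runs reproducible); convergence when max|Δh| < 1e-8, cap
1000 iterations.  The log-likelihood is asserted non-decreasing every
iteration, and the fitted haplotype margins equal the observed allele
frequencies exactly (an EM fixed-point property used as a test oracle).
With no double heterozygotes the estimator is plain gamete counting in
one step.  HWE uses the Pearson 1-df chi-square without continuity
correction (monomorphic samples return chi-square 0 with a warning);
LD statistics follow the standard D, D′ = |D|/D_max, r² definitions.

## Problem sizes and determinism

Every stochastic test fixes its seed; generators are pure functions of
(config, seed).  Monte-Carlo property tests use 200 replicates of the
43-population simulation (type-I error, recovery, corrected-scan
calibration), 10,000 draws for the uniform-null inflation factor, 1,000
random sequences for the digest oracle, 500 subjects for EM recovery,
and a 2000-fragment / 100k-read configuration for the end-to-end 4C
ordering — sizes at which the checked quantities' Monte-Carlo error is
several times smaller than the asserted tolerances.

## Known limitations

* The published drift-adjusted coefficients depend on an unpublished
  genetic-distance matrix; only the structure of the correction is
  verifiable here, not those numbers.
* The inflation factor assumes the null set shares the observed fits'
  correlation structure; with a mismatched null it can be arbitrarily
  miscalibrated (see above).
* Migratory distances are treated as fixed, error-free covariates.
* The 4C asymmetry statistic compares weight mass, not profile shape;
  two profiles with equal downstream mass but different contact geometry
  are indistinguishable to it.
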