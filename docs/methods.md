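# Methods

## Generative model of a PMR measurement

A specimen is characterized by two latent quantities: `h`, the number of
haploid genome equivalents in the analyzed aliquot, and `p`, the true
proportion of the genomic target that is methylated. DNA is fragmented, so
the aliquot holds `G = round(h·f)` fragments with `f = 10⁴` fragments per
haploid genome (the scale implied by ALU-repeat quantification of fragmented
DNA; rounding error is < 10⁻⁴ genomes at this f). The number of methylated
target alleles captured by the reaction is

    B ~ Binomial(G, p/f)        E[B] = h·p

The reference is an M.SssI-treated sample of 5,500 genome equivalents whose
fragment count is fixed at its expectation `Gʳ = round(5500·f)` — the
reference aliquot is a controlled lab quantity, not a per-specimen random
variable — while its methylated count is drawn per reaction:

    Bʳ ~ Binomial(Gʳ, c/f)      E[Bʳ] = 5500·c

with conversion efficiency `c = 1` by default (complete M.SssI treatment /
bisulfite conversion). Setting `c < 1` reproduces the known artifact of an
under-methylated reference: PMR is inflated by roughly 1/c and its variance
grows (exposed as an option; default behaviour assumes a valid reference).

The observable is `PMR = 100·(B/G)/(Bʳ/Gʳ)`. Key consequences, all covered
by tests:

* **Unbiasedness.** E[PMR] ≈ 100·p at every h (the only bias term is the
  O(1/5500) ratio bias from E[1/Bʳ]).
* **Heteroscedasticity.** Var(PMR) ≈ 10⁴·p/h from the numerator alone, so
  the SD falls like h^(−1/2) and rises with p.
* **Zero inflation.** PMR = 0 iff B = 0, with exact probability
  `(1−p/f)^G ≈ exp(−ph)`. The genome-level shorthand `(1−p)^h` is also
  provided; the two forms differ by up to ~0.064 for p ≤ 0.3 (worst near
  h ≈ 3 at p = 0.3) and agree to 0.01 only for small p (≤ ~0.05). Both are
  exposed because both appear in practice; the binomial form is the one the
  simulator actually obeys.

Numerical edge cases: a specimen whose aliquot rounds to zero fragments
(P ≈ 0.5% per tumor under the default quantity model) detects nothing and is
assigned PMR = 0 in the simulation path, while the direct `compute_pmr` on
counts raises on G = 0 so that hand-built degenerate inputs fail loudly.
A reference draw of Bʳ = 0 (probability ~e^(−5500) at defaults, reachable
only with user-set tiny references) is redrawn up to a bounded retry count
and then raises.

## Population scenarios

True methylation proportions follow a Beta–Bernoulli mixture per group: with
probability `1 − π` a tumor is unmethylated (p = 0), otherwise p is Beta
with given mean and variance (moment-parameterized:
`k = m(1−m)/v − 1, α = mk, β = (1−m)k`; the (0.2, 0.01) case is Beta(3,12)).
The registry holds nine alternatives — means (0.2, 0.27) and (0.4, 0.47)
with variance patterns (0.01,0.01), (0.04,0.04), (0.01,0.04), all at π = 1,
plus three mixtures with π = (0.5, 0.7) on the (0.4, 0.47) Betas — and six
nulls: the cross of Beta means {0.2, 0.4} × variances {0.01, 0.04} plus two
π = 0.67 mixtures. Group-mean differences are 0.07 (pure Beta) and 0.13
(mixtures). Custom scenarios are definable from YAML/JSON with the same
fields.

Input DNA quantity follows a capped lognormal chosen to mimic archival
colorectal specimens: with `ln L ~ Normal(0, 0.75²)`, the genome count is
`Q = 10^(2.74 − L)`, giving a hard cap of 10^2.74 ≈ 550 genomes,
P(Q < 10) = 0.2301 and P(Q < 1) = 0.0895. The deviate L plays the role of a
C(t)-like cycle count (larger L = fewer genomes). Group membership is
deterministic by count (first n₁ tumors are group 1) so that every replicate
has exact group sizes; unequal 1:2 / 2:1 allocations round group 1 to the
nearest integer (200 → 67/133).

## Variance estimation and weights

Observations are ranked by *effective DNA quantity*; the orientation of the
surrogate must be declared (`quantity`: larger = more DNA; `ct`: larger =
less DNA) and ranking is stable with ties broken by input order. Variances
are estimated from both comparison groups pooled — the premise is that
sampling noise depends on DNA quantity only, not on the study variable.

* **Quantile weights** split the ranked data into k contiguous nearly equal
  groups (n = 200, k = 5 → 40 per quintile; remainders are distributed one
  per group from the lowest-quantity group upward) and assign each
  observation the within-group sample variance (n−1 denominator).
* **Window weights** use a centered window of w ranked neighbours
  (default 41: the observation plus the 20 ranked just above and below).
  The m = (w−1)/2 lowest-ranked observations share the variance of the
  bottom-most w observations, the m highest that of the top-most w.
* Weights are `1/max(variance, floor)` with
  `floor = max(10⁻¹², 10⁻⁸ · max group variance)`: a bin of identical PMRs
  (e.g. all zeros at very low quantity) would otherwise get infinite weight;
  with the floor, a fully degenerate dataset reduces exactly to OLS.
* **Threshold weights** are 1 iff the effective quantity exceeds the cutoff
  (for C(t) surrogates: iff the C(t) is below it), reproducing
  exclusion-based analysis as a weighting scheme.

Weights are treated as known in the subsequent fit; the estimation noise of
the empirical variances is deliberately not propagated.

## The test family

Each method regresses the outcome (PMR, or ln(PMR+1) for log-scale methods)
on an intercept and a 0/1 group indicator by weighted least squares. With a
binary regressor the fit has a closed form — the coefficient is the
difference of weighted group means and its standard error uses the weighted
residual mean square — which the implementation uses directly for replicate
throughput; the test suite verifies exact agreement (≈10⁻¹⁴) with
statsmodels WLS and with a separately coded pooled-variance t-test.
P-values are two-sided from a t distribution on `n_effective − 2` degrees of
freedom, where `n_effective` counts positively weighted observations; this
makes the threshold methods bit-identical to OLS on the filtered subset.
For log-scale weighted methods the variances driving the weights are
estimated from the log-transformed outcome, since those are the variances
relevant to the fitted model.

Choices made where the design was genuinely open: classical (homoscedastic)
standard errors rather than sandwich estimators, two-sided tests, and
odd-only window widths (a centered window needs symmetry; "window of 40" is
taken as 41).

## Simulation studies

A study cell = scenario × method suite × replicates. Defaults follow the
study design the registry mimics: 200 tumors, α = 0.05, 10,000 replicates
for null (false-positive rate) grids and 1,000 for power grids — sizes that
keep a full null grid (6 scenarios × 6 methods × 10,000) around a minute on
one CPU. Every replicate draws from an independent `SeedSequence` substream,
so results are reproducible and independent of execution order. Replicates
where a method fails (e.g. a group entirely zero-weighted under extreme
mixtures) are counted and excluded from that method's denominator, with a
warning above 1%. Rejection rates carry binomial Monte-Carlo standard
errors `sqrt(r(1−r)/n)`.

Measured behaviour under the defaults (recomputed by the test suite and
`scripts/acceptance.py`, not asserted from memory): all six methods hold the
5% level on the null scenarios to within Monte-Carlo wiggle (raw-PMR OLS
runs slightly conservative, ~0.04, reflecting the heavy-tailed outcome); the
inverse-variance WLS methods dominate the power comparison, the
quantity-threshold filters are intermediate, and OLS on raw PMR is weakest,
with WLS-Q and WLS-W within a few points of each other everywhere. On the
right-skewed high-variance alternative, weighted regression on ln(PMR+1)
beats unweighted log-scale OLS. Window-based weighting needs enough
observations per window: at very small windows (e.g. w = 5 at n = 60–100)
the inverse of an unstable variance estimate over-weights lucky
observations and inflates the type-I error to ~0.07–0.11, while w ≈ 41 is
calibrated at n ≥ 120.

## What the generator does and does not emulate

The simulator reproduces fragment-sampling noise, zero inflation, the
quantity–variance relationship, and population-level Beta/Beta–Bernoulli
heterogeneity. It does **not** model tumor/normal cell mixture, PCR
amplification-efficiency kinetics, C(t) measurement chemistry, plate or
batch effects, or center-stratified quantity distributions. Passing tests
therefore demonstrate the statistical properties of the estimators under
fragment-sampling measurement error, not robustness to those additional
real-data phenomena. Real C(t)-based analyses also depend on a calibration
from C(t) to genome equivalents that must come from the user's own assay;
`pmrwls` only requires the declared orientation of the surrogate.

## Known limitations

* Weights are conditioned on, so severe weight-estimation noise (small
  samples, small windows) inflates type-I error as quantified above; the
  engine exposes `window_size_sensitivity` to check a planned design.
* The t-test on raw PMR is mildly conservative and on ln(PMR+1) mildly
  anticonservative (≈0.057 worst-case at n = 200 over the null registry) —
  ordinary small-sample behaviour of least squares under skewed outcomes.
* The reference-ratio bias O(1/reference genomes) is ignored; it is ~0.02%
  at the default 5,500-genome reference.
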