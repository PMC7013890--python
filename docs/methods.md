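# Methods

## The q statistic and its conventions

For an outcome y over N records partitioned into strata h = 1..H with sizes
N_h, the package computes

    q = 1 − SSW/SST,  SSW = Σ_h N_h σ_h²,  SST = N σ²,

with **population** variances (divisor N_h and N). The field's definition is
ambiguous about the divisor; the population convention is chosen because it
makes the two published forms of the statistic (the stratum-variance form
and the SSW/SST form) coincide exactly, and it makes q identical to the
between/total variance share of a one-way ANOVA decomposition — which the
test suite exploits as an independent oracle. Singleton strata contribute
σ_h² = 0 to SSW. A constant outcome (SST = 0) is reported as q = 0 with a
`degenerate` flag rather than an error.

q is clipped into [0, 1] only against floating-point underflow; the
mathematical bounds hold exactly (SSW ≤ SST for any partition), and the
refinement property — a finer partition never has smaller q — is asserted
over randomized tables in the tests.

## Significance of q

The literature around these detectors reports p-values for q without a
canonical test, so two are provided:

* **Permutation (default).** Stratum labels are randomly reassigned
  (equivalently, y is permuted against the fixed partition); p =
  (1 + #{q* ≥ q_obs}) / (1 + n_perm) with n_perm = 999 by default and an
  explicit seed. This is exact up to Monte-Carlo error under the null of no
  association and makes no distributional assumption. Its validity (type-I
  error at α = 0.05 within [0.03, 0.07] over 500 null replicates) is checked
  in the acceptance tests.
* **Noncentral-F transform (cross-check).** F = (N−H)/(H−1) · q/(1−q)
  referred to a noncentral F(H−1, N−H; λ) with
  λ = [Σ_h Ȳ_h² − (Σ_h √N_h Ȳ_h)²/N] / σ², the analytic test from the
  geographical-detector literature. It is offered for users who want the
  analytic route; the permutation test is authoritative here.

## Risk detector

For every unordered pair of strata with ≥ 2 members each: Welch's t on the
stratum means,

    t = (x̄_a − x̄_b) / sqrt(s_a²/n_a + s_b²/n_b),

with sample variances and Satterthwaite degrees of freedom, two-sided at a
95% default confidence level. The published formula for this detector prints
a minus between the two variance terms; that sign produces a negative
radicand whenever the second term dominates and is treated as a typographic
slip — the standard Welch plus is used. No multiplicity correction is
applied by default (mirroring per-pair reporting practice in this
literature); `fdr=True` switches on Benjamini–Hochberg.

## Ecological detector

F = [N₁(N₂−1)·SSW₁] / [N₂(N₁−1)·SSW₂] referred to F(N₁−1, N₂−1). The
direction of the test is not specified in the source formulation; the
package reports a two-sided p (doubled smaller tail) and names the factor
with the smaller SSW `dominant` when significant, `"tie"` otherwise. A zero
denominator SSW yields an infinite F flagged with p = 0.

## Interaction detector

The overlay X₁∩X₂ assigns each record the pair of its stratum labels;
empty joint cells simply do not occur as strata. q(X₁), q(X₂) and q(X₁∩X₂)
are all computed on the records covered by *both* stratifications, so the
three values decompose the same SST. Classification:

| condition | label |
|---|---|
| \|q_ab − (q_a+q_b)\| ≤ tol | Independent |
| q_ab > q_a + q_b | Enhance, nonlinear |
| q_ab ≥ max(q_a, q_b) | Enhance, bi |
| q_ab ≥ min(q_a, q_b) | Weaken, single |
| otherwise | Weaken, nonlinear |

evaluated top to bottom with tol = 1e−9. The published rule uses strict
inequalities and leaves boundaries undefined; here a boundary resolves to
the adjacent category nearer Independent, making the classifier total and
deterministic on [0,1]³ (property-tested). Because the overlay refines both
marginal partitions, true Weaken labels cannot arise from the overlay
itself — they can only appear when classifying externally supplied q
triples.

## Moran's I

I = (n/S₀)·(zᵀWz)/(zᵀz) with z = y − ȳ. Inference uses the randomization
(permutation) moments: E[I] = −1/(n−1) and the standard variance formula in
S₀, S₁, S₂ and the sample kurtosis, with a two-sided normal p-value; an
exact permutation p is available. Weights are a genuine modelling choice for
point data and are therefore documented in every result object: the default
is k-nearest-neighbour (k = 8), binary, row-standardised, on haversine
(great-circle) distances. An inverse-distance scheme is available. The
analytic moments are cross-checked in the tests against brute-force
permutation and the statistic against a naive double-loop implementation.

## Grouping convention

Records split into group 1 (fatalities > 0, analysed on the fatalities
column) and group 2 (fatalities = 0 and injuries > 0, analysed on injuries);
records with neither are excluded and counted. The strict form "fatalities
≥ 1" is equivalent for integer counts; "> 0" is used so that non-integer
severity scores (see below) group correctly. Missing factor values are
carried as the sentinel code −1 and excluded record-wise from any
stratification involving that factor, keeping q comparable across factors
with different missingness.

## The synthetic generator

Each record draws a zone (categorical), coordinates from the zone's
isotropic Gaussian cloud (degrees), a year, and a category per factor —
optionally with per-zone multiplicative probability tilts, which is the only
built-in source of factor–factor dependence. The latent mean is

    μ = β₀ + s · ( Σ_f a_f[code_f] + Σ c[code_a, code_b] )

with per-factor effects a mean-centered under the category probabilities,
cross-terms c doubly centered, and s the per-outcome `effect_scale`.
Centering makes the marginal outcome mean β₀ exactly and gives a
single-factor population q the closed form Σ p_h a_h² / (Σ p_h a_h² + σ²)
under Gaussian noise (`expected_q`), which the tests verify by Monte Carlo
and use for parameter-recovery checks (planted q ∈ {0.1, 0.3, 0.5}
recovered within 0.03 at n = 5000).

Noise models: Gaussian (continuous, truncated at 0 — baselines are set high
enough that truncation is negligible), Poisson, and a **moment-matched
discrete** distribution on a small support whose probabilities are solved
from the moment system (infeasible targets raise an error naming the
constraint). Planted effects move its conditional mean by exponential
tilting, which stays on the support and preserves the marginal mean;
conditional means are clipped to the feasible open range (2% margin), a
rare-event adjustment that biases group means by well under 0.01 at the
preset effect sizes.

### The calibration preset

`make_preset("shenzhen_like")` emulates the published summary statistics of
a 3250-record urban crash dataset: a 30% fatal-group share (the source
prints no group sizes; chosen once as a plausible split), five spatial
zones, the full 17-factor coding, and group outcomes matching the printed
moments — fatal group mean 0.48 / SD 0.301, injury group mean 1.41 / SD
1.055. One printed pair is mathematically awkward: *no* distribution on
non-negative integers can have mean 0.48 with SD 0.301 (the minimum SD of an
integer variable at that mean is ≈ 0.50), so the printed fatal-group moments
cannot describe literal fatality counts. The preset therefore draws the
fatal-group severity from a three-point distribution on {0.25, 0.5, 1.0}
matching the printed moments exactly, and documents it as an emulation
choice, not a claim about the real data. Injury counts *are*
moment-matchable on integers and use support {1, 2, 5}.

Planted effects are monotone unit-variance ramps per factor scaled by
relative amplitudes (violation factors strongest), with effect_scale 0.095
(fatalities) and 0.14 (injuries) — sized so the strong factors clear the
permutation test at the preset sample sizes while group means stay within
sampling error of the printed values. The preset's spatial zone effects are
deliberately mild, so its Moran z-scores are small; `spatial_demo` carries
the strong-clustering configuration (tight clusters, zone-shifted means,
z ≫ 2.58). `null` plants nothing; `interaction_demo` plants a doubly
centered diagonal cross-term (between-cell SD ≈ 0.85 against σ = 1) with
powerless marginals, yielding nonlinear enhancement in ≥ 95% of seeds.

### What the generator does not emulate

Road-network geometry (coordinates are Gaussian blobs), realistic joint
factor distributions beyond zone tilts, temporal trends, overdispersion
mixtures, and the actual published per-factor q values (explicitly a
non-goal — those require the non-public microdata). Passing tests
demonstrate that the detectors recover *planted* structure of the stated
kinds at the stated sample sizes, not that any particular real-world dataset
has that structure.

## Pipeline conventions

Factor tables mask a factor (no q shown) when its permutation p exceeds
α = 0.05 (configurable). Risk tables are produced only for unmasked factors.
Interaction matrices cover **all** unordered factor pairs, including masked
factors, because a pair of individually non-significant factors can combine
into a significant joint stratification — the phenomenon the type-share
summary is designed to surface. Type shares are computed over all pairs.
Combined-factor detection ranks overlay strata by mean outcome and tests
each top-k stratum against the pooled complement (one-sided Welch).

## Problem sizes

Default test and acceptance runs use the preset sizes above (N ≤ 5000,
permutations ≤ 999, ≤ 500 replicates for calibration checks); these are
sufficient for the Monte-Carlo tolerances quoted and keep full runs in the
tens of seconds on one core.

## Known limitations

* The permutation and noncentral-F p-values for q need not agree closely at
  small N; the permutation test is the reference.
* The ecological detector's F reference distribution treats SSW ratios as
  variance ratios with (N−1) degrees of freedom per factor, following the
  published formulation; it is conservative when H is large.
* Moran's I on point data depends materially on the weight specification;
  results always carry `weights_spec` and should not be compared across
  different weight choices.
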