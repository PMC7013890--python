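# geodetect

Stratified-heterogeneity analysis of traffic-accident casualty severity.

Road-safety records are categorical through and through: the cause of the
crash, the responsible party, the road class, the lighting, the zone of the
city. When the *strata* of such a factor differ systematically in outcome
severity — more fatalities per crash in some strata than others — the factor
carries explanatory power, and models that ignore the stratification will
misestimate local risk. This package implements the family of *geographical
detectors* that measure and test exactly that, for epidemiologists and
transport-safety analysts working with point-level accident records.

## The statistics

The foundation is the **q statistic** of a partition of N records into
strata h = 1..H:

    q = 1 − SSW / SST,    SSW = Σ_h N_h σ_h²,    SST = N σ²

where σ_h² and σ² are population variances of the outcome within stratum h
and overall. q ∈ [0, 1] is the share of outcome variance explained by the
stratification: q = 0 means the factor is uninformative, q = 1 means it
determines the outcome completely. Four detectors build on it:

* **factor detector** — q of one factor, with a seeded permutation test
  (an analytic noncentral-F transform test is available as a cross-check);
* **risk detector** — pairwise Welch t comparisons of stratum means with
  Satterthwaite degrees of freedom, locating high-risk strata;
* **ecological detector** — F = [N₁(N₂−1)·SSW₁] / [N₂(N₁−1)·SSW₂], asking
  which of two factors explains more;
* **interaction detector** — q of the overlay X₁∩X₂ (the common refinement
  whose strata are non-empty joint categories), classified against q(X₁),
  q(X₂) and their sum into *weaken / enhance / independent / nonlinear
  enhancement* types. Nonlinear enhancement — q(X₁∩X₂) > q(X₁) + q(X₂) —
  is the signature of factors that are jointly far more dangerous than
  separately.

A global **Moran's I** (row-standardised kNN weights, haversine distances,
randomization inference) screens outcomes for spatial dependence.

Because real crash microdata are rarely shareable, the package ships a
**synthetic record generator**: spatially clustered records with 17 coded
factors, planted factor effects with a closed-form population q, planted
pairwise cross-terms, and a calibration preset reproducing the published
summary statistics of a large urban crash dataset (N = 3250, two severity
groups with outcome means 0.48 and 1.41). Every detector is therefore
testable against known ground truth.

## Worked example

```python
from geodetect import (generate, make_preset, split_groups, stratify,
                       compute_q, q_significance, interaction_detector,
                       moran_from_table)

table = generate(make_preset("shenzhen_like"), seed=7)
g1, g2, excluded = split_groups(table)
print(f"records: {table.n}  fatal group: {g1.n}  injury group: {g2.n}")

y = g1.outcome("fatalities")
moran = moran_from_table(g1, "fatalities")
print(f"Moran's I = {moran.i_statistic:.3f}  z = {moran.z_score:.2f}")

for name in ("primary_cause", "responsible_party", "day_of_week"):
    strat = stratify(g1, name)
    res = compute_q(y, strat)
    p = q_significance(y, strat, n_perm=999, seed=0)
    print(f"{name:<20} q = {res.q:.3f}  p = {p:.3f}")

r = interaction_detector(y, stratify(g1, "primary_cause"),
                         stratify(g1, "responsible_party"))
print(f"primary_cause x responsible_party: q_ab = {r.q_ab:.3f} "
      f"(sum {r.q_sum:.3f}) -> {r.type_label}")
```

prints

```
records: 3250  fatal group: 957  injury group: 2293
Moran's I = 0.009  z = 0.66
primary_cause        q = 0.160  p = 0.001
responsible_party    q = 0.068  p = 0.001
day_of_week          q = 0.007  p = 0.328
primary_cause x responsible_party: q_ab = 0.352 (sum 0.227) -> Enhance, nonlinear
```

Reading this: the planted violation factors explain 16.0% and 6.8% of the
fatality heterogeneity and clear the permutation test (p = 0.001 at 999
permutations), the day of the week explains nothing (p = 0.33 — it would be
masked as "-" in a factor table), and the overlay of cause and responsible
party explains more than the two factors *summed* (0.352 > 0.227): nonlinear
enhancement, i.e. specific cause-by-party combinations are
disproportionately lethal. Moran's I on this preset is small and
non-significant because its spatial zone effects are deliberately mild; the
`spatial_demo` preset produces strong clustering.

scikit-learn users can reach the same results through estimator classes
(`FactorDetector`, `RiskDetector`, `EcologicalDetector`,
`InteractionDetector`, `MoranI`) with `fit(X, y)` and fitted attributes
(`q_`, `p_value_`, `type_label_`, ...), composable with sklearn tooling.

A command-line interface mirrors the library:

```bash
geodetect simulate --preset shenzhen_like --seed 7 --out crashes.csv
geodetect detect   --input crashes.csv --outcome fatalities
geodetect interact --input crashes.csv --outcome fatalities
geodetect combine  --input crashes.csv --factors primary_cause,responsible_party --top-k 10
geodetect moran    --input crashes.csv
geodetect report   --input crashes.csv --out report.json
```

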