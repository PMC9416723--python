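# Methods

## Mass-balance derivation of guidance values

The central quantity is a urinary guidance value: the metabolite
concentration that corresponds, at steady state, to intake of the parent
substance at its Acceptable Daily Intake,

    HBM-GV [µg/L] = ADI · (MW_met · F_ue / MW_parent) / V_urine · 1000,

with the ADI in mg/kg bw/day, molar masses in g/mol, `F_ue` the molar
urinary excretion fraction in (0, 1], and `V_urine` the body-weight-adjusted
daily urine volume (0.03 L/kg bw/day children, 0.02 adults). The model
assumes steady-state balance between intake and urinary elimination — spot
samples, short-term exposure peaks and day-to-day variation in urine output
are outside it.

Molar masses are not consistently tabulated in regulatory summaries, so the
registry ships them as named constants recomputed from molecular formulas
with average atomic masses (e.g. 3-PBA C13H10O3 = 214.22, cypermethrin
C22H19Cl2NO3 = 416.30, tau-fluvalinate C26H22ClF3N2O3 = 502.91).

### Rounding

Published guidance values follow a recognisable convention which
`round_gv` codifies: half-up to two significant figures, then values
≥ 50 µg/L to the nearest 10 µg/L (88.5 → 90, 30.1 → 30, 6.39 → 6.4,
56.8 → 60). Two published values do not follow it — both
lambda-cyhalothrin entries (derived 8.89 and 13.3 µg/L, published 9 and
14) — and are stored as printed overrides with the raw derivation retained
and flagged in the value's provenance note.

### Screening values and the parent-MW convention

The screening value for a common metabolite takes the *minimum ADI* and the
*minimum excretion fraction* across the metabolite's parent substances.
Because those two minima come from different substances, one parent molar
mass must still be chosen for the equation. The package default
(`screening_mw_convention = "named:tau-fluvalinate"`) uses the heaviest
candidate parent, which is the most conservative choice and reproduces the
published adult value of 4.8 µg/L exactly; for children it yields
3.19 µg/L against a published 3.25 (within 2%), and reports flag the
difference. `"min_adi_parent"` is available as an alternative. For
4-FPBA the single assessable parent (cyfluthrin) fixes everything; its
screening derivation deliberately uses the worst-case 9% fraction rather
than the measured 47% because the measured value rests on one volunteer.
The adult 4-FPBA screening value computes to 24.1 µg/L while 24.7 is the
published constant; the published figure is carried as the adopted
comparison value with the derivation retained.

The published refined screening values at the 11/21/31% excretion
scenarios are not linear rescalings of the worst-case base under any single
ADI–MW combination; the package computes linearly scaled values and carries
the published figures as reported constants without asserting equality.

## Exposure tables

Inputs are aggregated percentiles (µg/L, never creatinine-adjusted — the
schema has no creatinine column by design) per study population and
biomarker. `NR` cells become missing values, never zeros, and rows with
non-monotone percentiles are rejected with row-level diagnostics. The
packaged fixture transcribes the printed 95th percentiles of the aligned
European studies (2014–2021); where only an RCR is printed the percentile is
back-calculated as RCR × GV (noted per row), and the handful of percentiles
that are not recoverable at all are shipped as clearly-flagged synthetic
plausible values that no test asserts. The Belgian children DCCA value is
stored as 7.52 µg/L (it is printed both as 7.5 and 7.52; 7.52 reproduces
both dependent published ratios at printed precision). Percentiles of sums
are not sums of percentiles, so a sum biomarker (Σ(3-PBA + 4-FPBA)) is only
accepted as a verbatim reported row.

## Tier engine

* **Tier S** — RCR of each common-metabolite P95 against the screening
  value; a reported sum is screened against the 3-PBA value (valid because
  the 4-FPBA screening value is higher).
* **Tier I** — RCR of each selective-metabolite P95 against the
  substance-specific guidance value. Cyfluthrin is compared against the
  4-FPBA *screening* value (16.0 / 24.7 µg/L), the conservative yardstick
  given its single-volunteer toxicokinetic basis; this is also the only
  reading that reproduces the published RCR matrix. Missing percentiles
  yield explicit NR rows. Two published cells are irreproducible from
  their own printed inputs and are carried as documented discrepancies: the
  German adults permethrin entry (printed 0.003, computes to 0.002) and the
  narrative "highest children deltamethrin RCR 0.044" against the matrix's
  0.059 for France (the engine reproduces the matrix).
* **Sum of RCRs** — shared biomarkers are allocated to a single substance
  (ClF3CA → lambda-cyhalothrin, DCCA → cypermethrin, DBCA → deltamethrin)
  to avoid double counting; sums are keyed per study *and* population.
* **Tier C** — the measured 3-PBA level is split into the maximum possible
  per-substance contributions, `GV_3PBA(substance) × RCR(selective)`, where
  `GV_3PBA` uses the substance's own ADI and molar mass with the worst-case
  9% fraction. The unattributed residual defaults to tau-fluvalinate (the
  only contributor with no selective biomarker of its own); attributing it
  to the reference substance instead gives the provable upper bound, and a
  sweep utility reports both together with the refined RCR as a function of
  the permethrin share of DCCA. Relative potencies are ADI ratios against
  lambda-cyhalothrin (lowest ADI). With these defaults the most exposed
  children cohort refines from a screening RCR of 2.17 to ≈1.10.

## Probabilistic refinement

Distributions: log-logistic (shape β, scale α; quantile
α(p/(1−p))^(1/β)), Weibull (shape k, scale λ), triangular, and point
masses, all via `scipy.stats`. Quantile fitting minimises summed squared
error on log quantiles — scale-invariant and appropriate for right-skewed
concentration data; for the log-logistic and Weibull families the problem
is linear after transforming the probability axis and is solved exactly,
so round-trip recovery is at machine precision. A linear-scale objective
and a numerical path for the triangular family are selectable.

The exceedance analysis is a **two-dimensional Monte Carlo**: the
log-logistic describes between-individual exposure variability (for the
most exposed cohort: shape 2.025207, scale 1.687245 µg/L, whose 95th
percentile of 7.22 µg/L brackets the reported 7.05), while the excretion
fraction — Weibull shape 2.4009431, scale 0.3465461, mean 0.307 — is a
single uncertain toxicokinetic parameter, not a per-individual trait. The
headline `exceedance_probability` is therefore the population fraction
whose exposure exceeds the guidance value at the *central* (mean) fraction;
at n = 10,000 and the default scenario this is ≈2.2%, in agreement with the
closed-form log-logistic survival at the mean fraction. Joint integration
over both distributions — as if the fraction varied per individual — is
also reported (`diagnostics["joint_exceedance"]`, ≈5%) together with the
p05/p50/p95 uncertainty band of the exceedance fraction across the Fue
distribution; the band spans roughly 0.7%–19%, which is the honest width of
this uncertainty. Under the mixed-ADI scenario (per-draw ADI uniform over
the seven assessable substances, optional user weights) the per-substance
exceedance ranges from ≈2.2% (lambda-cyhalothrin) down to ≈0.005%
(permethrin), with a uniform average near 0.5%. One seeded generator
drives each run (exposures drawn first, then fractions, then ADI indices),
so results are bit-reproducible; no variance-reduction tricks are used.

The screening-value distribution uses a triangular fraction distribution,
default (0.09, 0.21, 0.55): the lowest reported averaged excretion value,
the geometric-mean scenario as mode, and the highest reported upper range
bound. No pooling rule over the packaged rates table reproduces exactly
this triple (pooled min/median/p95 of the point values is 0.09/0.21/0.63),
so the default is anchored to the published scenario values and a helper
(`derive_triangular_from_rates`) computes the literal min/median/p95 for
users who prefer it.

## Synthetic cohorts

The generator draws individual-level concentrations with the requested
marginals; dependence between 3-PBA and selective metabolites uses a
Gaussian copula (shared latent normal), giving Spearman correlation
6/π·arcsin(r/2). Aggregation uses type-7 (linear-interpolation)
percentiles — stated explicitly because percentile conventions differ — and
percentile-bootstrap 95% CIs, refusing cohorts below 20 individuals. The
generator emulates the *statistical* structure the aggregated pipeline
assumes; it does not enforce within-individual mass balance (a person's
3-PBA being at least the sum of attributable parts), model urine-volume or
creatinine variability, or simulate toxicokinetics from dietary intake — so
passing end-to-end tests demonstrates correct plumbing and statistical
convergence, not toxicokinetic realism.

## Problem sizes and numerical choices

Monte Carlo defaults to 10,000 iterations; tests use 10,000–50,000 draws
for distributional checks and 100 replicates × n = 1,000 for bootstrap
coverage, sizes at which every check runs in seconds on one CPU. Ties in
the minimum-ADI selection break alphabetically; probabilities are validated
to lie strictly inside (0, 1); sampled fractions are clipped to (0, 1];
comparisons against published tables use half-up rounding at each cell's
printed precision.

## Known limitations

* Steady-state assumption; spot-sample variability is not modelled.
* The screening children value differs from the published constant by 1.7%
  because the publication's exact parent-MW choice is undocumented; the
  published constants are used for risk characterisation, the derivation
  for everything parametric.
* Etofenprox is registered but non-assessable (ether-linked alcohol moiety;
  3-PBA is not a proper marker); derivation requests raise a policy error.
* Exposure percentiles that the source material does not print are synthetic
  placeholders (flagged in the fixture) and carry no evidential weight.
* The break-even statements about tau-fluvalinate (<65% of 3-PBA) and
  permethrin (>50% of DCCA) depend on scenario details that are not fully
  specified; the sweep utilities report the curves without asserting the
  thresholds.
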