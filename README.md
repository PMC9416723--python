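# pyrethroid-hbm

Tiered risk assessment of pyrethroid insecticide exposure from human
biomonitoring data: urinary metabolite concentrations are compared against
guidance values derived from health-based reference doses, and identified
concerns are refined with substance-specific, combined-mixture and
probabilistic analyses.

Pyrethroids share metabolic pathways, so urinary biomarkers are mostly
*common* metabolites: 3-phenoxybenzoic acid (3-PBA) covers cypermethrin,
deltamethrin, lambda-cyhalothrin, permethrin, tau-fluvalinate and others,
while DCCA, DBCA, ClF3CA and 4-FPBA are more selective. This package turns
that complexity into a tiered workflow for public-health surveillance:
screening on the common metabolites first, refinement only where a concern
appears.

## The model

Under steady-state mass balance, intake at the Acceptable Daily Intake (ADI)
corresponds to the urinary concentration

```
HBM-GV = ADI · (MW_met · F_ue / MW_parent) / V_urine        [mg/L]
```

with `F_ue` the molar fraction of the ingested parent excreted as the
metabolite and `V_urine` the body-weight-adjusted daily urine volume
(0.03 L/kg bw/day for children, 0.02 for adults). The tiers are:

* **Tier S (screening)** — a deliberately conservative screening value for
  3-PBA/4-FPBA built from the lowest ADI (0.0025 mg/kg bw/day,
  lambda-cyhalothrin) and the lowest excretion fraction (9%); the Risk
  Characterisation Ratio RCR = P95 / GV flags concern when above 1.
* **Tier I (substance-specific)** — each selective metabolite's P95 against
  the substance's own guidance value.
* **Tier C (combined)** — the measured 3-PBA level is decomposed into
  per-substance contributions (bounded by the selective-metabolite RCRs) and
  the screening RCR is rescaled by ADI-ratio relative potencies:
  `refined = RCR_screen · Σ (amount_i / measured) · (ADI_ref / ADI_i)`.
* **Probabilistic refinement** — the population exposure distribution is
  reconstructed from reported percentiles (log-logistic), the excretion
  fraction is treated as an uncertain parameter (Weibull or triangular), and
  a seeded two-dimensional Monte Carlo estimates the population fraction
  exceeding the guidance value.

## Worked example

```python
import pyrethroid_hbm as ph

registry = ph.load_registry()          # packaged substances/biomarkers/fractions
report = ph.run_full_assessment(seed=1)

for r in report.tier_s:
    if r.concern:
        print(r.study_id, r.biomarker_id, round(r.rcr, 2))
belgium = next(c for c in report.tier_c if c.study_id == "BE-3xG")
print("refined", round(belgium.refined_rcr, 3))
```

prints

```
BE-3xG 3-PBA 2.17
CY-ORGANIKO 3-PBA 1.95
FR-ESTEBAN 3-PBA 1.31
IL-RAVMABAT 3-PBA 1.44
NL-SPECIMEN 3-PBA 1.54
SI-SLOCRP 3-PBA 1.14
refined 1.099
```

Every children cohort exceeds the 3-PBA screening value (RCR 1.14–2.17), no
adult cohort does, and no substance-specific ratio comes near 1. The
combined refinement brings every cohort below 1 except the most exposed one
(Belgium), which lands just above (≈1.10) under the conservative assumption
that all unattributed 3-PBA stems from tau-fluvalinate. The Monte Carlo
refinement quantifies the residual population risk:

```
$ pyrethroid-hbm mc-exceedance --seed 1 --n 10000
{ "exceedance_probability": 0.0224, ... }
```

i.e. about 2% of the most exposed children population would exceed the
guidance value if all exposure were to the most toxic pyrethroid; under a
mixed-substance scenario the estimate falls to roughly 0.5% (range
2% – 0.01% across substances).

A CLI mirrors the library: `derive-gv`, `screen`, `assess`, `combine`,
`mc-screening`, `mc-exceedance`, `synth` (synthetic cohorts for end-to-end
testing) and `report` (JSON / CSV bundle / markdown).

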