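# eciaf

Tools for measuring the **overall burden of early-childhood malnutrition**
with the composite index of anthropometric failure (CIAF) and its extended
form (eCIAF), built for analysts working with national household surveys of
child anthropometry (DHS/MICS-style two-stage stratified cluster designs).

Conventional indicators — stunting (HAZ < −2), wasting (WHZ < −2),
underweight (WAZ < −2), overweight (WHZ > +2) — overlap: a child can fail
several at once, so none of them alone measures how many children have *any*
anthropometric failure. The CIAF partitions children into mutually exclusive
failure groups,

| code | group |
|------|-------|
| A | no failure |
| B | wasting only |
| C | wasting and underweight |
| D | stunting, wasting and underweight |
| E | stunting and underweight |
| F | stunting only |
| Y | underweight only |
| G | stunting and overweight *(eCIAF)* |
| H | overweight only *(eCIAF)* |

and the overall burden is 1 − P(A). The package implements the full
analysis pipeline around that index:

- **`eciaf.anthro`** — LMS z-scores (z = ((x/M)^L − 1)/(L·S)) for HAZ, WAZ,
  WHZ and BMIZ, the restricted tail adjustment for the weight-based scores
  beyond ±3 SD, biological-plausibility flagging, and exclusion tallies.
- **`eciaf.classify`** — conventional indicators and the CIAF/eCIAF partition.
- **`eciaf.survey`** — design-weighted prevalence with 95% CIs by first-stage
  Taylor linearization under a stratified cluster design, nationally and by
  region.
- **`eciaf.cfa`** — two-group configural frequency analysis over the 2³
  stunting×wasting×underweight configurations: margin-model expected counts,
  per-configuration Fisher exact tests, Bonferroni-adjusted "discrimination
  types".
- **`eciaf.quantiles`** — quantile profiles (τ = 0.05 … 0.95 by 0.025) of the
  z-score distributions per survey, sex and age group, with cluster-bootstrap
  bands.
- **`eciaf.simulate`** — a two-stage cluster survey generator with known
  ground truth on the latent z-score scale, so the whole pipeline can be
  exercised and validated without restricted survey micro-data.
- **`eciaf.reporting` / `eciaf.cli`** — descriptive tables, 2025 global
  nutrition-target assessment, and the `eciaf` command-line driver.

The packaged growth reference is a **synthetic** LMS table (see
`docs/methods.md`): internally consistent and realistic in shape, but not
the published WHO 2006 values — supply your own reference CSVs
(`indicator,sex,key,L,M,S`) for real-data work.

## Worked example

```python
from eciaf import (
    SurveyDesignSpec, apply_exclusions, build_config_table, classify_frame,
    compute_zscores_frame, discrimination_types, flag_implausible_frame,
    generate_three_survey_scenario, subtype_prevalence_table,
)

surveys = generate_three_survey_scenario(scale=0.3, seed=20111)
classified = {}
for label, (records, truth) in surveys.items():
    scored = flag_implausible_frame(compute_zscores_frame(records))
    included, tally = apply_exclusions(scored)
    classified[label] = classify_frame(included)

table = subtype_prevalence_table(classified["GSPS-like"], SurveyDesignSpec())
print(table[["group_code", "estimate", "ci_low", "ci_high"]].round(3))

cfa = discrimination_types(
    build_config_table(classified["GSPS-like"], classified["GMICS-like"],
                       ("GSPS-like", "GMICS-like")))
print(cfa.to_frame())
```

prints the weighted subtype prevalences for the heavy-tailed panel-style
survey,

```
   group_code  estimate  ci_low  ci_high
0           A     0.462   0.407    0.516
1           B     0.031   0.016    0.047
2           C     0.076   0.051    0.101
3           D     0.050   0.028    0.071
4           E     0.101   0.073    0.128
5           F     0.119   0.091    0.147
6           Y     0.020   0.008    0.033
7           X     0.000   0.000    0.000
8           G     0.024   0.009    0.038
9           H     0.118   0.087    0.149
10    overall     0.538   0.484    0.593
```

(the subtype rows sum to 1 and the overall eCIAF burden is exactly
1 − P(A) ≈ 53.8%), and the two-group CFA table whose final column marks the
configurations on which the two surveys differ significantly — here the
wasting configurations and the no-failure cell:

```
  stunting wasting underweight  obs_a  obs_b   exp_b  p_value  discrimination
0      Yes     Yes         Yes     26     70    77.2    0.066           False
...
4       No     Yes         Yes     36     55    73.2    0.000            True
5       No     Yes          No     15     12    21.7    0.000            True
7       No      No          No    260   1254  1217.6    0.000            True
```

The same pipeline is available from the shell:

```bash
eciaf simulate --scale 0.3 --seed 20111 --output-dir sim/
eciaf run --seed 20111 --output-dir out/   # full pipeline + manifest
```

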