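# Methods

This note documents the statistical model behind each module, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions.

## Z-scoring (`eciaf.anthro`, `eciaf.reference`)

A growth reference in LMS form gives, per indicator, sex and key (age in
completed months, or length/height in cm for weight-for-height), a Box-Cox
power L, median M and coefficient of variation S. The z-score of a
measurement x is

    z = ((x/M)^L − 1) / (L·S),   or   z = ln(x/M)/S when L = 0.

Reference parameters are interpolated linearly in the key between tabulated
rows — the conventional practice for LMS tables. Age is treated as completed
(integer) months, as survey extracts record it. Numerically the transform is
evaluated in `expm1`/`log1p` form so that it degrades smoothly to the L = 0
log form for arbitrarily small |L| (below ~1e−150 the L·S product underflows
and the log form is used outright).

**Restricted tail adjustment.** For the weight-based scores (WAZ, WHZ,
BMIZ — not HAZ), raw z beyond ±3 is re-expressed on a linear scale anchored
at the ±2 and ±3 SD reference curves: z = 3 + (x − SD3)/(SD3 − SD2) above
+3, mirrored below −3. This is the standard-analysis convention for survey
tabulations; it is continuous at the knots, order-preserving, and leaves
every score inside ±3 untouched. It is on by default with a switch, since
published survey tabulations normally use it.

**Plausibility limits.** A z-score strictly outside HAZ [−6, 6],
WAZ [−6, 5], WHZ [−5, 5], BMIZ [−5, 5] (closed intervals; boundaries are
plausible) is flagged biologically implausible. These are the standard
fixed-exclusion limits; they live in one constant block
(`anthro.FLAG_LIMITS`) so alternatives are a one-line edit. Flags are set on
the adjusted scores, matching the standard workflow.

**Exclusions.** Children under 6 completed months and flagged children are
dropped, tallied by reason with the age rule applied first — a child failing
both is counted once, under age. Row count kept plus tally always equals the
input size. Missing measurements yield missing z components and exclusion
from any statistic that needs them; nothing is imputed.

**The packaged reference is synthetic.** The published WHO 2006 tables are
not redistributable here, so the default table
(`data/synthetic_lms_reference.csv`) is constructed in code
(`reference.build_synthetic_reference`): smooth median curves of realistic
shape (height-for-age a + b·t + c·ln(1+t); weight-for-height quadratic in
height) with constant L and S per indicator in the range the published
references span, tabulated at integer months 0–60 and heights 45–130 cm.
The weight-for-age median is *defined* as the weight-for-height median
evaluated at the median height for that age, and BMI-for-age follows from
both, so a child at the median of height and weight scores zero on all four
indicators — internal consistency the pipeline's statistics rely on, and the
only property they rely on. Absolute medians do not match the WHO
publication, so z-scores computed against this table are not comparable to
published ones; for real data, load genuine reference CSVs via
`LMSTable.from_csv`.

## Classification (`eciaf.classify`)

Thresholds are strict (z = −2.0 exactly is not a failure), matching the
convention of the index's definitions. Overweight is defined on WHZ > +2
(the DHS/MICS convention) and is switchable to BMIZ > +2. Two taxonomy
edge cases are handled explicitly:

- stunted ∧ wasted ∧ ¬underweight has no letter in the classical taxonomy
  (it is essentially empty in real data — its observed count is zero in all
  published tables this package's layouts follow); it gets sentinel code X,
  counts as failure, and is reported separately;
- underweight ∧ overweight (possible under the WHZ definition) maps to H
  (G if also stunted) with a data-quality warning, since the taxonomy
  predates the combination.

The classifier is total on the admissible indicator space, and the CIAF
view is derived from the eCIAF view by dropping over-nutrition (G→F, H→A).

## Survey estimation (`eciaf.survey`)

Point estimate: the weighted ratio p̂ = Σwᵢyᵢ/Σwᵢ (scale-invariant, so raw
weights are used). Variance: first-stage Taylor linearization with the
with-replacement PSU approximation — per stratum h with n_h PSUs,
n_h/(n_h−1)·Σⱼ(z_hj − z̄_h)² with z_hj the PSU total of (yᵢ − p̂)wᵢ/Σw.
This is the default of standard survey software; replicate-weight methods
are out of scope. The household (secondary sampling unit) is carried in the
design spec for fidelity but does not enter the first-stage variance.
CIs are symmetric Wald, p̂ ± 1.96·se, clipped to [0,1], matching the
symmetric intervals such analyses print; logit-scale intervals are available
via `ci_scale="logit"`. Single-PSU strata raise by default, with `collapse`
(pool singletons into one pseudo-stratum) and `certainty` (zero
contribution) as explicit alternatives. Regional estimates are domain
estimates: weights as-is, variance restricted to the region's PSUs.

## Two-group CFA (`eciaf.cfa`)

Observed counts over the 8 stunting×wasting×underweight configurations per
survey, *unweighted*: the CFA tests sampled frequencies, not weighted
population estimates. Expected counts come from the margin (independence)
model E[c,g] = row_total_c·N_g/N, which conserves both margins exactly.
Each configuration is tested by a two-sided Fisher exact test
(minimum-likelihood rule) on the 2×2 table [this configuration vs all
others] × [group 1, group 2]; a configuration observed in neither group
keeps p = 1 and stays in the table. One test method is applied uniformly to
all configurations for coherence. Multiplicity is controlled by Bonferroni
over the K = 8 configurations (local level α/8 = 0.00625 at α = 0.05);
Holm and unadjusted thresholds are available. The Bonferroni default is the
only local level consistent with published discrimination-type patterns in
this literature, where p ≈ 0.014–0.015 rows are marked non-significant at a
nominal α of 0.05.

## Quantile profiles (`eciaf.quantiles`)

The τ-grid is 0.05 to 0.95 in steps of 0.025 (37 points). The estimate at
each τ is the weighted midpoint-interpolation (Hazen) sample quantile:
observation i sits at cumulative-weight position (cᵢ − wᵢ/2)/W and the
curve is interpolated linearly. With equal weights this equals
`numpy.quantile(..., method="hazen")` (e.g. the median of 1…100 is 50.5)
and coincides with the pinball-loss minimizer up to the choice of point
within a flat segment; the interpolating convention was chosen because it
is deterministic, standard, and exactly reproducible by an independent
sorting oracle. Sampling weights enter the estimate, consistent with the
rest of the pipeline. Profiles are nondecreasing in τ by construction; a
monotone sort is applied defensively to band edges.

Bands are 95% percentile intervals from a cluster bootstrap: PSUs resampled
with replacement within each group, 999 replicates by default, fixed seed —
identical seeds give identical bands. A rank-score asymptotic band would be
an alternative; the bootstrap was chosen because it respects the cluster
design and is fully specifiable. Two profiles "differ" at τ when their
bands are disjoint there (touching bands do not differ). Age strata are
6–23 vs 24–59 completed months, inclusive.

## Synthetic surveys (`eciaf.simulate`)

Regions are strata; clusters (PSUs) are drawn without replacement from each
region's pool; the design weight is pool/n_psu, with the within-cluster
stage taken as certainty. A child's latent (HAZ*, WHZ*) is region shift +
cluster effect + child effect; the cluster effect carries a share `icc` of
the total variance (default 0.03, a typical anthropometric cluster
correlation) and the two scores are correlated at `corr_haz_whz` (default
0.15) at both levels. Height is the LMS inverse of HAZ* at the child's age
and sex; weight is the LMS inverse of WHZ* at that height. WAZ and BMIZ are
*not* generated: they emerge from the one height/weight pair through the
reference, exactly as in a real survey, which guarantees internal
consistency among the indices. Because shifts live on the z scale,
configured prevalences have closed-form targets (stunting ≈ Φ(−2 − shift)
at sd 1). Children per household are Poisson (sparse counts, many
households with none); ages uniform over 6–59 completed months; sex by a
0.505 male ratio.

The packaged three-survey scenario mirrors the structure of the national
data sources it emulates: a large MICS-like survey (81 clusters per region
× 15 households, 0.54 children per household), a DHS-like survey (41 × 30,
0.17) and a smaller panel-style survey (33 × 15, 0.32), the cluster counts
and household takes scaled from the real designs and the children-per-
household means chosen so the expected sample sizes land near the real
analytic samples (≈6.5k/2.1k/1.6k at scale 1). The panel-like survey has
matched median shifts but heavier latent tails (sd_haz 1.45, sd_whz 1.75 vs
≈1.0), so it shows more wasting *and* more overweight despite similar
medians — the distributional signature that makes quantile profiles cross
near the centre and gives the CFA discrimination types to find.

**What the generator does not emulate:** nonresponse, digit preference and
other measurement error, seasonality, age heaping, real regional geography,
and the real WHO reference scale. Passing tests therefore demonstrate the
*statistical machinery* (weighting, variance, classification, testing) is
correct under a known truth — not that any specific published prevalence is
reproduced from micro-data, which remains access-restricted.

## Target assessment (`eciaf.reporting`)

Relative change is (followup − baseline)/baseline × 100, rendered half-up
at integer precision ("Decrease of 37%"); all computation is at full
precision and rounding happens only at render time. The 40%-stunting-
reduction verdict is reported both on the unrounded change (strict ≤ −40)
and on the rounded change, because a −39.9% change prints as "Decrease of
40%" and the two readings genuinely disagree; the wasting (< 5%) and
overweight (< 6%) rules are strict thresholds on the follow-up prevalence.
Descriptive tables compare surveys with the chi-square test of homogeneity
(categorical) and Kruskal–Wallis (continuous) — Kruskal–Wallis rather than
ANOVA because the summaries reported alongside are medians and IQRs; ANOVA
remains a one-line change via `scipy.stats.f_oneway` if means are wanted.

## Validation problem sizes

The validation suite sizes its simulations for fast, reproducible runs:
confidence-interval coverage uses 200 replicate surveys of ~1 700 children
(10 strata × 8 PSUs × 12 households) against a census-like truth run of
~86 000 children; the Fisher-vs-enumeration sweep covers every 2×2 table
with grand total ≤ 60 (one representative per row/column/transpose orbit,
~84 000 tests); quantile-oracle agreement is checked at every grid τ for
n up to 1 000. These sizes are the package's own choices and are stated in
the tests themselves.

## Known limitations

- The synthetic reference limits comparability of absolute z-scores with
  published tabulations (by design; swap in real reference CSVs).
- Variance estimation ignores the second stage and finite-population
  corrections (standard with-replacement approximation; slightly
  conservative).
- No poststratification or calibration of weights; no design-effect output.
- The CFA's Fisher+Bonferroni combination is a declared convention: other
  local tests (chi-square components, z-tests) would give different
  p-values on the same expected counts.
- Quantile bands use the percentile bootstrap; no studentization, so
  very small PSU counts per group (< ~20) make the bands optimistic.
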