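# Methods

## Coordinate and data conventions

All pixel coordinates are at 20× magnification, origin top-left. Patches are
1792 px squares (448 px at 5×; scale factor 4) and every patch/tile interval
is half-open, `[x0, x0 + side)`, so the 4×4 tile grid partitions a patch
exactly and a nucleus on a shared edge belongs to exactly one tile. Physical
resolution (µm/px) is deliberately out of scope: every rule operates on
counts inside fixed pixel windows. Nuclei classes are normalised to
{neoplastic, lymphocyte, stromal, necrotic, other}; a PanNuke-style detector
vocabulary is mapped by default (inflammatory → lymphocyte, connective →
stromal, dead → necrotic, non-neoplastic epithelial → other) and unknown
classes are a hard error, never silently dropped. "Lymphocyte" is therefore
operationally "inflammatory nucleus" — an accepted proxy, overridable via
`class_mapping`.

## Tile scoring

Thresholds (`ScoringThresholds`, all counts per 448 px tile): validity ≥ 10
nuclei; TILs ≥ 20 neoplastic and ≥ 5 lymphocytes; sTILs ≥ 5 lymphocytes and
stromal > neoplastic (strict); necrosis flag ≥ 15 necrotic nuclei,
independent of the TILs/sTILs category. Invalid tiles contribute to no
category and never carry the necrosis flag. The TILs and sTILs definitions
can both hold (e.g. 20 neoplastic, 25 stromal, 5 lymphocytes); stroma
dominance is evaluated first, because "stromal outnumbering neoplastic"
marks the tile as stroma-dominant tissue — `stils_precedence=False` flips
the precedence. Comparisons are ≥ for the count thresholds and strict >
for stroma dominance. Nuclei outside every labelled patch are ignored.

## Patient features

For each scope (the four retained patterns and `overall`) and signal
(TILs/sTILs/necrotic tile counts per patch) the package reports
min/max/mean/population-SD, named presence/density/abundance/dispersion.
The naming (max as "density") follows the field's convention for this
marker and is isolated in one constant. Choices worth making explicit:

- **Micropapillary** is excluded by default from the pattern scopes *and*
  from `overall` (`exclude_micropapillary=False` restores it): the pattern
  is rare and its counts noisy; percentages `pct_*` always keep all five
  patterns and sum to 100 over tumour patches.
- **Absent scope → zero-fill**: a patient without, say, papillary patches
  gets 0 for all papillary features. Absence of a pattern means zero
  observed immune tiles in it; this keeps the design matrix complete
  without imputation. It is a modelling choice, not an observed zero.
- **Population SD** (divisor n) so single-patch scopes give dispersion 0
  rather than NaN.
- Mean and SD are computed from exact integer sums (`S/n`,
  `sqrt((nQ − S²)/n²)`), making the aggregation a bit-reproducible function
  of the count multiset; the brute-force test oracle recomputes the same
  closed forms from raw nuclei by pure-Python enumeration.

Feature selections for modelling: `overall` (12), `gps_tils` (48 = 4
patterns × 12, the marker), each optionally + the 5 percentages, and
`gps_tils+grade` (ordinal grade 1–3; patients with unknown grade are
dropped from that selection only). The TCR utility normalises Shannon
diversity H = −Σ pᵢ ln pᵢ by ln(1 + TILs abundance); the natural log and
the +1 offset (keeping the denominator positive for abundance ≤ 1) are an
interpretation, stated here because the convention is not fixed elsewhere.

## Grading

Base grade by predominant pattern (lepidic → 1; acinar/papillary → 2;
solid/micropapillary → 3), upgraded to 3 when solid + micropapillary ≥ 20 %.
Predominance ties break toward the higher-grade pattern (conservative:
upgrades risk). Percentages are over patch counts, identical to area
percentages for equal-sized patches. Grades derived from predicted
percentages and grades parsed from reports are kept as separate columns.

## Survival protocol

Overall survival is right-censored at 60 months (`time' = min(time, 60)`,
events beyond the horizon cleared; an event at exactly 60 is kept). The Cox
model is fitted with lifelines (`CoxPHFitter`, L2 penalty 0.1 by default —
48 features on ~150 discovery patients are ill-conditioned unpenalised; on
a convergence failure the penalty escalates ×10 up to twice; constant
columns get coefficient 0). Features are z-scored with discovery-fold
statistics so the penalty treats them symmetrically. Cross-validation is a
seeded patient-level 2-fold split without event stratification; a fold
without events is an error suggesting a different seed. Each validation
patient receives the linear predictor as risk score and a group from the
discovery fold's median (at or below → low risk). Harrell's C counts a pair
as comparable when the strictly shorter time is an event (time ties are not
compared) and scores tied risks ½; the in-package implementation is
broadcast-vectorised and is checked exactly against an O(n²) enumeration
oracle and against lifelines. Kaplan–Meier curves come from lifelines; the
two-group log-rank statistic (hypergeometric variance, χ²₁) is implemented
in-package and agrees with lifelines to < 1e-6. The permutation test
permutes pooled out-of-fold group labels against the fixed (time, event)
pairs, with the add-one estimate p = (1 + #{perm ≥ obs})/(n_perm + 1),
floor 1/(n_perm+1).

### Known limitation: pooled permutation on cross-validated groups

The label-permutation test is exact when labels are independent of
outcomes. Cross-validated groups violate this subtly: fold A's labels come
from a model trained on fold B's outcomes and vice versa (the
pre-validation effect). Measured on 200 null cohorts (n = 300, all hazard
coefficients zero), the pooled test rejects at p ≤ 0.05 in ~13 % of
replicates instead of 5 %, while the mean out-of-fold C-index stays at
0.50. The inflation is unchanged by fold-stratified permutation and by the
ridge strength (the median split uses only score ranks), and disappears
when the labels come from a model trained on an independent cohort —
confirming the mechanism. `permutation_p_refit` provides an exact
alternative that permutes outcomes against features and reruns the entire
cross-validation per permutation; it costs 2·n_perm Cox fits and is meant
for final confirmatory analyses, not replicate studies. The pooled scheme
remains the default because it is the published protocol; its p-values
should be read as moderately anti-conservative near the threshold.

### Adjustment and confounders

The multivariate Cox adjustment fits the full cohort (risk score as
continuous value or binary group; age continuous; sex/smoking binary; stage
ordinal I–IV by default, dummy coding optional; unknown stage dropped) and
reports HR with Wald 95 % CI. Collinear or constant designs are rejected
naming the offending columns. The confounder battery uses Spearman
correlation for continuous variables, Mann–Whitney U plus pooled-SD
Cohen's d for binary, and one-way ANOVA with η² for multi-level factors;
single-level variables are skipped with a warning. A permutation feature
importance (mean C-index drop over column shuffles on a full fit) stands in
for model-attribution methods.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
histomorphology. Per patient: 1 slide (85 %) or 2 (15 %); per slide,
Poisson(40)∨5 patches on a non-overlapping grid, ~10 % non-tumour; tumour
patch patterns drawn from a patient-specific Dirichlet composition with
α = (1.0, 1.5, 1.0, 0.2, 1.0) over (lepidic, acinar, papillary,
micropapillary, solid) — acinar-leaning, micropapillary rare. Each tile
draws independent Poisson counts per class around per-pattern base
intensities (e.g. neoplastic 14/tile in lepidic vs 35 in solid, lymphocyte
4–5, stromal 6–10, necrotic 0.5–4), multiplied by patient-level log-normal
factors: lymphocyte SD 0.6 (plus a per-pattern wiggle of SD 0.25), stromal
0.3, necrotic 0.6. These levels put the tile thresholds in the informative
range — most tiles pass the 10-nucleus validity bar, and the 20-neoplastic
and 5-lymphocyte bars are crossed by a latent-dependent fraction of tiles.
Nuclei are placed uniformly within their tile; the downstream computation
uses only per-tile counts, so within-tile texture is irrelevant, and a
counts-only generation path skips coordinate placement for replicate
studies (both paths are asserted identical). Survival is exponential with
log-hazard β·(u_lymph, u_stromal, u_necro) on the latent log-multipliers —
the simplest model consistent with Cox PH downstream — censored by
min(Uniform(0, 120), 60) months; baseline hazard 0.012/month yields ~45 %
events within the horizon. The null preset has all β = 0; the strong preset
β = (−1.5, 0, 1.0) implies a hazard ratio of ≈ e^0.9 ≈ 2.5 per SD of
log-infiltration — a strong but plausible protective effect. Clinical
covariates (age, sex, stage, smoking) are independent of the hazard by
construction, so the confounder battery's null behaviour is testable; the
reported grade mimics pattern-based grading with 15 % disagreement and 10 %
unknown.

What passing tests on these cohorts do **not** show: robustness to
detector/classifier error structure (misclassified nuclei, patch-label
noise), spatially correlated infiltration within slides, non-exponential
hazards, or informative censoring. The generator is a correctness and
calibration harness, not a realism claim.

## Problem sizes and numerical choices

Replicate studies use n = 300 patients with the counts-only generation
path and 200 permutations per test (resolution 1/201, ample for a 0.05
threshold); oracle-equivalence checks use 50-patient cohorts with ~10
patches/slide for the pure-Python enumeration and 100 random instances of
n ≤ 200 for the concordance oracle; the strong-effect recovery uses three
n = 300 cohorts and one n = 500 cohort for the adjusted hazard ratio.
Tie-breaks and degenerate inputs: scores exactly at the median cutoff go to
the low-risk group; empty tiles count zero; a cohort where every patient
lands on one side of every cutoff yields a degenerate report (log-rank 0,
p 1) rather than an error; permutation p-values never reach 0 by the
add-one convention. All randomness flows from explicit integer seeds
through `numpy.random.default_rng`; identical config + seed reproduces
every artifact byte-for-byte.
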