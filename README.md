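# gpstils

Growth-pattern-specific tumour-infiltrating-lymphocyte (GPS-TILs) scoring and
survival stratification for lung adenocarcinoma (LUAD).

## The problem

LUAD tumours are graded from their architectural growth patterns (lepidic,
acinar, papillary, micropapillary, solid), but three-tier grading stratifies
survival poorly, especially for intermediate-grade tumours. Immune
infiltration carries prognostic signal of its own, and its meaning depends on
*where* the lymphocytes sit — which growth pattern they infiltrate.
`gpstils` turns two routinely produced machine outputs — per-slide nuclei
detections (centroid + cell class at 20×) and per-patch growth-pattern
labels — into a patient-level, pattern-resolved immune marker and a
cross-validated survival stratification. No images are touched: the inputs
are plain CSV/TSV tables.

## The marker

Each classified 1792 px tissue patch is split into a 4×4 grid of 448 px
tiles. A tile with fewer than 10 nuclei is not considered. Otherwise it is

- **sTILs** if it has ≥ 5 lymphocytes and strictly more stromal than
  neoplastic nuclei (stroma dominance is evaluated first),
- **TILs** if it has ≥ 20 neoplastic nuclei and ≥ 5 lymphocytes,
- **neither** otherwise; independently it is flagged **necrotic** when it
  has ≥ 15 necrotic nuclei.

Per patch this gives a three-feature vector *(n_TILs, n_sTILs, n_necrotic)*.
Per patient and per scope *s* ∈ {lepidic, acinar, papillary, solid, overall}
the per-patch counts *x₁…x_m* of each signal are summarised by

  presence = min xᵢ, density = max xᵢ, abundance = x̄, dispersion = population SD,

giving 5 scopes × 3 signals × 4 statistics = 60 features plus the five
growth-pattern percentages (micropapillary is excluded from the feature
scopes by default because of its scarcity; the 48 pattern-specific features
are the GPS-TILs marker). Survival analysis follows a fixed protocol:
overall survival right-censored at 60 months; ridge-penalised Cox PH model,
two-fold patient-level cross-validation; each patient scored out-of-fold;
groups split at the discovery fold's median (at or below → low risk); pooled
Kaplan–Meier curves, Harrell's C-index, and a 1,000-permutation log-rank
test. IASLC-style grades (predominant pattern, ≥ 20 % high-grade upgrade)
provide the baseline comparison, and a synthetic cohort generator makes the
whole chain testable end to end.

## Worked example

```bash
python examples/04_survival_stratification.py
```

generates 200 synthetic patients with a strong protective infiltration
effect and prints:

```
out-of-fold C-index: 0.666 +/- 0.017
log-rank statistic:  25.92
permutation p-value: 0.000999 (1000 permutations)
KM low-risk survival at 60 months: 0.60 (n=108)
KM high-risk survival at 60 months: 0.23 (n=92)

multivariate Cox adjustment (HR [95% CI], p):
  risk_score    1.64 [1.38, 1.96]  p=3.6e-08
  age           0.98 [0.96, 1.00]  p=0.0189
  sex_male      1.03 [0.67, 1.57]  p=0.904
  stage         1.07 [0.85, 1.35]  p=0.565
```

A C-index of 0.666 means two thirds of comparable patient pairs are ranked
correctly by the out-of-fold risk score; the permutation p sits at the
resolution floor 1/1001; the low-risk group retains 60 % survival at five
years against 23 % in the high-risk group; and the marker's hazard ratio
stays clearly above 1 after adjusting for age, sex and stage. The other
examples (`examples/01…05`) walk through tile scoring, feature aggregation,
grading and null calibration individually.

There is also a thin CLI:

```bash
gpstils simulate --n-patients 100 --seed 1 --out cohort/
gpstils pipeline --nuclei cohort/nuclei.csv --patches cohort/patches.csv \
    --clinical cohort/clinical.tsv --slide-map cohort/slide_map.csv \
    --seed 1 --out run/
```

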