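"""Cross-validated risk stratification on a simulated cohort.

Generates 200 patients with a strong protective infiltration effect,
runs the full pipeline (tile scoring -> GPS-TILs features -> two-fold
cross-validated Cox risk scores -> discovery-median stratification ->
pooled Kaplan-Meier + permutation-tested log-rank), and prints the
stratification report plus the adjusted marker effect.
"""

import pandas as pd

from gpstils import (CohortConfig, PipelineConfig, generate_cohort,
                     multivariate_cox, right_censor, run_pipeline)
from gpstils.simulate import STRONG_EFFECT_BETAS

cohort = generate_cohort(CohortConfig(n_patients=200, seed=8,
                                      hazard_betas=STRONG_EFFECT_BETAS))
config = PipelineConfig(random_seed=8, n_permutations=1000)
artifacts = run_pipeline(cohort.nuclei, cohort.patches, cohort.clinical,
                         cohort.slide_map, config)

report = artifacts["report"]
print("out-of-fold C-index: "
      f"{report.cv.cindex_mean:.3f} +/- {report.cv.cindex_sd:.3f}")
print(f"log-rank statistic:  {report.logrank_statistic:.2f}")
print(f"permutation p-value: {report.permutation_pvalue:.4g} "
      f"({report.n_permutations} permutations)")
for group, curve in report.km_curves.items():
    print(f"KM {group}-risk survival at 60 months: {curve['survival'].iloc[-1]:.2f} "
          f"(n={int(curve['at_risk'].iloc[0])})")

# adjust the continuous risk score for age, sex and stage
rec = right_censor(cohort.clinical, config.censor_horizon_months)
clin = rec.set_index("patient_id").loc[report.cv.assignments.index]
mv = multivariate_cox(pd.DataFrame({
    "os_months": clin["os_months"], "os_event": clin["os_event"],
    "risk_score": report.cv.assignments["risk_score"],
    "age": clin["age"].astype(float),
    "sex_male": (clin["sex"] == "male").astype(float),
    "stage": clin["stage"].map({"I": 1, "II": 2, "III": 3, "IV": 4}).astype(float),
}))
print("\nmultivariate Cox adjustment (HR [95% CI], p):")
for cov, r in mv.iterrows():
    print(f"  {cov:12s} {r.HR:5.2f} [{r.CI95_low:.2f}, {r.CI95_high:.2f}]  p={r.p:.3g}")
# A C-index well above 0.5 and a permutation p at the resolution floor
# indicate the simulated infiltration effect is recovered; the risk
# score stays prognostic after adjusting for the clinical covariates.
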