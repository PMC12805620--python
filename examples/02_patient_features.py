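"""Aggregate scored patches into the growth-pattern-specific feature set.

Simulates a 12-patient cohort, scores every patch, and prints one
patient's pattern percentages and TILs features.  presence/density/
abundance/dispersion are the min/max/mean/SD of per-patch tile counts.
"""

from gpstils import CohortConfig, generate_cohort, score_patches
from gpstils.features import aggregate_cohort

cohort = generate_cohort(CohortConfig(n_patients=12, seed=3, patches_per_slide_mean=15))
scored = score_patches(cohort.nuclei, cohort.patches)
features = aggregate_cohort(scored, cohort.slide_map)

pid = features.index[0]
row = features.loc[pid]
print(f"patient {pid}: {features.shape[1]} features")
print("\ngrowth-pattern percentages (of tumour patches):")
print(row.filter(like="pct_").round(1).to_string())
print("\noverall TILs statistics (tile counts per patch):")
print(row.filter(like="overall_tils").round(2).to_string())
print("\nlepidic-scope TILs statistics (0 if the patient has no lepidic patches):")
print(row.filter(like="lepidic_tils").round(2).to_string())
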