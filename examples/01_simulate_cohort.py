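"""Simulate a two-group resting-state cohort with planted group effects.

Builds the default study design — 28 patients and 28 controls, 220 volumes
at TR 3.2 s, 40 ROIs in four communities, ten seed-target edges whose
correlation is 0.3 higher in patients — and prints what was planted and how
well a single subject's empirical correlations track the target.
"""

import numpy as np

from roinet import build_group_covariance, default_study_spec, simulate_cohort

spec = default_study_spec(master_seed=7)
print(f"cohort: 2 x {spec.n_per_group} subjects, "
      f"{spec.n_timepoints} volumes @ TR {spec.tr}s, {spec.n_rois} ROIs")
print("planted patient-minus-control correlation deltas:")
for eff in spec.planted_effects:
    print(f"  {eff.seed} -- {eff.target}: {eff.delta:+.2f}")

cohort = simulate_cohort(spec)
cov = build_group_covariance(spec, "patient")
corr = cov / np.sqrt(np.outer(np.diag(cov), np.diag(cov)))

# first patient subject: compare one planted edge's empirical correlation
ts = cohort.subjects[spec.n_per_group]  # patients follow the controls
i = spec.roi_labels.index(spec.planted_effects[0].seed)
j = spec.roi_labels.index(spec.planted_effects[0].target)
r = np.corrcoef(ts.values[:, i], ts.values[:, j])[0, 1]
print(f"\nsubject {ts.subject_id} ({cohort.groups[spec.n_per_group]}): "
      f"empirical r = {r:.3f} vs target {corr[i, j]:.3f} on the first planted edge")
print("(sampling noise at T=220 is roughly 1/sqrt(T-3) ~ 0.07 on the z scale,"
      " before the nuisance contamination is removed)")
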