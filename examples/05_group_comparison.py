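"""Edge-wise group inference: recover the planted group differences.

Runs the full FUN chain on one simulated cohort and compares patients to
controls edge by edge (pooled two-sample t on Fisher-z values, BH-FDR over
all tested seed-target connections, retained at p-FDR < 0.05).
"""

from roinet import (
    DenoiseConfig,
    SeedRestriction,
    default_study_spec,
    denoise_subject,
    edgewise_group_comparison,
    fisher_z,
    functional_connectivity,
    simulate_cohort,
)

spec = default_study_spec(master_seed=1)
cohort = simulate_cohort(spec)
mats = [
    fisher_z(functional_connectivity(denoise_subject(ts, cf, DenoiseConfig())[0]))
    for ts, cf in zip(cohort.subjects, cohort.confounds)
]
seeds = sorted({e.seed for e in spec.planted_effects}, key=spec.roi_labels.index)
table = edgewise_group_comparison(mats, cohort.groups, SeedRestriction(seeds=seeds))

sig = table[table["significant"]]
planted = {frozenset((e.seed, e.target)) for e in spec.planted_effects}
hits = sum(frozenset((s, t)) in planted for s, t in zip(sig["seed"], sig["target"]))
print(f"tested connections: {len(table)}")
print(f"retained at p-FDR < 0.05: {len(sig)} "
      f"({hits} of {len(planted)} planted edges, {len(sig) - hits} false)")
print("\nretained connections (t > 0 means stronger in patients):")
cols = ["seed", "target", "t", "p", "p_fdr"]
print(sig[cols].round(4).to_string(index=False))
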