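"""MACC matrix and the cohort-level alignment test.

Generates a cohort of 8 patients (1 remote) x 4 orientation-field
connectomes with 20 degrees of angular jitter, builds the MACC matrix,
aggregates to patient level and runs the one-sample t-test, then compares
the observed mean against the Monte-Carlo chance level of the metric.
"""

from recurtrack import (
    SyntheticCohortConfig,
    TrackingParams,
    build_macc_matrix,
    chance_level,
    connectome_level,
    generate_cohort,
    one_sample_test,
    patient_level,
)

cfg = SyntheticCohortConfig(n_patients=8, n_connectomes=4, n_remote=1,
                            angular_jitter_deg=20.0, rng_seed=2)
cohort = generate_cohort(cfg)
params = TrackingParams(target_count=100, rng_seed=2)
matrix = build_macc_matrix(cohort.patients, cohort.connectomes, params,
                           metric="abs_pearson")

print(f"MACC matrix: {matrix.values.shape[0]} patients x "
      f"{matrix.values.shape[1]} connectomes, "
      f"{matrix.n_entries} analyzed entries, remote: {sorted(matrix.remote_ids)}")

pl = patient_level(matrix)  # remote patient excluded by default
print(f"patient-level MACCs (n = {len(pl)}): "
      + ", ".join(f"{v:.3f}" for v in pl))

res = one_sample_test(pl.to_numpy(), null_mean=0.0)
print(f"one-sample t-test vs 0: mean = {res.mean:.3f}, SD = {res.sd:.3f}, "
      f"t({res.df}) = {res.t_stat:.1f}, p = {res.p_two_sided:.2g}, "
      f"95% CI ({res.ci95_low:.3f}, {res.ci95_high:.3f}), d = {res.cohens_d:.2f}")

_, grand, sd = connectome_level(matrix)
print(f"connectome-level grand mean = {grand:.3f} (SD {sd:.4f}) "
      "- low SD means the result barely depends on which connectome is used")

mean_chance, _ = chance_level("abs_pearson", n_draws=200_000, rng_seed=0)
print(f"chance level of |r| for random 3-vectors: {mean_chance:.3f} (analytic 2/pi)")
# a mean MACC well above chance indicates fibers align with tumor progression
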