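"""Condition one subject's signals and inspect the connectivity structure.

Preprocessing order: per-ROI linear detrend, regression of the signal
common to all ROIs, zero-phase band-pass (0.018 Hz up to just below
Nyquist).  The common-signal regression removes the shared nuisance the
generator added but also pushes correlations negative - the classic
anticorrelation side effect, visible below in the inter-module mean.
"""

from sadnet import (
    PARADIGMS,
    PreprocessConfig,
    correlation_matrix,
    default_ground_truth,
    edge_groups,
    group_mean_matrix,
    preprocess_set,
    simulate_cohort,
)

spec = default_ground_truth()
cohort = simulate_cohort(spec, seed=1)

matrices = []
for sub in cohort.subjects:
    clean = preprocess_set(sub.timeseries[PARADIGMS[0]], PreprocessConfig())
    matrices.append(correlation_matrix(clean))
print("preprocessing:", preprocess_set(cohort.subjects[0].timeseries[PARADIGMS[0]]).processing)

mean = group_mean_matrix(matrices)
groups = edge_groups(mean, spec.planted_partition)
print(f"\ngroup-mean connectivity over {len(matrices)} subjects ({PARADIGMS[0]}):")
for name, entry in groups.items():
    print(f"  {name:8s} {entry['count']:4d} edges   mean r = {entry['mean']:+.3f} (SEM {entry['sem']:.3f})")
print(
    "\nwithin-module means are positive, the inter-module mean negative - "
    "the planted two-module structure, amplified by common-signal regression."
)
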