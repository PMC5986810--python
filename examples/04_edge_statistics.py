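"""Test which hub edges carry a paradigm x sadness-intensity interaction.

For each connector hub the 19 incident edges get a mixed ANOVA on their
correlation values (factors paradigm and group, subject as blocking
factor), FDR-corrected across edges.  The generator plants a
high-sadness-only shift on sACCl-dlPFCl (-0.30) and sACCl-mFPl (+0.20)
in the sadness paradigm, so those two edges should survive FDR.  An
occasional extra edge can reach significance: a group-specific shift on
sACCl also moves the common signal of that cell, which the regression
step spreads thinly over the remaining edges.
"""

from sadnet import (
    PARADIGMS,
    PreprocessConfig,
    correlation_matrix,
    default_ground_truth,
    edge_condition_tests,
    preprocess_set,
    simulate_cohort,
)

spec = default_ground_truth()
cohort = simulate_cohort(spec, seed=1)

by_subject = {}
groups = {}
for sub in cohort.subjects:
    groups[sub.subject_id] = sub.group
    by_subject[sub.subject_id] = {
        p: correlation_matrix(preprocess_set(sub.timeseries[p], PreprocessConfig()))
        for p in PARADIGMS
    }

for hub in ("dlPFCl", "mFPl"):
    table = edge_condition_tests(by_subject, hub, groups)
    sig = table[table["significant"]]
    print(f"\n{hub}: {len(table)} edges tested, {len(sig)} FDR-significant")
    cols = ["roi", "F_interaction", "p_interaction", "p_fdr"]
    print(sig[cols].round(5).to_string(index=False))
    for _, row in sig.iterrows():
        d_high = row[f"mean_r[high-sadness|{PARADIGMS[1]}]"] - row[f"mean_r[high-sadness|{PARADIGMS[0]}]"]
        d_low = row[f"mean_r[low-sadness|{PARADIGMS[1]}]"] - row[f"mean_r[low-sadness|{PARADIGMS[0]}]"]
        print(
            f"  {hub}-{row['roi']}: paradigm shift {d_high:+.3f} in high-sadness vs "
            f"{d_low:+.3f} in low-sadness (paired-t p = {row['paired_t_p[high-sadness]']:.2g} / "
            f"{row['paired_t_p[low-sadness]']:.2g})"
        )
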