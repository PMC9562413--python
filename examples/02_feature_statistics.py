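"""Extract per-beat timing features and test their association with SBP.

Runs the full cohort through detection and feature extraction, aggregates
per-session medians, and prints Pearson/Spearman correlations of each
interval with cuff SBP plus the robust (Huber) trend slope.
"""

from cuffless import SynthConfig, build_dataset, generate_cohort, preprocess_record, \
    segment_cycles
from cuffless.analysis_stats import correlate_feature_sbp, summarize_distribution
from cuffless.features import FEATURE_NAMES, aggregate_medians

annotated = []
for record, _ in generate_cohort(SynthConfig(n_subjects=10, seed=42)):
    anns = segment_cycles(preprocess_record(record))
    annotated.append(({"subject_id": record.subject_id, "state": record.state,
                       "repetition": record.repetition, "sbp": record.sbp}, anns))

ds = build_dataset(annotated)
med = aggregate_medians(ds)
print(f"{len(ds)} per-beat feature records -> {len(med)} per-session medians\n")

print(f"{'feature':10s} {'pearson r':>10s} {'p':>9s} {'spearman r':>11s} "
      f"{'huber slope':>12s}")
for feature in FEATURE_NAMES:
    a = correlate_feature_sbp(med[feature].to_numpy(), med["sbp"].to_numpy(), feature)
    print(f"{feature:10s} {a.r_pearson:10.3f} {a.p_pearson:9.1e} "
          f"{a.r_spearman:11.3f} {a.huber_slope:12.3f}")

s = summarize_distribution(med.loc[med.state == "rest", "s1j_ms"].to_numpy(),
                           feature="s1j_ms", state="rest")
print(f"\nrest-state S1-J: mean={s.mean:.1f} ms sd={s.sd:.1f} ms "
      f"Shapiro W={s.shapiro_w:.3f} (p={s.shapiro_p:.2f})")
print("\nNegative correlations for the S1-anchored intervals are the method's "
      "physiological core:\nhigher systolic pressure shortens the delay between "
      "the first heart sound and the\nballistocardiogram's I/J/K recoil complex. "
      "The Huber slope (mmHg change per ms of\ninterval) is the robust version of "
      "the trend an ordinary least-squares line would fit.")
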