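"""Estimate SBP with the four regression families on gated datasets.

Reproduces the evaluation protocol: two-SD outlier gates build the D1/D2
datasets, subjects are split 17/4 so no person's beats leak between train
and test, and each model is scored with EVS, R^2, MAE, MSE on the held-out
subjects.  The forest's mean-decrease-in-impurity importances rank the
features.
"""

import numpy as np

from cuffless import SynthConfig, build_dataset, generate_cohort, preprocess_record, \
    segment_cycles
from cuffless.features import FEATURE_NAMES
from cuffless.regress import run_experiment, summary_table

annotated = []
for record, _ in generate_cohort(SynthConfig(seed=42)):
    anns = segment_cycles(preprocess_record(record))
    annotated.append(({"subject_id": record.subject_id, "state": record.state,
                       "repetition": record.repetition, "sbp": record.sbp}, anns))
ds_raw = build_dataset(annotated)
print(f"raw dataset: {len(ds_raw)} per-beat records from "
      f"{len(ds_raw.subjects)} subjects\n")

reports = []
for gate in ("D1", "D2"):
    reports.extend(run_experiment(ds_raw, gate, seed=42))
print(summary_table(reports).to_string(index=False, float_format=lambda v: f"{v:.3f}"))

rf = next(r for r in reports if r.model == "RF" and r.gate == "D2")
order = np.argsort(rf.mdi_importances)[::-1]
print("\nRF (D2) feature importances (MDI):")
for idx in order[:5]:
    print(f"  {FEATURE_NAMES[idx]:10s} {rf.mdi_importances[idx]:.3f}")
print(f"\nRF D2 signed error: {rf.mean_error:+.2f} +- {rf.sd_error:.2f} mmHg "
      f"on {rf.n_test} held-out beats")
print("\nMAE is in mmHg; R^2/EVS near 1 mean the held-out subjects' pressures are "
      "recovered\nfrom beat timing alone.  The importance ranking shows which "
      "intervals the forest\nactually uses -- with the default generator the "
      "SBP-coupled S1-anchored intervals\ndominate.")
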