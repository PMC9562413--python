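"""Simulate one subject's recordings and detect heart-sound / BCG-wave events.

Builds a small synthetic cohort (one subject, three states, two repetitions),
runs the band-pass preprocessing and the cycle-by-cycle event search, and
prints detection accuracy against the generator's ground truth.
"""

import numpy as np

from cuffless import SynthConfig, generate_cohort, preprocess_record, segment_cycles

cfg = SynthConfig(n_subjects=1, duration_s=20.0, seed=42)
pairs = generate_cohort(cfg)
print(f"{len(pairs)} records (1 subject x 3 states x 2 repetitions)\n")

for record, truth in pairs:
    annotations = segment_cycles(preprocess_record(record))
    complete = [a for a in annotations if a.complete]
    j_err = []
    for a in complete:
        b = int(np.argmin(np.abs(truth.j - a.t_j)))
        j_err.append(abs(a.t_j - truth.j[b]) * 1e3)
    print(f"{record.record_id:22s} SBP={record.sbp:6.1f} mmHg  "
          f"beats={truth.n_beats:3d}  complete={len(complete):3d}  "
          f"median |J error|={np.median(j_err):.2f} ms")

print("\nEach line is one 20 s recording: 'complete' counts heartbeats where "
      "all five events\n(S1, I, J, K, S2) were found; the J error compares the "
      "detected BCG J peak with the\ngenerator's ground-truth time -- "
      "sub-millisecond agreement means the zero-phase\nfiltering and peak "
      "search do not bias beat timing.")
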