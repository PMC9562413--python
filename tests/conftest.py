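"""Shared fixtures: small cohorts and detection helpers.

Heavy cohort fixtures are session-scoped so the detection-accuracy,
correlation-sign, and regression tests all reuse one generated cohort.
"""

from __future__ import annotations

import numpy as np
import pytest

from cuffless import (DetectorConfig, SynthConfig, build_dataset, generate_cohort,
                      preprocess_record, segment_cycles)

#: One fixed cohort seed used across the suite.
COHORT_SEED = 7


def detect_cohort(pairs, det_cfg: DetectorConfig | None = None):
    """Run preprocessing + detection over (record, truth) pairs.

    Returns (annotated, matches) where ``annotated`` feeds build_dataset and
    ``matches`` is a list of per-beat dicts comparing detected event times
    with ground truth (matched by nearest J within 50 ms).
    """
    annotated = []
    matches = []
    for rec, truth in pairs:
        pre = preprocess_record(rec)
        anns = segment_cycles(pre, det_cfg or DetectorConfig())
        annotated.append(({"subject_id": rec.subject_id, "state": rec.state,
                           "repetition": rec.repetition, "sbp": rec.sbp}, anns))
        complete = [a for a in anns if a.complete]
        used = set()
        for a in complete:
            b = int(np.argmin(np.abs(truth.j - a.t_j)))
            if abs(truth.j[b] - a.t_j) < 0.05 and b not in used:
                used.add(b)
                matches.append({
                    "record_id": rec.record_id,
                    "s1": a.t_s1 - truth.s1[b], "i": a.t_i - truth.i[b],
                    "j": a.t_j - truth.j[b], "k": a.t_k - truth.k[b],
                    "s2": a.t_s2 - truth.s2[b],
                    "truth_beats": truth.n_beats,
                    "det": a, "truth_idx": b, "truth": truth,
                })
        matches.append({"record_id": rec.record_id, "_n_truth": truth.n_beats,
                        "_n_matched": len(used)})
    return annotated, matches


@pytest.fixture(scope="session")
def default_cohort():
    """Full default cohort (126 records) at the suite's fixed seed."""
    return generate_cohort(SynthConfig(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def default_detection(default_cohort):
    """Detection results and raw feature dataset for the default cohort."""
    annotated, matches = detect_cohort(default_cohort)
    ds_raw = build_dataset(annotated)
    return {"annotated": annotated, "matches": matches, "ds_raw": ds_raw}


@pytest.fixture(scope="session")
def small_cohort():
    """Two-subject cohort for cheap unit checks."""
    return generate_cohort(SynthConfig(n_subjects=2, seed=COHORT_SEED))
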