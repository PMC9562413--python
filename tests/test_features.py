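"""Feature arithmetic, two-SD gates (vs brute force), and median aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cuffless.detect import CycleAnnotation
from cuffless.errors import DataError
from cuffless.features import (FEATURE_NAMES, FeatureDataset, FeatureRecord,
                               aggregate_medians, apply_gate, build_dataset,
                               compute_cycle_features)


def _cycle(s1=0.100, i=0.205, j=0.250, k=0.305, s2=0.420, a_i=-0.2, a_j=0.6, a_k=-0.3):
    return CycleAnnotation(beat_index=0, t_s1=s1, t_i=i, t_j=j, t_k=k, t_s2=s2,
                           a_i=a_i, a_j=a_j, a_k=a_k, complete=True)


def _feature_dataset(s1j_values, s1k=None, ij=None):
    records = []
    for n, v in enumerate(s1j_values):
        records.append(FeatureRecord(
            subject_id=f"S{n % 5:02d}", state="rest", repetition=1, beat_index=n,
            s1j_ms=v, js2_ms=140.0, s1i_ms=v - 45.0, is2_ms=185.0,
            s1k_ms=(s1k[n] if s1k is not None else v + 55.0), ks2_ms=85.0,
            ij_ms=(ij[n] if ij is not None else 45.0), jk_ms=55.0,
            slope_ij=20.0, slope_jk=-18.0, sbp=120.0))
    return FeatureDataset(records=records, gate="raw")


def test_interval_orientation_and_values():
    rec = compute_cycle_features(_cycle(), sbp=120.0, subject_id="S01",
                                 state="rest", repetition=1)
    assert rec.s1j_ms == pytest.approx(150.0)
    assert rec.js2_ms == pytest.approx(170.0)
    assert rec.s1i_ms == pytest.approx(105.0)
    assert rec.ij_ms == pytest.approx(45.0)
    assert rec.jk_ms == pytest.approx(55.0)
    assert len(rec.vector()) == 10


def test_slope_rise_over_run():
    c = _cycle(i=0.30, j=0.35, k=0.405, a_i=-0.2, a_j=0.6, a_k=-0.3)
    rec = compute_cycle_features(c, 120.0, "S01", "rest", 1)
    assert rec.slope_ij == pytest.approx(16.0)
    assert rec.slope_jk == pytest.approx(-16.36, abs=0.005)


def test_incomplete_cycle_rejected():
    c = _cycle()
    c.complete = False
    with pytest.raises(DataError):
        compute_cycle_features(c, 120.0, "S01", "rest", 1)


def test_interval_identities_hold_exactly(default_detection):
    ds = default_detection["ds_raw"]
    for r in ds.records[:2000]:
        assert r.s1k_ms == pytest.approx(r.s1j_ms + r.jk_ms, abs=1e-9)
        assert r.s1j_ms == pytest.approx(r.s1i_ms + r.ij_ms, abs=1e-9)
        assert r.ij_ms > 0 and r.jk_ms > 0


def test_build_dataset_counts_and_label_propagation():
    cycles = [_cycle(), _cycle(s1=1.1, i=1.205, j=1.25, k=1.305, s2=1.42)]
    incomplete = CycleAnnotation(beat_index=2)
    meta_a = {"subject_id": "S01", "state": "rest", "repetition": 1, "sbp": 118.0}
    meta_b = {"subject_id": "S02", "state": "rest", "repetition": 1, "sbp": None}
    ds = build_dataset([(meta_a, cycles + [incomplete]), (meta_b, cycles)])
    assert len(ds) == 2                      # only labeled, complete cycles
    assert all(r.sbp == 118.0 for r in ds.records)
    assert ds.provenance["S01_rest_r1"] == {"seen": 3, "complete": 2, "accepted": 2}
    assert ds.provenance["S02_rest_r1"]["accepted"] == 0


def test_gate_discards_three_sigma_outlier():
    values = [150.0] * 9
    # append a value that lands beyond two *sample* SDs of the 10-value set
    values.append(180.0)
    x = np.array(values)
    assert abs(x[-1] - x.mean()) > 2 * x.std(ddof=1)
    ds = _feature_dataset(values)
    kept = apply_gate(ds, "D1")
    assert len(kept) == 9
    assert all(r.s1j_ms == 150.0 for r in kept.records)


def test_gate_degenerate_zero_sd_keeps_all():
    ds = _feature_dataset([150.0] * 8)
    assert len(apply_gate(ds, "D1")) == 8
    assert len(apply_gate(ds, "D2")) == 8


def test_gate_requires_raw_input():
    ds = _feature_dataset([150.0, 151.0, 152.0, 200.0])
    d1 = apply_gate(ds, "D1")
    with pytest.raises(DataError):
        apply_gate(d1, "D2")


def _brute_force_gate(ds, feature_names):
    keep = np.ones(len(ds.records), dtype=bool)
    for name in feature_names:
        x = np.array([getattr(r, name) for r in ds.records])
        sd = x.std(ddof=1) if len(x) > 1 else 0.0
        if sd == 0:
            continue
        keep &= np.abs(x - x.mean()) <= 2 * sd
    return [r for r, k in zip(ds.records, keep) if k]


@settings(max_examples=40, deadline=None)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_gates_match_brute_force_and_nest(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 40))
    s1j = rng.normal(180, 15, n)
    if rng.random() < 0.2:
        s1j[:] = 150.0  # degenerate zero-spread case
    ds = _feature_dataset(list(s1j), s1k=rng.normal(235, 15, n), ij=rng.normal(45, 4, n))
    d1, d2 = apply_gate(ds, "D1"), apply_gate(ds, "D2")
    assert [r.beat_index for r in d1.records] == \
        [r.beat_index for r in _brute_force_gate(ds, ("s1j_ms",))]
    assert [r.beat_index for r in d2.records] == \
        [r.beat_index for r in _brute_force_gate(ds, ("s1j_ms", "s1k_ms", "ij_ms"))]
    assert set(r.beat_index for r in d2.records) <= set(r.beat_index for r in d1.records)


def test_gate_fraction_invariant_to_affine_rescaling():
    rng = np.random.default_rng(11)
    s1j = rng.normal(180, 15, 60)
    ds = _feature_dataset(list(s1j))
    ds_scaled = _feature_dataset(list(7.5 * s1j - 300.0))
    assert len(apply_gate(ds, "D1")) == len(apply_gate(ds_scaled, "D1"))


def test_median_robust_to_outlier():
    ds = FeatureDataset(records=[
        FeatureRecord(subject_id="S01", state="rest", repetition=1, beat_index=n,
                      s1j_ms=v, js2_ms=1, s1i_ms=1, is2_ms=1, s1k_ms=1, ks2_ms=1,
                      ij_ms=1, jk_ms=1, slope_ij=1, slope_jk=1, sbp=120.0)
        for n, v in enumerate([10.0, 12.0, 100.0])], gate="raw")
    med = aggregate_medians(ds)
    assert len(med) == 1
    assert med["s1j_ms"].iloc[0] == 12.0


def test_group_of_one_returns_its_values():
    ds = _feature_dataset([42.0])
    med = aggregate_medians(ds)
    assert med["s1j_ms"].iloc[0] == 42.0
    assert med["n_cycles"].iloc[0] == 1


@settings(max_examples=25, deadline=None)
@given(st.lists(st.floats(min_value=-1e3, max_value=1e3, allow_nan=False),
                min_size=1, max_size=30))
def test_median_matches_sorting_oracle(values):
    ds = FeatureDataset(records=[
        FeatureRecord(subject_id="S01", state="rest", repetition=1, beat_index=n,
                      s1j_ms=v, js2_ms=0, s1i_ms=0, is2_ms=0, s1k_ms=0, ks2_ms=0,
                      ij_ms=1, jk_ms=1, slope_ij=0, slope_jk=0, sbp=120.0)
        for n, v in enumerate(values)], gate="raw")
    med = aggregate_medians(ds)["s1j_ms"].iloc[0]
    s = sorted(values)
    n = len(s)
    oracle = s[n // 2] if n % 2 else 0.5 * (s[n // 2 - 1] + s[n // 2])
    assert med == pytest.approx(oracle, rel=1e-12, abs=1e-12)
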