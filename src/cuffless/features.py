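"""Per-cycle timing/slope features, outlier gating, and median aggregation.

Each complete cardiac cycle yields a 10-dimensional record: eight oriented
time intervals (earlier event to later event, in ms) between the heart
sounds S1/S2 and the BCG waves I/J/K, and the two BCG segment slopes I->J
and J->K in normalized units per second.  Record-level outlier gates then
build the two analysis datasets: D1 discards cycles whose S1-J interval is
more than two sample standard deviations from the pooled mean, and D2
additionally applies the same two-SD bound to the S1-K and I-J intervals.
A per-(subject, state, repetition) median of each feature gives the robust
"global estimate" used for the association analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .detect import CycleAnnotation
from .errors import DataError

__all__ = ["FEATURE_NAMES", "FeatureRecord", "FeatureDataset", "compute_cycle_features",
           "build_dataset", "apply_gate", "aggregate_medians"]

logger = logging.getLogger(__name__)

#: The 10 features, in canonical column order.
FEATURE_NAMES = ("s1j_ms", "js2_ms", "s1i_ms", "is2_ms", "s1k_ms", "ks2_ms",
                 "ij_ms", "jk_ms", "slope_ij", "slope_jk")

#: Features whose two-SD bound defines the D2 gate (D1 uses only the first).
D1_GATE_FEATURES = ("s1j_ms",)
D2_GATE_FEATURES = ("s1j_ms", "s1k_ms", "ij_ms")


@dataclass
class FeatureRecord:
    """One cycle's 10-feature vector plus label and provenance."""

    subject_id: str
    state: str
    repetition: int
    beat_index: int
    s1j_ms: float
    js2_ms: float
    s1i_ms: float
    is2_ms: float
    s1k_ms: float
    ks2_ms: float
    ij_ms: float
    jk_ms: float
    slope_ij: float
    slope_jk: float
    sbp: float

    def vector(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])

    def as_row(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class FeatureDataset:
    """Labeled feature records plus gating state and provenance counts.

    ``provenance`` maps record id -> dict(seen=, complete=, accepted=).
    """

    records: list[FeatureRecord]
    gate: str = "raw"
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        cols = ["subject_id", "state", "repetition", "beat_index",
                *FEATURE_NAMES, "sbp"]
        if not self.records:
            return pd.DataFrame(columns=cols)
        return pd.DataFrame([r.as_row() for r in self.records])[cols]

    def matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, y) with X of shape (n, 10) in canonical feature order."""
        X = np.array([r.vector() for r in self.records]).reshape(-1, len(FEATURE_NAMES))
        y = np.array([r.sbp for r in self.records])
        return X, y

    @property
    def subjects(self) -> list[str]:
        return sorted({r.subject_id for r in self.records})

    def acceptance_fraction(self) -> float:
        seen = sum(p["seen"] for p in self.provenance.values()) or len(self.records)
        accepted = len(self.records)
        return accepted / seen if seen else float("nan")


def compute_cycle_features(cycle: CycleAnnotation, sbp: float, subject_id: str,
                           state: str, repetition: int) -> FeatureRecord:
    """Feature vector of one complete cycle.

    Interval A-B is (t_B - t_A) * 1000 ms, oriented earlier -> later; the
    slopes are rise over run of the filtered-normalized BCG between the wave
    extrema.  Incomplete cycles are rejected outright -- no partial records.
    """
    if not cycle.complete:
        raise DataError(f"cycle {cycle.beat_index} is incomplete")
    s1, i, j, k, s2 = cycle.t_s1, cycle.t_i, cycle.t_j, cycle.t_k, cycle.t_s2
    return FeatureRecord(
        subject_id=subject_id, state=state, repetition=repetition,
        beat_index=cycle.beat_index,
        s1j_ms=(j - s1) * 1000.0,
        js2_ms=(s2 - j) * 1000.0,
        s1i_ms=(i - s1) * 1000.0,
        is2_ms=(s2 - i) * 1000.0,
        s1k_ms=(k - s1) * 1000.0,
        ks2_ms=(s2 - k) * 1000.0,
        ij_ms=(j - i) * 1000.0,
        jk_ms=(k - j) * 1000.0,
        slope_ij=(cycle.a_j - cycle.a_i) / (j - i),
        slope_jk=(cycle.a_k - cycle.a_j) / (k - j),
        sbp=sbp,
    )


def build_dataset(annotated_records: Iterable[tuple[Mapping, Sequence[CycleAnnotation]]]
                  ) -> FeatureDataset:
    """Assemble the raw (ungated) dataset from per-record annotations.

    ``annotated_records`` yields (metadata, annotations) pairs where metadata
    carries subject_id, state, repetition and the sbp label.  Records without
    a label contribute no feature rows but are counted in provenance.
    """
    records: list[FeatureRecord] = []
    provenance: dict = {}
    for meta, annotations in annotated_records:
        rid = f"{meta['subject_id']}_{meta['state']}_r{meta['repetition']}"
        complete = [a for a in annotations if a.complete]
        prov = {"seen": len(annotations), "complete": len(complete), "accepted": 0}
        provenance[rid] = prov
        sbp = meta.get("sbp")
        if sbp is None:
            logger.warning("%s: no SBP label; cycles excluded from the dataset", rid)
            continue
        for cycle in complete:
            records.append(compute_cycle_features(
                cycle, float(sbp), meta["subject_id"], meta["state"],
                int(meta["repetition"])))
        prov["accepted"] = len(complete)
    return FeatureDataset(records=records, gate="raw", provenance=provenance)


def apply_gate(ds: FeatureDataset, gate: str) -> FeatureDataset:
    """Two-SD outlier gate producing the D1 or D2 dataset.

    Mean and sample standard deviation are pooled over the whole raw dataset.
    A feature with zero spread keeps every record (the bound degenerates).
    D2's constraint set is a superset of D1's, so D2 acceptance is always a
    subset of D1 acceptance.
    """
    if ds.gate != "raw":
        raise DataError(f"gate must start from a raw dataset, got {ds.gate!r}")
    if gate not in ("D1", "D2"):
        raise DataError(f"unknown gate {gate!r}")
    gate_features = D1_GATE_FEATURES if gate == "D1" else D2_GATE_FEATURES
    if not ds.records:
        return FeatureDataset(records=[], gate=gate, provenance=dict(ds.provenance))
    kept = list(ds.records)
    values = {name: np.array([getattr(r, name) for r in ds.records])
              for name in gate_features}
    mask = np.ones(len(ds.records), dtype=bool)
    for name, x in values.items():
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        if sd == 0.0:
            continue
        mask &= np.abs(x - np.mean(x)) <= 2.0 * sd
    kept = [r for r, ok in zip(ds.records, mask) if ok]
    provenance = {rid: dict(p) for rid, p in ds.provenance.items()}
    per_record_kept: dict[str, int] = {}
    for r, ok in zip(ds.records, mask):
        rid = f"{r.subject_id}_{r.state}_r{r.repetition}"
        per_record_kept[rid] = per_record_kept.get(rid, 0) + int(ok)
    for rid, p in provenance.items():
        p["accepted"] = per_record_kept.get(rid, 0)
    return FeatureDataset(records=kept, gate=gate, provenance=provenance)


def aggregate_medians(ds: FeatureDataset) -> pd.DataFrame:
    """Per-(subject, state, repetition) median of each feature, plus SBP.

    The median over the cycles of one session is the robust global estimate
    of each feature used by the association analyses; for even group sizes
    it is the midpoint of the central order statistics.
    """
    df = ds.to_frame()
    if df.empty:
        return df
    grouped = df.groupby(["subject_id", "state", "repetition"], sort=True)
    med = grouped[list(FEATURE_NAMES)].median()
    med["sbp"] = grouped["sbp"].first()
    med["n_cycles"] = grouped.size()
    return med.reset_index()
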