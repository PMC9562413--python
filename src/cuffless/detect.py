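"""Cycle-by-cycle event search: I/J/K in the BCG, then S1/S2 in the PCG.

The search is anchored on the BCG J wave, the most prominent landmark in the
band-filtered recoil signal.  J candidates are local maxima above a
prominence threshold with a refractory spacing between successive peaks
(keeping the larger peak on conflict).  The I and K waves are the nearest
local minima before and after each J.  Heart sounds are then located on a
rectified, low-passed PCG amplitude envelope: S1 as the largest envelope
maximum in a window ending at J, and S2 as the largest envelope maximum in a
neighborhood of K.  Cycles missing any of the five events are kept but
marked incomplete so that provenance counts stay truthful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import ConfigError
from .io_signals import SignalRecord

__all__ = ["DetectorConfig", "CycleAnnotation", "detect_bcg_ijk",
           "detect_pcg_sounds", "segment_cycles", "pcg_envelope"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectorConfig:
    """Tunable windows and thresholds of the event search (all in seconds
    or normalized units)."""

    min_jj_s: float = 0.4          # refractory spacing between J peaks
    s1_search_s: float = 0.3       # window before J searched for S1
    s2_window_s: float = 0.15      # half-width around K searched for S2
    ik_search_s: float = 0.15      # how far from J the I/K minima may sit
    envelope_cutoff_hz: float = 20.0
    j_prominence: float = 0.1

    def __post_init__(self) -> None:
        for name in ("min_jj_s", "s1_search_s", "s2_window_s", "ik_search_s",
                     "envelope_cutoff_hz", "j_prominence"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be positive")
        if self.min_jj_s < 0.25:
            raise ConfigError("min_jj_s below 0.25 s would admit rates beyond 240 bpm")


@dataclass
class CycleAnnotation:
    """The five event times and three BCG amplitudes of one heartbeat.

    ``complete`` means all five events were found.  Events that were not
    found are NaN.  Enforced ordering is only t_i < t_j < t_k, t_s1 < t_j,
    t_s2 > t_j; S1 is *not* required to precede I, since with short S1->J
    delays the I wave may rise before the first heart sound ends.
    """

    beat_index: int
    t_s1: float = np.nan
    t_i: float = np.nan
    t_j: float = np.nan
    t_k: float = np.nan
    t_s2: float = np.nan
    a_i: float = np.nan
    a_j: float = np.nan
    a_k: float = np.nan
    complete: bool = False

    def as_row(self) -> dict:
        return {"beat_index": self.beat_index, "t_s1": self.t_s1, "t_i": self.t_i,
                "t_j": self.t_j, "t_k": self.t_k, "t_s2": self.t_s2,
                "a_i": self.a_i, "a_j": self.a_j, "a_k": self.a_k,
                "complete": self.complete}


def detect_bcg_ijk(bcg: np.ndarray, fs: float,
                   config: DetectorConfig | None = None) -> list[tuple]:
    """Find (t_i, t_j, t_k, a_i, a_j, a_k) triplets on a filtered, normalized BCG.

    Triplets missing I or K carry NaN in those slots.  The list may be empty
    (e.g. for a monotone input with no local maxima).
    """
    config = config or DetectorConfig()
    bcg = np.asarray(bcg, dtype=float)
    if bcg.size < 3:
        return []
    distance = max(1, int(round(config.min_jj_s * fs)))
    # find_peaks drops the smaller of two peaks closer than `distance`,
    # which realizes the greedy keep-the-larger refractory rule.
    j_idx, _ = signal.find_peaks(bcg, prominence=config.j_prominence, distance=distance)
    minima, _ = signal.find_peaks(-bcg)
    out = []
    win = int(round(config.ik_search_s * fs))
    for j in j_idx:
        before = minima[(minima < j) & (minima >= j - win)]
        after = minima[(minima > j) & (minima <= j + win)]
        i = before[-1] if len(before) else None   # nearest preceding minimum
        k = after[0] if len(after) else None      # nearest following minimum
        out.append((
            i / fs if i is not None else np.nan,
            j / fs,
            k / fs if k is not None else np.nan,
            bcg[i] if i is not None else np.nan,
            bcg[j],
            bcg[k] if k is not None else np.nan,
        ))
    return out


def pcg_envelope(pcg: np.ndarray, fs: float, cutoff_hz: float = 20.0) -> np.ndarray:
    """Rectified, zero-phase low-passed amplitude envelope of the PCG."""
    sos = signal.butter(4, cutoff_hz, btype="lowpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.abs(np.asarray(pcg, dtype=float)))


def _largest_env_peak(env: np.ndarray, peaks: np.ndarray, lo: int, hi: int) -> int | None:
    """Index of the largest envelope local maximum in [lo, hi]; ties -> earlier."""
    cand = peaks[(peaks >= lo) & (peaks <= hi)]
    if len(cand) == 0:
        return None
    best = cand[np.argmax(env[cand])]  # argmax returns the first maximal entry
    return int(best)


def detect_pcg_sounds(pcg: np.ndarray, fs: float, ijk: list[tuple],
                      config: DetectorConfig | None = None) -> list[CycleAnnotation]:
    """Locate S1 before each J and S2 near each K on the PCG envelope.

    One annotation per triplet, beat indices sequential.  A search window
    extending past the record boundary marks that cycle incomplete rather
    than raising.
    """
    config = config or DetectorConfig()
    pcg = np.asarray(pcg, dtype=float)
    n = len(pcg)
    env = pcg_envelope(pcg, fs, config.envelope_cutoff_hz)
    env_peaks, _ = signal.find_peaks(env)
    annotations = []
    for beat_index, (t_i, t_j, t_k, a_i, a_j, a_k) in enumerate(ijk):
        ann = CycleAnnotation(beat_index=beat_index, t_i=t_i, t_j=t_j, t_k=t_k,
                              a_i=a_i, a_j=a_j, a_k=a_k)
        j = int(round(t_j * fs))
        lo = j - int(round(config.s1_search_s * fs))
        s1 = None
        if lo >= 0:
            s1 = _largest_env_peak(env, env_peaks, lo, j - 1)
        if s1 is not None:
            ann.t_s1 = s1 / fs
        s2 = None
        if np.isfinite(t_k):
            k = int(round(t_k * fs))
            half = int(round(config.s2_window_s * fs))
            if k - half >= 0 and k + half < n:
                s2 = _largest_env_peak(env, env_peaks, k - half, k + half)
        if s2 is not None and s2 / fs > t_j:
            ann.t_s2 = s2 / fs
        ann.complete = bool(
            np.isfinite(ann.t_s1) and np.isfinite(ann.t_i) and np.isfinite(ann.t_j)
            and np.isfinite(ann.t_k) and np.isfinite(ann.t_s2)
            and ann.t_i < ann.t_j < ann.t_k and ann.t_s1 < ann.t_j and ann.t_s2 > ann.t_j)
        annotations.append(ann)
    return annotations


def segment_cycles(record: SignalRecord,
                   config: DetectorConfig | None = None) -> list[CycleAnnotation]:
    """Full per-record event search on a preprocessed (filtered, normalized) record."""
    config = config or DetectorConfig()
    ijk = detect_bcg_ijk(record.bcg, record.fs, config)
    if not ijk:
        logger.info("%s: no J peaks found", record.record_id)
        return []
    annotations = detect_pcg_sounds(record.pcg, record.fs, ijk, config)
    n_complete = sum(a.complete for a in annotations)
    logger.info("%s: %d cycles, %d complete", record.record_id, len(annotations), n_complete)
    return annotations
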