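"""Plain-text interchange for signal records, annotations, and result tables.

A recording is one CSV file with columns ``time,pcg,bcg`` (time in seconds,
amplitudes in arbitrary units) plus a sidecar ``<name>.meta`` file of flat
``key=value`` lines carrying subject id, protocol state, repetition, sampling
rate and -- when available -- the cuff systolic pressure in mmHg.  Desk-scale
recordings make text I/O adequate, and the format round-trips through any
generic CSV reader.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

__all__ = ["STATES", "SignalRecord", "read_record", "write_record", "write_table", "read_table"]

logger = logging.getLogger(__name__)

#: Protocol states, in measurement order.
STATES = ("rest", "activity", "post_activity")

_TIME_TOL_S = 1e-9


@dataclass
class SignalRecord:
    """One two-channel PCG/BCG recording with metadata.

    Time is stored in seconds, 0-based from record start, with a constant
    step of ``1/fs``.  ``sbp`` is the cuff systolic pressure label in mmHg
    and may be ``None`` for unlabeled records so detection and feature
    extraction can still run.
    """

    subject_id: str
    state: str
    repetition: int
    fs: float
    t: np.ndarray
    pcg: np.ndarray
    bcg: np.ndarray
    sbp: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pcg = np.asarray(self.pcg, dtype=float)
        self.bcg = np.asarray(self.bcg, dtype=float)
        if self.state not in STATES:
            raise DataError(f"unknown state {self.state!r}; expected one of {STATES}")
        if self.repetition < 1:
            raise DataError("repetition must be a positive integer")
        if not self.fs > 0:
            raise DataError("sampling rate must be positive")
        if not (len(self.t) == len(self.pcg) == len(self.bcg)):
            raise DataError("t, pcg, bcg must have equal length")
        if len(self.t) >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise DataError("time vector must be strictly increasing")
            if np.max(np.abs(dt - 1.0 / self.fs)) > _TIME_TOL_S:
                raise DataError("time step is not constant at 1/fs within 1e-9 s")
        if self.sbp is not None and not (50.0 < self.sbp < 260.0):
            raise DataError(f"sbp={self.sbp} mmHg outside the plausible (50, 260) range")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def record_id(self) -> str:
        return f"{self.subject_id}_{self.state}_r{self.repetition}"

    def with_channels(self, pcg: np.ndarray, bcg: np.ndarray) -> "SignalRecord":
        """Copy of this record with replaced channel data."""
        return replace(self, pcg=np.asarray(pcg, float), bcg=np.asarray(bcg, float))


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta")


def read_record(path: str | Path, metadata: Mapping[str, object] | None = None) -> SignalRecord:
    """Read a ``time,pcg,bcg`` CSV (plus optional sidecar) into a :class:`SignalRecord`.

    The sampling rate is inferred from the median time step; rows with any
    non-numeric cell are dropped.  Explicit ``metadata`` entries override the
    sidecar file.  If a metadata ``fs`` disagrees with the inferred rate, a
    warning is logged once and the inferred rate wins.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    for col in ("time", "pcg", "bcg"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    df = df[["time", "pcg", "bcg"]].apply(pd.to_numeric, errors="coerce").dropna()
    if len(df) < 2:
        raise DataError(f"{path}: fewer than 2 numeric rows")
    t = df["time"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise DataError(f"{path}: time column is not strictly increasing")
    fs = 1.0 / float(np.median(np.diff(t)))

    meta: dict[str, object] = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        for line in sidecar.read_text().splitlines():
            line = line.strip()
            if line and "=" in line:
                k, v = line.split("=", 1)
                meta[k.strip()] = v.strip()
    if metadata:
        meta.update(metadata)

    if "fs" in meta and not math.isclose(float(meta["fs"]), fs, rel_tol=1e-6):
        logger.warning("%s: metadata fs=%s disagrees with inferred fs=%.6g; using inferred",
                       path, meta["fs"], fs)
    sbp = meta.get("sbp")
    return SignalRecord(
        subject_id=str(meta.get("subject_id", path.stem)),
        state=str(meta.get("state", "rest")),
        repetition=int(meta.get("repetition", 1)),
        fs=fs,
        t=t - t[0],
        pcg=df["pcg"].to_numpy(),
        bcg=df["bcg"].to_numpy(),
        sbp=None if sbp in (None, "", "None") else float(sbp),
    )


def write_record(record: SignalRecord, path: str | Path) -> Path:
    """Write a record as CSV at full double precision, metadata to a sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"time": record.t, "pcg": record.pcg, "bcg": record.bcg})
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "subject_id": record.subject_id,
        "state": record.state,
        "repetition": record.repetition,
        "fs": f"{record.fs:.17g}",
    }
    if record.sbp is not None:
        meta["sbp"] = f"{record.sbp:.17g}"
    _sidecar_path(path).write_text("".join(f"{k}={v}\n" for k, v in meta.items()))
    return path


def write_table(rows: Sequence[Mapping[str, object]], path: str | Path,
                fieldnames: Sequence[str] | None = None) -> Path:
    """Write uniform key-value rows as CSV with deterministic (sorted) columns.

    All rows must share one key set; ``fieldnames`` declares the schema for an
    empty table (header-only file).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if rows:
        keys = set(rows[0].keys())
        for i, row in enumerate(rows):
            if set(row.keys()) != keys:
                raise FormatError(f"row {i} keys {sorted(row.keys())} != schema {sorted(keys)}")
        fieldnames = sorted(keys)
    elif fieldnames is None:
        raise FormatError("empty table requires an explicit fieldnames schema")
    else:
        fieldnames = sorted(fieldnames)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        for row in rows:
            writer.writerow({k: _fmt(v) for k, v in row.items()})
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a table written by :func:`write_table`."""
    return pd.read_csv(path)


def _fmt(v: object) -> object:
    if isinstance(v, float) or isinstance(v, np.floating):
        return f"{float(v):.17g}"
    return v
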