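"""Synthetic cohorts of paired PCG/BCG recordings with ground-truth events.

The generator emulates a squat-exercise measurement protocol: each subject is
recorded in three states (rest, activity, post-activity) with two repetitions
per state, and each session carries one cuff SBP label.  The physiological
coupling is deliberately minimal and explicit: the S1->J delay shrinks
linearly with SBP (negative slope), the I and K waves ride rigidly with J,
and S2 trails S1 by the systolic interval.  Everything else -- heart-rate
jitter, amplitude variability, white noise, baseline wander -- is nuisance
structure for exercising the detectors.

Beat morphology
---------------
The PCG beat is two Gaussian-windowed tone bursts (cosine carrier, default
40 Hz, inside the 34-50 Hz analysis band) centered on S1 and S2.  The BCG
beat is a triplet of Gaussian bumps (negative I, positive J, negative K).
Because wave *locations* are defined on the band-limited signal -- the
recording hardware this emulates band-limits the BCG before sampling -- the
raw triplet parameters are calibrated once per configuration so that the
band-filtered template has its I/J/K extrema exactly at the nominal offsets
(-ij_ms, 0, +jk_ms) relative to J.  Without that calibration the 1-10 Hz
band reshapes the complex and drags the flanking minima by 10-20 ms, and no
detector could agree with the stated ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize

from .errors import ConfigError
from .io_signals import STATES, SignalRecord
from .preprocess import apply_bandpass, bcg_filter_spec

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "BeatParams",
    "SubjectParams",
    "synth_cycle",
    "generate_session",
    "generate_cohort",
    "generate_planted_features",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SynthConfig:
    """Cohort-generation parameters.

    All timing couplings are in milliseconds; amplitudes are in normalized
    units (the raw record is later max-abs normalized, so only ratios
    matter).  ``s1j_slope_ms_per_mmhg`` must be negative: higher pressure
    shortens the S1->J delay, which is the qualitative behaviour the whole
    pipeline is built to recover.
    """

    # protocol structure
    n_subjects: int = 21
    states: Sequence[str] = STATES
    repetitions: int = 2
    fs: float = 1000.0
    duration_s: float = 30.0
    # blood pressure model (mmHg)
    sbp_rest_mean: float = 112.0
    sbp_rest_sd: float = 8.0
    sbp_activity_shift_mean: float = 18.0
    sbp_activity_shift_sd: float = 5.0
    sbp_post_shift_mean: float = 2.0
    sbp_post_shift_sd: float = 4.0
    # heart rate model (bpm)
    hr_rest_mean: float = 70.0
    hr_rest_sd: float = 8.0
    hr_activity_mean: float = 95.0
    hr_activity_sd: float = 10.0
    hr_post_mean: float = 78.0
    hr_post_sd: float = 8.0
    # timing couplings (ms)
    s1j_intercept_ms: float = 180.0
    s1j_slope_ms_per_mmhg: float = -1.2
    # systolic ejection time shortens under the sympathetic activation that
    # raises SBP, so S1->S2 carries its own (steeper) negative coupling and
    # the J-S2 interval inherits a net negative slope; set to 0 to decouple.
    s2_slope_ms_per_mmhg: float = -1.8
    systole_ms: float = 320.0
    systole_sd_ms: float = 15.0
    ij_ms: float = 45.0
    jk_ms: float = 55.0
    # per-beat variability
    s1j_jitter_ms: float = 4.0
    rr_jitter_ms: float = 20.0
    systole_jitter_ms: float = 2.0
    bcg_scale_sd: float = 0.10
    bcg_wave_sd: float = 0.05
    pcg_amp_sd: float = 0.10
    # waveform shape
    pcg_tone_hz: float = 40.0
    pcg_burst_sigma_s: float = 0.015
    s1_amp: float = 1.0
    s2_amp: float = 0.7
    # measurement noise
    noise_sd: float = 0.05
    wander_amp: float = 0.1
    wander_freq_hz: float = 0.3
    # layout
    edge_margin_s: float = 1.2
    end_margin_s: float = 1.0
    bcg_filter_order: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        positive = [
            ("n_subjects", self.n_subjects), ("repetitions", self.repetitions),
            ("fs", self.fs), ("duration_s", self.duration_s),
            ("sbp_rest_mean", self.sbp_rest_mean), ("hr_rest_mean", self.hr_rest_mean),
            ("hr_activity_mean", self.hr_activity_mean), ("hr_post_mean", self.hr_post_mean),
            ("s1j_intercept_ms", self.s1j_intercept_ms), ("systole_ms", self.systole_ms),
            ("ij_ms", self.ij_ms), ("jk_ms", self.jk_ms),
            ("pcg_tone_hz", self.pcg_tone_hz), ("pcg_burst_sigma_s", self.pcg_burst_sigma_s),
        ]
        for name, value in positive:
            if not value > 0:
                raise ConfigError(f"{name} must be strictly positive, got {value}")
        if not self.s1j_slope_ms_per_mmhg < 0:
            raise ConfigError("s1j_slope_ms_per_mmhg must be negative "
                              "(S1-J shortens as pressure rises)")
        unknown = set(self.states) - set(STATES)
        if unknown:
            raise ConfigError(f"unknown states {sorted(unknown)}")
        if self.systole_ms <= self.s1j_intercept_ms - self.ij_ms:
            raise ConfigError("systole must outlast the S1->I delay")

    def noiseless(self) -> "SynthConfig":
        """Copy with every per-beat noise and jitter source set to zero.

        Subject-level physiology (baseline SBP, heart rate, systole length)
        still varies; only measurement noise and beat-to-beat jitter vanish,
        so each beat is an exact template copy.
        """
        return replace(self, noise_sd=0.0, wander_amp=0.0, s1j_jitter_ms=0.0,
                       rr_jitter_ms=0.0, systole_jitter_ms=0.0, bcg_scale_sd=0.0,
                       bcg_wave_sd=0.0, pcg_amp_sd=0.0)

    def noise_equivalent_sbp_mae(self) -> float:
        """Mean absolute SBP error of an ideal single-cycle S1-J reader, mmHg.

        The per-beat S1-J jitter is Gaussian with sd ``s1j_jitter_ms``; an
        estimator inverting the linear coupling therefore makes a mean
        absolute error of ``sd * sqrt(2/pi) / |slope|``.  This is the noise
        floor against which regression performance is judged.
        """
        return (self.s1j_jitter_ms * np.sqrt(2.0 / np.pi)
                / abs(self.s1j_slope_ms_per_mmhg))


@dataclass
class GroundTruth:
    """Per-beat event times (s), BCG wave amplitudes (n.u.), and session SBP."""

    s1: np.ndarray
    i: np.ndarray
    j: np.ndarray
    k: np.ndarray
    s2: np.ndarray
    a_i: np.ndarray
    a_j: np.ndarray
    a_k: np.ndarray
    sbp: float

    @property
    def n_beats(self) -> int:
        return len(self.j)


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject physiology drawn once per cohort."""

    subject_id: str
    sbp_baseline: float
    systole_ms: float


@dataclass(frozen=True)
class BeatParams:
    """Fully-resolved timing and amplitude of one beat."""

    t_s1: float
    s1j_s: float
    systole_s: float
    bcg_scale: float = 1.0
    wave_factors: tuple[float, float, float] = (1.0, 1.0, 1.0)
    s1_amp: float = 1.0
    s2_amp: float = 0.7


# ---------------------------------------------------------------------------
# Template calibration
# ---------------------------------------------------------------------------

#: Target extremum amplitudes of the band-filtered unit-scale template.
_FILTERED_AMPS = np.array([-0.35, 0.70, -0.38])

_calibration_cache: dict[tuple, "BcgTemplate"] = {}


@dataclass(frozen=True)
class BcgTemplate:
    """Raw Gaussian-triplet parameters whose filtered extrema sit at nominal."""

    centers: tuple[float, float, float]   # offsets from J, seconds
    amps: tuple[float, float, float]
    sigmas: tuple[float, float, float]
    filtered_amps: tuple[float, float, float]

    def evaluate(self, t_rel: np.ndarray) -> np.ndarray:
        """Raw template at times relative to the J wave."""
        out = np.zeros_like(t_rel, dtype=float)
        for a, c, s in zip(self.amps, self.centers, self.sigmas):
            out += a * np.exp(-0.5 * ((t_rel - c) / s) ** 2)
        return out


def _refined_extrema(y: np.ndarray, tg: np.ndarray, nominal: np.ndarray, fs: float):
    """Sub-sample extremum positions/values near each nominal offset."""
    pos, val = [], []
    for t0, sgn in zip(nominal, (-1.0, 1.0, -1.0)):
        idx = np.where((tg > t0 - 0.025) & (tg < t0 + 0.025))[0]
        i = idx[np.argmax(sgn * y[idx])]
        denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
        d = 0.0 if denom == 0 else np.clip(0.5 * (y[i - 1] - y[i + 1]) / denom, -0.5, 0.5)
        pos.append(tg[i] + d / fs)
        val.append(y[i] - 0.25 * (y[i - 1] - y[i + 1]) * d)
    return np.array(pos), np.array(val)


def bcg_template(config: SynthConfig) -> BcgTemplate:
    """Calibrated BCG beat template for this configuration (cached).

    Solves a small least-squares problem: adjust the raw Gaussian centers,
    amplitudes, and widths so that after the configuration's BCG band-pass
    the template's extrema are at exactly (-ij_ms, 0, +jk_ms) with the
    canonical filtered amplitudes.  Deterministic; typically < 2 s, run once.
    """
    key = (round(config.fs, 6), round(config.ij_ms, 6), round(config.jk_ms, 6),
           config.bcg_filter_order)
    if key in _calibration_cache:
        return _calibration_cache[key]

    fs = config.fs
    nominal = np.array([-config.ij_ms, 0.0, config.jk_ms]) / 1000.0
    spec = bcg_filter_spec(fs, order=config.bcg_filter_order)
    tg = np.arange(-2.0, 2.0 + 0.5 / fs, 1.0 / fs)

    def build(p: np.ndarray) -> np.ndarray:
        c, a, s = p[:3], p[3:6], np.exp(p[6:9])
        x = np.zeros_like(tg)
        for aa, cc, ss in zip(a, c, s):
            x += aa * np.exp(-0.5 * ((tg - cc) / ss) ** 2)
        return apply_bandpass(x, spec)

    def resid(p: np.ndarray) -> np.ndarray:
        pos, val = _refined_extrema(build(p), tg, nominal, fs)
        return np.concatenate([(pos - nominal) * 5000.0, (val - _FILTERED_AMPS) * 10.0])

    p0 = np.concatenate([nominal, [-0.5, 0.9, -0.55], np.log([0.010, 0.013, 0.011])])
    lb = np.concatenate([nominal - 0.04, [-5.0, 0.2, -5.0], np.log([0.004] * 3)])
    ub = np.concatenate([nominal + 0.04, [-0.1, 5.0, -0.1], np.log([0.05] * 3)])
    res = optimize.least_squares(resid, p0, bounds=(lb, ub), diff_step=1e-3,
                                 xtol=1e-12, ftol=1e-12, max_nfev=500)
    pos, val = _refined_extrema(build(res.x), tg, nominal, fs)
    worst_ms = float(np.max(np.abs(pos - nominal)) * 1000.0)
    if worst_ms > 1.0:
        logger.warning("BCG template calibration residual %.2f ms for %s", worst_ms, key)
    tmpl = BcgTemplate(centers=tuple(res.x[:3]), amps=tuple(res.x[3:6]),
                       sigmas=tuple(np.exp(res.x[6:9])), filtered_amps=tuple(val))
    _calibration_cache[key] = tmpl
    return tmpl


# ---------------------------------------------------------------------------
# Beat and session synthesis
# ---------------------------------------------------------------------------

#: Half-width of a beat's waveform support, seconds.  Gaussian tails beyond
#: this are below double precision for every template this package emits.
_SUPPORT_S = 0.45


def _beat_events(sbp: float, bp: BeatParams, config: SynthConfig) -> tuple[float, ...]:
    t_j = bp.t_s1 + bp.s1j_s
    t_i = t_j - config.ij_ms / 1000.0
    t_k = t_j + config.jk_ms / 1000.0
    t_s2 = bp.t_s1 + bp.systole_s
    return bp.t_s1, t_i, t_j, t_k, t_s2


def _beat_waveforms(t: np.ndarray, sbp: float, bp: BeatParams,
                    config: SynthConfig, template: BcgTemplate):
    """Evaluate one beat's PCG and BCG contributions on an arbitrary grid."""
    t_s1, t_i, t_j, t_k, t_s2 = _beat_events(sbp, bp, config)
    sig = config.pcg_burst_sigma_s
    f0 = config.pcg_tone_hz
    pcg = (bp.s1_amp * np.exp(-0.5 * ((t - t_s1) / sig) ** 2)
           * np.cos(2.0 * np.pi * f0 * (t - t_s1))
           + bp.s2_amp * np.exp(-0.5 * ((t - t_s2) / sig) ** 2)
           * np.cos(2.0 * np.pi * f0 * (t - t_s2)))
    bcg = np.zeros_like(t)
    for a, c, s, w in zip(template.amps, template.centers, template.sigmas, bp.wave_factors):
        bcg += bp.bcg_scale * w * a * np.exp(-0.5 * ((t - t_j - c) / s) ** 2)
    return pcg, bcg


def synth_cycle(sbp: float, beat_params: BeatParams, config: SynthConfig,
                t: np.ndarray | None = None):
    """One beat's (pcg segment, bcg segment, per-beat ground truth).

    With no explicit grid the segment spans the beat's full waveform support
    on the global ``k/fs`` sample lattice, so summing segments reproduces a
    zero-noise session exactly.
    """
    if not (50.0 < sbp < 260.0):
        raise ConfigError(f"sbp={sbp} outside the plausible range")
    template = bcg_template(config)
    events = _beat_events(sbp, beat_params, config)
    t_s1, t_i, t_j, t_k, t_s2 = events
    if not (t_i < t_j < t_k and t_s1 < t_j and t_s2 > t_j):
        raise ConfigError("beat parameters violate event ordering")
    if t is None:
        k0 = int(np.ceil((t_s1 - _SUPPORT_S) * config.fs))
        k1 = int(np.floor((t_s2 + _SUPPORT_S) * config.fs))
        t = np.arange(k0, k1 + 1) / config.fs
    pcg, bcg = _beat_waveforms(t, sbp, beat_params, config, template)
    wf = beat_params.wave_factors
    truth = GroundTruth(
        s1=np.array([t_s1]), i=np.array([t_i]), j=np.array([t_j]),
        k=np.array([t_k]), s2=np.array([t_s2]),
        a_i=np.array([template.filtered_amps[0] * beat_params.bcg_scale * wf[0]]),
        a_j=np.array([template.filtered_amps[1] * beat_params.bcg_scale * wf[1]]),
        a_k=np.array([template.filtered_amps[2] * beat_params.bcg_scale * wf[2]]),
        sbp=sbp,
    )
    return pcg, bcg, truth


def _draw_beat(rng: np.random.Generator, t_s1: float, sbp: float,
               subject: SubjectParams, config: SynthConfig, max_tries: int = 100) -> BeatParams:
    """Draw per-beat jitter, resampling on (vanishingly rare) ordering violations."""
    d_sbp = sbp - config.sbp_rest_mean
    for _ in range(max_tries):
        s1j_ms = (config.s1j_intercept_ms + config.s1j_slope_ms_per_mmhg * d_sbp
                  + rng.normal(0.0, config.s1j_jitter_ms))
        systole_ms = (subject.systole_ms + config.s2_slope_ms_per_mmhg * d_sbp
                      + rng.normal(0.0, config.systole_jitter_ms))
        bp = BeatParams(
            t_s1=t_s1, s1j_s=s1j_ms / 1000.0, systole_s=systole_ms / 1000.0,
            bcg_scale=max(0.2, 1.0 + rng.normal(0.0, config.bcg_scale_sd)),
            wave_factors=tuple(np.maximum(0.3, 1.0 + rng.normal(0.0, config.bcg_wave_sd, 3))),
            s1_amp=config.s1_amp * max(0.2, 1.0 + rng.normal(0.0, config.pcg_amp_sd)),
            s2_amp=config.s2_amp * max(0.2, 1.0 + rng.normal(0.0, config.pcg_amp_sd)),
        )
        t_s1_, t_i, t_j, t_k, t_s2 = _beat_events(sbp, bp, config)
        if t_s1_ < t_j and t_i < t_j < t_k < t_s2 and t_i > t_s1_ - 0.3:
            return bp
    raise ConfigError("could not draw a beat satisfying S1<I<J<K<S2 ordering")


_STATE_HR = {
    "rest": ("hr_rest_mean", "hr_rest_sd"),
    "activity": ("hr_activity_mean", "hr_activity_sd"),
    "post_activity": ("hr_post_mean", "hr_post_sd"),
}


def generate_session(subject: SubjectParams, state: str, repetition: int,
                     sbp: float, config: SynthConfig,
                     rng: np.random.Generator) -> tuple[SignalRecord, GroundTruth]:
    """One recording: template beats at the state's heart rate plus noise."""
    fs = config.fs
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs
    mean_attr, sd_attr = _STATE_HR[state]
    hr = float(np.clip(rng.normal(getattr(config, mean_attr), getattr(config, sd_attr)),
                       40.0, 180.0))
    period = 60.0 / hr
    if config.duration_s < config.edge_margin_s + config.end_margin_s + period:
        raise ConfigError("duration too short for a single beat between the edge margins")

    template = bcg_template(config)
    pcg = np.zeros(n)
    bcg = np.zeros(n)
    beats: list[BeatParams] = []
    t_s1 = config.edge_margin_s
    while True:
        bp = _draw_beat(rng, t_s1, sbp, subject, config)
        if bp.t_s1 + bp.systole_s > config.duration_s - config.end_margin_s:
            break
        beats.append(bp)
        t_s1 += period + rng.normal(0.0, config.rr_jitter_ms / 1000.0)
    if not beats:
        raise ConfigError("duration too short for a single beat")

    for bp in beats:
        k0 = max(0, int(np.ceil((bp.t_s1 - _SUPPORT_S) * fs)))
        k1 = min(n - 1, int(np.floor((bp.t_s1 + bp.systole_s + _SUPPORT_S) * fs)))
        seg = slice(k0, k1 + 1)
        p, b = _beat_waveforms(t[seg], sbp, bp, config, template)
        pcg[seg] += p
        bcg[seg] += b

    if config.wander_amp > 0:
        for chan in (pcg, bcg):
            chan += config.wander_amp * np.sin(
                2.0 * np.pi * config.wander_freq_hz * t + rng.uniform(0.0, 2.0 * np.pi))
    if config.noise_sd > 0:
        pcg += rng.normal(0.0, config.noise_sd, n)
        bcg += rng.normal(0.0, config.noise_sd, n)

    events = [_beat_events(sbp, bp, config) for bp in beats]
    truth = GroundTruth(
        s1=np.array([e[0] for e in events]),
        i=np.array([e[1] for e in events]),
        j=np.array([e[2] for e in events]),
        k=np.array([e[3] for e in events]),
        s2=np.array([e[4] for e in events]),
        a_i=np.array([template.filtered_amps[0] * bp.bcg_scale * bp.wave_factors[0]
                      for bp in beats]),
        a_j=np.array([template.filtered_amps[1] * bp.bcg_scale * bp.wave_factors[1]
                      for bp in beats]),
        a_k=np.array([template.filtered_amps[2] * bp.bcg_scale * bp.wave_factors[2]
                      for bp in beats]),
        sbp=sbp,
    )
    record = SignalRecord(subject_id=subject.subject_id, state=state,
                          repetition=repetition, fs=fs, t=t, pcg=pcg, bcg=bcg, sbp=sbp)
    return record, truth


_STATE_SHIFT = {
    "rest": (0.0, 0.0),
    "activity": ("sbp_activity_shift_mean", "sbp_activity_shift_sd"),
    "post_activity": ("sbp_post_shift_mean", "sbp_post_shift_sd"),
}


def generate_cohort(config: SynthConfig | None = None
                    ) -> list[tuple[SignalRecord, GroundTruth]]:
    """Full cohort: ``n_subjects x len(states) x repetitions`` records.

    Per-subject baselines are drawn once; state shifts are drawn per session
    (repetitions of the activity states differ, as repeated cuff readings
    would).  Identical seed gives bit-identical output.
    """
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    out: list[tuple[SignalRecord, GroundTruth]] = []
    for s in range(config.n_subjects):
        subject = SubjectParams(
            subject_id=f"S{s + 1:02d}",
            sbp_baseline=float(np.clip(rng.normal(config.sbp_rest_mean, config.sbp_rest_sd),
                                       80.0, 200.0)),
            systole_ms=float(np.clip(rng.normal(config.systole_ms, config.systole_sd_ms),
                                     200.0, 450.0)),
        )
        for state in config.states:
            for rep in range(1, config.repetitions + 1):
                shift = _STATE_SHIFT[state]
                if shift == (0.0, 0.0):
                    d = 0.0
                else:
                    d = rng.normal(getattr(config, shift[0]), getattr(config, shift[1]))
                sbp = float(np.clip(subject.sbp_baseline + d, 70.0, 230.0))
                out.append(generate_session(subject, state, rep, sbp, config, rng))
    return out


def generate_planted_features(n_records: int = 400, n_subjects: int = 20, seed: int = 0,
                              slope_ms_per_mmhg: float = -1.2,
                              signal_feature: str = "s1j_ms"):
    """Feature-level dataset where only one feature carries SBP signal.

    Bypasses waveform synthesis: draws SBP per record and builds the
    10-feature vector with realistic scales, coupling *only*
    ``signal_feature`` to SBP (plus 2 ms jitter); every other feature is
    independent noise.  Used to check that feature-importance rankings
    recover a planted signal.
    """
    from .features import FEATURE_NAMES, FeatureDataset, FeatureRecord

    rng = np.random.default_rng(seed)
    base = {"s1j_ms": 180.0, "js2_ms": 140.0, "s1i_ms": 135.0, "is2_ms": 185.0,
            "s1k_ms": 235.0, "ks2_ms": 85.0, "ij_ms": 45.0, "jk_ms": 55.0,
            "slope_ij": 23.0, "slope_jk": -20.0}
    scale = {"s1j_ms": 8.0, "js2_ms": 8.0, "s1i_ms": 8.0, "is2_ms": 8.0,
             "s1k_ms": 8.0, "ks2_ms": 8.0, "ij_ms": 3.0, "jk_ms": 3.0,
             "slope_ij": 2.0, "slope_jk": 2.0}
    records = []
    for i in range(n_records):
        sbp = float(rng.normal(115.0, 12.0))
        values = {}
        for name in FEATURE_NAMES:
            if name == signal_feature:
                values[name] = (base[name] + slope_ms_per_mmhg * (sbp - 115.0)
                                + rng.normal(0.0, 2.0))
            else:
                values[name] = base[name] + rng.normal(0.0, scale[name])
        records.append(FeatureRecord(
            subject_id=f"S{(i % n_subjects) + 1:02d}", state="rest",
            repetition=1, beat_index=i, sbp=sbp, **values))
    return FeatureDataset(records=records, gate="raw")
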