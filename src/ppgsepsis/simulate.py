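"""Parametric PPG waveform simulator.

Generates fingertip-photoplethysmogram-like waveforms for two purposes:

* the noise-free reference *template* required by the template-matching
  quality stage (a periodic pulse train at a requested mean heart rate), and
* labelled synthetic cohorts -- subjects, records, and clinical metadata
  rows -- so the full classification pipeline can be built and tested
  without access to an ICU waveform archive.

Each beat is modelled as the sum of two Gaussian components on the beat
period: a dominant systolic wave and a smaller, later dicrotic wave.  Beat
periods are perturbed i.i.d. around the mean heart rate (truncated at three
standard deviations), and records can carry baseline drift, slow amplitude
modulation in the low-frequency (0.04-0.15 Hz) band, and additive white
noise.  The simulator records the ground-truth systolic peak positions of
every beat it renders, which downstream peak-detection tests use as an
oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np

__all__ = [
    "PulseShapeParams",
    "SimConfig",
    "PPGRecord",
    "CohortSimSpec",
    "simulate_ppg",
    "generate_template",
    "inject_artifacts",
    "simulate_cohort",
    "DEFAULT_SHAPE",
]

#: ICD-9 codes defining the sepsis class (sepsis, severe sepsis, septic shock).
SEPSIS_ICD9 = ("99591", "99592", "78552")
#: ICD-9 codes admitting a subject to the control class.
CONTROL_ICD9 = ("311", "3051", "30000", "2948", "3004")


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class PulseShapeParams:
    """Two-Gaussian pulse morphology, expressed as fractions of the beat period.

    The systolic component is the dominant per-beat maximum; the dicrotic
    component is the secondary wave following it.  Centers and widths are
    fractions of the beat period so the same shape scales across heart rates.
    """

    systolic_amplitude: float = 1.0
    systolic_center_frac: float = 0.30
    systolic_width_frac: float = 0.10
    dicrotic_amplitude: float = 0.35
    dicrotic_center_frac: float = 0.62
    dicrotic_width_frac: float = 0.12

    def validate(self) -> None:
        fracs = (
            self.systolic_center_frac,
            self.systolic_width_frac,
            self.dicrotic_center_frac,
            self.dicrotic_width_frac,
        )
        if not all(0.0 < f < 1.0 for f in fracs):
            raise InvalidConfigError("all shape fractions must lie in (0, 1)")
        if self.dicrotic_center_frac <= self.systolic_center_frac:
            raise InvalidConfigError("dicrotic wave must follow the systolic wave")
        if self.systolic_amplitude <= 0 or self.dicrotic_amplitude <= 0:
            raise InvalidConfigError("amplitudes must be positive")
        if self.dicrotic_amplitude >= self.systolic_amplitude:
            raise InvalidConfigError("dicrotic amplitude must be below systolic")


DEFAULT_SHAPE = PulseShapeParams()


@dataclass(frozen=True)
class SimConfig:
    """Record-level simulation parameters.

    Parameters
    ----------
    fs : sampling rate in Hz.
    duration_s : record length in seconds.
    hr_bpm : mean heart rate in beats per minute; must lie in [20, 220].
    hr_jitter_frac : standard deviation of the per-beat period perturbation,
        as a fraction of the mean period (truncated at +-3 sigma).
    drift_amplitude, drift_freq_hz : sinusoidal baseline-wander component.
    am_depth, am_freq_hz : slow multiplicative amplitude modulation; the
        modulation frequency sits in the low-frequency band of fingertip PPG.
    noise_std : standard deviation of additive white Gaussian noise.
    seed : RNG seed; every stochastic term derives from it.
    """

    fs: float = 125.0
    duration_s: float = 120.0
    hr_bpm: float = 75.0
    hr_jitter_frac: float = 0.0
    drift_amplitude: float = 0.0
    drift_freq_hz: float = 0.1
    am_depth: float = 0.0
    am_freq_hz: float = 0.1
    noise_std: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0:
            raise InvalidConfigError("fs and duration_s must be positive")
        if not (20.0 <= self.hr_bpm <= 220.0):
            raise InvalidConfigError(
                f"hr_bpm={self.hr_bpm} outside the supported range [20, 220]"
            )
        if self.hr_jitter_frac < 0 or self.noise_std < 0:
            raise InvalidConfigError("hr_jitter_frac and noise_std must be >= 0")
        if not (0.0 <= self.am_depth < 1.0):
            raise InvalidConfigError("am_depth must lie in [0, 1)")


@dataclass
class PPGRecord:
    """A continuous single-channel PPG time series.

    ``true_peak_indices`` carries the simulator's ground-truth systolic peak
    sample positions and is ``None`` for real recordings.
    """

    samples: np.ndarray
    fs: float
    subject_id: str = ""
    label: Literal["sepsis", "control", "unknown"] = "unknown"
    true_peak_indices: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.true_peak_indices is not None:
            idx = np.asarray(self.true_peak_indices, dtype=np.int64)
            if idx.size and (np.any(np.diff(idx) <= 0) or idx[0] < 0 or idx[-1] >= self.samples.size):
                raise ValueError("true_peak_indices must be strictly increasing and in bounds")
            self.true_peak_indices = idx

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class CohortSimSpec:
    """Specification of a synthetic two-class cohort.

    ``class_effect`` scales the class-dependent morphology differences:
    sepsis-class subjects get a reduced dicrotic amplitude and suppressed
    low-frequency amplitude modulation relative to controls.  At
    ``class_effect=0`` the two classes are drawn from identical
    distributions.  The mechanism is a simulation convention for producing a
    learnable (or null) separation, not a physiological model of sepsis.
    """

    n_sepsis: int = 20
    n_control: int = 20
    hours_per_subject_range: tuple[float, float] = (2.0, 2.0)
    class_effect: float = 1.0
    artifact_rate: float = 0.0
    hr_range_bpm: tuple[float, float] = (60.0, 100.0)
    noise_std: float = 0.02
    hr_jitter_frac: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_sepsis < 0 or self.n_control < 0:
            raise InvalidConfigError("subject counts must be >= 0")
        if self.class_effect < 0:
            raise InvalidConfigError("class_effect must be >= 0")
        if not (0.0 <= self.artifact_rate <= 1.0):
            raise InvalidConfigError("artifact_rate must lie in [0, 1]")
        lo, hi = self.hours_per_subject_range
        if lo <= 0 or hi < lo:
            raise InvalidConfigError("hours_per_subject_range must satisfy 0 < min <= max")


def _render_beats(
    config: SimConfig, shape: PulseShapeParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Render the noise-free pulse train; returns (samples, peak_indices)."""
    n = int(round(config.fs * config.duration_s))
    t = np.arange(n) / config.fs
    base_period = 60.0 / config.hr_bpm

    # Draw beat periods until the beats tile past the end of the record.
    starts = []
    periods = []
    t_cursor = 0.0
    while t_cursor < config.duration_s + base_period:
        if config.hr_jitter_frac > 0:
            eps = rng.normal(0.0, config.hr_jitter_frac)
            eps = float(np.clip(eps, -3.0 * config.hr_jitter_frac, 3.0 * config.hr_jitter_frac))
        else:
            eps = 0.0
        starts.append(t_cursor)
        periods.append(base_period * (1.0 + eps))
        t_cursor += periods[-1]

    x = np.zeros(n)
    peaks = []
    for t0, T in zip(starts, periods):
        sys_c = t0 + shape.systolic_center_frac * T
        dic_c = t0 + shape.dicrotic_center_frac * T
        sys_w = shape.systolic_width_frac * T
        dic_w = shape.dicrotic_width_frac * T
        # Only evaluate the Gaussians where they are non-negligible.
        lo = max(0, int((t0 - T) * config.fs))
        hi = min(n, int((t0 + 2 * T) * config.fs) + 1)
        if lo >= hi:
            continue
        tt = t[lo:hi]
        x[lo:hi] += shape.systolic_amplitude * np.exp(-0.5 * ((tt - sys_c) / sys_w) ** 2)
        x[lo:hi] += shape.dicrotic_amplitude * np.exp(-0.5 * ((tt - dic_c) / dic_w) ** 2)
        # round half up so a constant period maps to a constant peak spacing
        p = int(np.floor(sys_c * config.fs + 0.5))
        if 0 <= p < n:
            peaks.append(p)
    return x, np.asarray(sorted(set(peaks)), dtype=np.int64)


def simulate_ppg(
    config: SimConfig,
    shape: PulseShapeParams = DEFAULT_SHAPE,
    subject_id: str = "",
    label: Literal["sepsis", "control", "unknown"] = "unknown",
) -> PPGRecord:
    """Simulate a PPG record.

    Beats are rendered as systolic + dicrotic Gaussian components at per-beat
    periods drawn around ``60 / hr_bpm``; optional drift, low-frequency
    amplitude modulation and white noise are then applied.  Deterministic
    given ``config.seed``.
    """
    config.validate()
    shape.validate()
    rng = np.random.default_rng(config.seed)
    x, peaks = _render_beats(config, shape, rng)
    n = x.size
    t = np.arange(n) / config.fs

    if config.am_depth > 0:
        phase = rng.uniform(0, 2 * np.pi)
        x = x * (1.0 + config.am_depth * np.sin(2 * np.pi * config.am_freq_hz * t + phase))
    if config.drift_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        x = x + config.drift_amplitude * np.sin(2 * np.pi * config.drift_freq_hz * t + phase)
    if config.noise_std > 0:
        x = x + rng.normal(0.0, config.noise_std, size=n)

    return PPGRecord(samples=x, fs=config.fs, subject_id=subject_id, label=label,
                     true_peak_indices=peaks)


def generate_template(fs: float, hr_bpm: float, duration_s: float) -> PPGRecord:
    """Generate the noise-free reference template at a given mean heart rate.

    Strictly periodic (zero jitter, drift, modulation and noise); the
    returned record's ``true_peak_indices`` gives the systolic peak
    positions, the first of which is used for first-peak alignment.
    """
    cfg = SimConfig(fs=fs, duration_s=duration_s, hr_bpm=hr_bpm,
                    hr_jitter_frac=0.0, drift_amplitude=0.0, am_depth=0.0,
                    noise_std=0.0, seed=0)
    return simulate_ppg(cfg)


def inject_artifacts(
    record: PPGRecord,
    kind: Literal["constant", "gaussian_burst", "motion"],
    span: tuple[int, int],
    rng_seed: int = 0,
    burst_std: float = 1.0,
    motion_amplitude: float = 5.0,
    motion_freq_hz: float = 0.25,
) -> PPGRecord:
    """Return a copy of ``record`` with ``span`` (half-open) corrupted.

    ``constant`` replaces the span by a single repeated value;
    ``gaussian_burst`` by white noise of ``burst_std``; ``motion`` adds a
    large-amplitude low-frequency sweep.  Samples outside the span are
    bit-identical to the input.  An empty span returns an unchanged copy.
    """
    lo, hi = span
    n = record.samples.size
    if lo < 0 or hi > n or lo > hi:
        raise ValueError(f"span {span} out of bounds for record of length {n}")
    x = record.samples.copy()
    if hi > lo:
        rng = np.random.default_rng(rng_seed)
        if kind == "constant":
            x[lo:hi] = x[lo]
        elif kind == "gaussian_burst":
            x[lo:hi] = rng.normal(0.0, burst_std, size=hi - lo)
        elif kind == "motion":
            t = np.arange(hi - lo) / record.fs
            phase = rng.uniform(0, 2 * np.pi)
            x[lo:hi] += motion_amplitude * np.sin(2 * np.pi * motion_freq_hz * t + phase)
        else:
            raise ValueError(f"unknown artifact kind: {kind!r}")
    return PPGRecord(samples=x, fs=record.fs, subject_id=record.subject_id,
                     label=record.label, true_peak_indices=record.true_peak_indices)


def _class_shape(label: str, class_effect: float, rng: np.random.Generator) -> tuple[PulseShapeParams, float]:
    """Per-subject pulse shape and amplitude-modulation depth for a class.

    Controls keep the default dicrotic amplitude and a pronounced
    low-frequency amplitude modulation; sepsis-class subjects have the
    dicrotic wave attenuated and the modulation suppressed, both scaled by
    ``class_effect``.  Small per-subject shape variation is added on top.
    """
    e = class_effect
    dic_amp = DEFAULT_SHAPE.dicrotic_amplitude
    am_depth = 0.12
    if label == "sepsis":
        dic_amp = dic_amp * max(0.05, 1.0 - 0.6 * e)
        am_depth = am_depth * max(0.0, 1.0 - 0.9 * e)
    else:
        am_depth = am_depth * (1.0 + 1.0 * e)
    # subject-level morphology variability, identical law for both classes
    dic_amp = float(np.clip(dic_amp * (1.0 + rng.normal(0, 0.05)), 0.02, 0.9))
    sys_w = float(np.clip(DEFAULT_SHAPE.systolic_width_frac * (1.0 + rng.normal(0, 0.05)), 0.05, 0.2))
    shape = replace(DEFAULT_SHAPE, dicrotic_amplitude=dic_amp, systolic_width_frac=sys_w)
    am_depth = float(np.clip(am_depth * (1.0 + rng.normal(0, 0.1)), 0.0, 0.6))
    return shape, am_depth


def simulate_cohort(spec: CohortSimSpec):
    """Simulate a labelled two-class cohort.

    Returns ``(records, subjects)`` where ``records`` is a list of
    :class:`PPGRecord` (one continuous record per subject) and ``subjects``
    a list of metadata rows satisfying the cohort-selection criteria for the
    corresponding class, so that the dataset stage labels them correctly.

    Each subject's RNG stream is seeded from ``(spec.seed, subject_index)``
    so the cohort is reproducible independent of generation order.
    """
    from .dataset import SubjectMeta  # local import to avoid a cycle

    spec.validate()
    records: list[PPGRecord] = []
    subjects: list[SubjectMeta] = []
    labels = ["sepsis"] * spec.n_sepsis + ["control"] * spec.n_control
    lo_h, hi_h = spec.hours_per_subject_range
    for idx, label in enumerate(labels):
        rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), idx]))
        sid = f"S{idx:04d}"
        hours = float(rng.uniform(lo_h, hi_h))
        hr = float(rng.uniform(*spec.hr_range_bpm))
        shape, am_depth = _class_shape(label, spec.class_effect, rng)
        cfg = SimConfig(
            fs=125.0,
            duration_s=hours * 3600.0,
            hr_bpm=hr,
            hr_jitter_frac=spec.hr_jitter_frac,
            drift_amplitude=0.05,
            drift_freq_hz=float(rng.uniform(0.05, 0.15)),
            am_depth=am_depth,
            am_freq_hz=float(rng.uniform(0.04, 0.15)),
            noise_std=spec.noise_std,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rec = simulate_ppg(cfg, shape, subject_id=sid, label=label)
        if spec.artifact_rate > 0:
            rec = _corrupt_windows(rec, spec.artifact_rate, rng)
        records.append(rec)

        if label == "sepsis":
            codes = {str(rng.choice(SEPSIS_ICD9))}
            meta = SubjectMeta(subject_id=sid, died_in_hospital=True,
                               n_icu_stays=1, n_admissions=1, icd9_codes=codes,
                               in_matched_subset=True, has_ppg=True)
        else:
            codes = {str(rng.choice(CONTROL_ICD9))}
            meta = SubjectMeta(subject_id=sid, died_in_hospital=False,
                               n_icu_stays=1, n_admissions=1, icd9_codes=codes,
                               in_matched_subset=True, has_ppg=True)
        subjects.append(meta)
    return records, subjects


def _corrupt_windows(rec: PPGRecord, rate: float, rng: np.random.Generator,
                     window_s: float = 3.0) -> PPGRecord:
    """Corrupt a random fraction of non-overlapping 3-s windows."""
    w = int(round(window_s * rec.fs))
    n_windows = rec.samples.size // w
    kinds = ("constant", "gaussian_burst", "motion")
    out = rec
    for i in range(n_windows):
        if rng.uniform() < rate:
            kind = kinds[int(rng.integers(0, len(kinds)))]
            out = inject_artifacts(out, kind, (i * w, (i + 1) * w),
                                   rng_seed=int(rng.integers(0, 2**31 - 1)))
    return out
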