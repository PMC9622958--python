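"""Template-matching quality assessment of PPG segments.

Each 2-minute segment is scanned with a 3-second window.  Per window the
pipeline is: constant-value check, systolic peak detection on the band-passed
trace, heart-rate estimation, simulation of a noise-free reference template
at the estimated rate, alignment of window and template on their first
systolic peaks, Pearson correlation over the overlap, and assignment to one
of four correlation groups:

====================  =========
Pearson coefficient   group
====================  =========
R >= 0.8              I
0.6 <= R < 0.8        II
0.5 <= R < 0.6        III
R < 0.5               IV
====================  =========

A segment is accepted only if every window lands in group I or II; windows
with constant values, too few peaks, or an estimated heart rate below
45 bpm reject the segment outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as spstats

from .preprocess import (
    FilterSpec,
    PeakList,
    Segment,
    bandpass_filter,
    detect_systolic_peaks,
    estimate_mean_hr,
)
from .simulate import PPGRecord, generate_template

__all__ = [
    "QualityThresholds",
    "CorrelationGroup",
    "ExclusionFlag",
    "WindowAssessment",
    "SegmentQC",
    "classify_correlation",
    "align_on_first_peak",
    "pearson_r",
    "assess_window",
    "assess_segment",
    "AlignmentImpossibleError",
    "ConstantSignalError",
    "WINDOW_SECONDS",
]

WINDOW_SECONDS = 3.0
#: overlaps shorter than this (seconds) are too short for a meaningful R
MIN_OVERLAP_SECONDS = 1.0


class AlignmentImpossibleError(ValueError):
    """Raised when first-peak alignment has no peak to align on."""


class ConstantSignalError(ValueError):
    """Raised when a correlation is requested for a zero-variance input."""


class CorrelationGroup(str, Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


class ExclusionFlag(str, Enum):
    CONSTANT = "CONSTANT"
    NO_PEAKS = "NO_PEAKS"
    LOW_HR = "LOW_HR"


class RejectReason(str, Enum):
    GROUP_III_OR_IV = "GROUP_III_OR_IV"
    CONSTANT_WINDOW = "CONSTANT_WINDOW"
    LOW_HR_WINDOW = "LOW_HR_WINDOW"
    NO_PEAKS_WINDOW = "NO_PEAKS_WINDOW"


@dataclass(frozen=True)
class QualityThresholds:
    """Correlation-group cut points and the minimum acceptable heart rate."""

    group1_min: float = 0.8
    group2_min: float = 0.6
    group3_min: float = 0.5
    min_hr_bpm: float = 45.0

    def validate(self) -> None:
        if not (0.0 < self.group3_min < self.group2_min < self.group1_min <= 1.0):
            raise ValueError("thresholds must satisfy 0 < g3 < g2 < g1 <= 1")


@dataclass
class WindowAssessment:
    """Per-window QC result: either a correlation group or an exclusion flag."""

    window_start: int
    R: Optional[float] = None
    group: Optional[CorrelationGroup] = None
    flag: Optional[ExclusionFlag] = None
    est_hr_bpm: Optional[float] = None

    @property
    def ok(self) -> bool:
        return self.group in (CorrelationGroup.I, CorrelationGroup.II)


@dataclass
class SegmentQC:
    """Segment-level verdict with the per-window evidence."""

    accepted: bool
    windows: List[WindowAssessment]
    reject_reasons: List[RejectReason] = field(default_factory=list)


def classify_correlation(
    R: float, thresholds: QualityThresholds = QualityThresholds()
) -> CorrelationGroup:
    """Map a Pearson coefficient to its correlation group (I best, IV worst)."""
    thresholds.validate()
    if not (-1.0 <= R <= 1.0):
        raise ValueError(f"Pearson coefficient {R} outside [-1, 1]")
    if R >= thresholds.group1_min:
        return CorrelationGroup.I
    if R >= thresholds.group2_min:
        return CorrelationGroup.II
    if R >= thresholds.group3_min:
        return CorrelationGroup.III
    return CorrelationGroup.IV


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; zero-variance inputs raise."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("inputs must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantSignalError("correlation undefined for constant input")
    r = spstats.pearsonr(x, y).statistic
    return float(np.clip(r, -1.0, 1.0))


def align_on_first_peak(
    window: Sequence[float],
    window_peaks: PeakList,
    template: PPGRecord,
) -> Tuple[np.ndarray, np.ndarray, int]:
    """Align a window and the reference template on their first systolic peaks.

    The template is shifted so its first systolic peak coincides with the
    window's first detected peak; the overlapping region of the two signals
    is returned.  The quality stage simulates the template one beat period
    longer than the window so that the overlap normally covers the whole
    window regardless of the alignment offset.
    """
    w = np.asarray(window, dtype=np.float64)
    if len(window_peaks) < 1:
        raise AlignmentImpossibleError("window has no detected systolic peak")
    if template.true_peak_indices is None or template.true_peak_indices.size < 1:
        raise AlignmentImpossibleError("template has no systolic peak")
    p_w = int(window_peaks.indices[0])
    p_t = int(template.true_peak_indices[0])
    offset = p_w - p_t  # template index i maps to window index i + offset
    t = template.samples
    lo = max(0, offset)
    hi = min(w.size, t.size + offset)
    if hi <= lo:
        return np.empty(0), np.empty(0), 0
    return w[lo:hi], t[lo - offset : hi - offset], hi - lo


def assess_window(
    window: Sequence[float],
    fs: float,
    thresholds: QualityThresholds = QualityThresholds(),
    filter_spec: FilterSpec = FilterSpec(),
    window_start: int = 0,
    filtered: Optional[np.ndarray] = None,
) -> WindowAssessment:
    """Assess one 3-s window against an HR-matched simulated template.

    ``filtered`` optionally supplies the already band-passed trace for the
    window (e.g. when the caller filtered the whole 2-min segment once);
    otherwise the window is filtered here.
    """
    w = np.asarray(window, dtype=np.float64)
    if w.size != int(round(WINDOW_SECONDS * fs)):
        raise ValueError(
            f"window must be {WINDOW_SECONDS} s at {fs} Hz, got {w.size} samples"
        )
    if np.ptp(w) == 0:
        return WindowAssessment(window_start, flag=ExclusionFlag.CONSTANT)

    filt = bandpass_filter(w, fs, filter_spec) if filtered is None else np.asarray(filtered)
    peaks = detect_systolic_peaks(filt, fs)
    if len(peaks) < 2:
        return WindowAssessment(window_start, flag=ExclusionFlag.NO_PEAKS)
    hr = estimate_mean_hr(peaks)
    if hr is None or hr < thresholds.min_hr_bpm:
        return WindowAssessment(window_start, flag=ExclusionFlag.LOW_HR, est_hr_bpm=hr)

    # Template one beat longer than the window so alignment keeps full overlap.
    hr_clipped = float(np.clip(hr, 20.0, 220.0))
    template = generate_template(fs, hr_clipped, WINDOW_SECONDS + 60.0 / hr_clipped)
    try:
        aw, at, n_overlap = align_on_first_peak(w, peaks, template)
    except AlignmentImpossibleError:
        return WindowAssessment(window_start, flag=ExclusionFlag.NO_PEAKS, est_hr_bpm=hr)
    if n_overlap < int(MIN_OVERLAP_SECONDS * fs):
        return WindowAssessment(window_start, flag=ExclusionFlag.NO_PEAKS, est_hr_bpm=hr)
    try:
        r = pearson_r(aw, at)
    except ConstantSignalError:
        return WindowAssessment(window_start, flag=ExclusionFlag.CONSTANT, est_hr_bpm=hr)
    return WindowAssessment(window_start, R=r,
                            group=classify_correlation(r, thresholds),
                            est_hr_bpm=hr)


_FLAG_TO_REASON = {
    ExclusionFlag.CONSTANT: RejectReason.CONSTANT_WINDOW,
    ExclusionFlag.LOW_HR: RejectReason.LOW_HR_WINDOW,
    ExclusionFlag.NO_PEAKS: RejectReason.NO_PEAKS_WINDOW,
}


def assess_segment(
    segment: Segment,
    thresholds: QualityThresholds = QualityThresholds(),
    filter_spec: FilterSpec = FilterSpec(),
    window_step_s: float = WINDOW_SECONDS,
) -> SegmentQC:
    """Assess a 2-minute segment window by window.

    The whole segment is band-passed once (zero-phase), then 3-s windows are
    enumerated from sample 0 with the given step (default: non-overlapping
    tiling, 40 windows).  The segment is accepted iff every window lands in
    correlation group I or II; all observed failure kinds are aggregated in
    ``reject_reasons``.
    """
    fs = segment.fs
    win_len = int(round(WINDOW_SECONDS * fs))
    step = int(round(window_step_s * fs))
    if step < 1:
        raise ValueError("window step must be positive")
    filt_full = bandpass_filter(segment.samples, fs, filter_spec)

    windows: List[WindowAssessment] = []
    reasons: set[RejectReason] = set()
    for start in range(0, segment.samples.size - win_len + 1, step):
        w = segment.samples[start : start + win_len]
        wa = assess_window(w, fs, thresholds, filter_spec, window_start=start,
                           filtered=filt_full[start : start + win_len])
        windows.append(wa)
        if wa.flag is not None:
            reasons.add(_FLAG_TO_REASON[wa.flag])
        elif not wa.ok:
            reasons.add(RejectReason.GROUP_III_OR_IV)
    accepted = not reasons
    return SegmentQC(accepted=accepted, windows=windows,
                     reject_reasons=sorted(reasons, key=lambda r: r.value))
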