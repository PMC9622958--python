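"""Deterministic PPG signal conditioning.

Fixed-length segmentation of continuous records (2-minute chunks, keeping
every other chunk to reduce within-record redundancy), zero-phase Butterworth
band-pass filtering, systolic peak detection via event-related moving
averages with dynamic thresholds, and mean heart-rate estimation from
inter-peak intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy import signal as sps

from .simulate import PPGRecord

__all__ = [
    "Segment",
    "FilterSpec",
    "PeakList",
    "UnsupportedRateError",
    "segment_signal",
    "bandpass_filter",
    "detect_systolic_peaks",
    "estimate_mean_hr",
    "SEGMENT_SECONDS",
    "SUPPORTED_FS",
]

SEGMENT_SECONDS = 120.0
SUPPORTED_FS = 125.0


class UnsupportedRateError(ValueError):
    """Raised for sampling rates other than 125 Hz; resampling is refused."""


@dataclass
class Segment:
    """One 2-minute PPG excerpt with provenance."""

    samples: np.ndarray
    fs: float
    subject_id: str
    segment_index: int
    label: str = "unknown"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        expected = int(round(self.fs * SEGMENT_SECONDS))
        if self.samples.size != expected:
            raise ValueError(
                f"segment must have exactly {expected} samples, got {self.samples.size}"
            )
        if self.segment_index < 0:
            raise ValueError("segment_index must be >= 0")


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass specification (defaults 0.5-8 Hz, order 3)."""

    order: int = 3
    low_hz: float = 0.5
    high_hz: float = 8.0
    family: str = "butterworth-bandpass"
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if not (0.0 < self.low_hz < self.high_hz < fs / 2.0):
            raise ValueError(
                f"band ({self.low_hz}, {self.high_hz}) invalid for fs={fs}"
            )


@dataclass
class PeakList:
    """Sample positions of detected systolic peaks."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.indices.size)


def segment_signal(record: PPGRecord) -> List[Segment]:
    """Split a record into non-overlapping 2-minute segments.

    Chunks are taken from sample 0; a trailing partial chunk is discarded,
    and of the full chunks only those at even positions (0, 2, 4, ...) are
    retained, which reduces the similarity between segments of one subject.
    Rates other than 125 Hz are rejected rather than resampled.
    """
    if record.fs != SUPPORTED_FS:
        raise UnsupportedRateError(
            f"only fs={SUPPORTED_FS} Hz is supported, got {record.fs}"
        )
    seg_len = int(round(record.fs * SEGMENT_SECONDS))
    n_chunks = record.samples.size // seg_len
    out = []
    for pos in range(0, n_chunks, 2):
        out.append(
            Segment(
                samples=record.samples[pos * seg_len : (pos + 1) * seg_len],
                fs=record.fs,
                subject_id=record.subject_id,
                segment_index=pos,
                label=record.label,
            )
        )
    return out


def bandpass_filter(samples: Sequence[float], fs: float,
                    spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Band-pass filter a signal; zero-phase by default.

    Zero-phase (forward-backward) application keeps peak positions aligned
    between the raw and filtered traces, which first-peak alignment in the
    quality stage relies on.
    """
    spec.validate(fs)
    x = np.asarray(samples, dtype=np.float64)
    if x.size < 3 * spec.order:
        raise ValueError("input too short for the requested filter order")
    sos = sps.butter(spec.order, [spec.low_hz, spec.high_hz],
                     btype="bandpass", fs=fs, output="sos")
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with edge truncation (same length as input)."""
    if width < 1:
        width = 1
    kernel = np.ones(width) / width
    num = np.convolve(x, kernel, mode="same")
    # correct edges for the shorter effective window
    counts = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / counts


def detect_systolic_peaks(
    filtered: Sequence[float],
    fs: float,
    w1_s: float = 0.111,
    w2_s: float = 0.667,
    beta: float = 0.02,
) -> PeakList:
    """Detect systolic peaks with two event-related moving averages.

    The band-passed signal is clipped at zero and squared; a short moving
    average (``w1_s``, the expected systolic-peak duration) is compared
    against a long one (``w2_s``, the expected beat duration) plus a
    data-driven offset ``beta * mean(squared signal)``.  Runs where the short
    average exceeds this dynamic threshold and that are at least ``w1_s``
    long become candidate systolic blocks; the maximum of the filtered
    signal inside each block is the peak.  A zero-variance input yields an
    empty peak list rather than an error.
    """
    x = np.asarray(filtered, dtype=np.float64)
    if x.size == 0 or np.ptp(x) == 0:
        return PeakList(indices=np.empty(0, dtype=np.int64), fs=fs)

    clipped = np.where(x > 0, x, 0.0)
    y = clipped * clipped
    w1 = max(1, int(round(w1_s * fs)))
    w2 = max(1, int(round(w2_s * fs)))
    ma_peak = _moving_average(y, w1)
    ma_beat = _moving_average(y, w2)
    thr1 = ma_beat + beta * float(np.mean(y))

    blocks = ma_peak > thr1
    # find contiguous True runs
    edges = np.diff(blocks.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if blocks[0]:
        starts = np.r_[0, starts]
    if blocks[-1]:
        ends = np.r_[ends, blocks.size]

    peaks = []
    for s, e in zip(starts, ends):
        if e - s >= w1:
            peaks.append(s + int(np.argmax(x[s:e])))
    return PeakList(indices=np.asarray(peaks, dtype=np.int64), fs=fs)


def estimate_mean_hr(peaks: PeakList) -> Optional[float]:
    """Mean heart rate in bpm from inter-peak intervals.

    Returns ``None`` (undefined heart rate) when fewer than two peaks are
    available, so callers can apply their exclusion rules; never returns a
    fabricated numeric value in that case.
    """
    if len(peaks) < 2:
        return None
    mean_interval_s = float(np.mean(np.diff(peaks.indices))) / peaks.fs
    return 60.0 / mean_interval_s
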