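"""Band-pass filtering and non-overlapping segmentation.

The analysis band is isolated with a fifth-order Butterworth band-pass
applied forward-backward (zero-phase), then each recording is cut into
consecutive non-overlapping windows of ``N = floor(T * fs)`` samples; the
trailing remainder is dropped.  Segments are the unit of classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from .io import Group, Recording

__all__ = ["BandSpec", "SegmentSet", "bandpass", "segment", "BAND_PRESETS"]

logger = logging.getLogger(__name__)

# Conventional EEG sub-band boundaries; gamma (>30 Hz) deliberately absent
# (excluded from the analysis because of muscle/line artifact contamination).
BAND_PRESETS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "alpha+beta": (8.0, 30.0),
    "default": (10.0, 30.0),
}


@dataclass(frozen=True)
class BandSpec:
    """Butterworth band-pass specification (one-pass design order)."""

    low_hz: float = 10.0
    high_hz: float = 30.0
    order: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(f"need 0 < low_hz < high_hz, got {self.low_hz}, {self.high_hz}")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")

    @classmethod
    def preset(cls, name: str, order: int = 5) -> "BandSpec":
        low, high = BAND_PRESETS[name]
        return cls(low, high, order)

    def sos(self, fs: float) -> np.ndarray:
        if self.high_hz >= fs / 2:
            raise ValueError(
                f"band edge {self.high_hz} Hz is not below the Nyquist frequency {fs / 2} Hz"
            )
        return signal.butter(self.order, [self.low_hz, self.high_hz],
                             btype="bandpass", fs=fs, output="sos")


@dataclass
class SegmentSet:
    """M band-passed segments of identical shape ch x N with class labels."""

    segments: np.ndarray          # (M, ch, N)
    labels: np.ndarray            # (M,) group value strings
    T: float
    fs: float
    band: BandSpec | None = None
    subject_ids: np.ndarray = field(default=None)  # (M,), for subject-blocked CV

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.segments.ndim != 3:
            raise ValueError("segments must be (M, ch, N)")
        if len(self.labels) != self.segments.shape[0]:
            raise ValueError("labels length must equal segment count")
        if self.subject_ids is None:
            self.subject_ids = np.array([""] * len(self.labels))

    @property
    def M(self) -> int:
        return self.segments.shape[0]

    @property
    def ch(self) -> int:
        return self.segments.shape[1]

    @property
    def N(self) -> int:
        return self.segments.shape[2]


def bandpass(recording: Recording, band: BandSpec) -> Recording:
    """Zero-phase Butterworth band-pass; returns a new Recording, same shape.

    Forward-backward application squares the magnitude response (doubling
    the effective roll-off) and cancels phase distortion, the standard
    choice for offline EEG work.
    """
    sos = band.sos(recording.fs)
    filtered = signal.sosfiltfilt(sos, recording.data, axis=1)
    return Recording(
        data=filtered,
        fs=recording.fs,
        channel_names=list(recording.channel_names),
        subject_id=recording.subject_id,
        group=recording.group,
        eyes=recording.eyes,
    )


def segment(recordings: Sequence[Recording], T: float,
            band: BandSpec | None = None) -> SegmentSet:
    """Cut recordings into consecutive non-overlapping ch x N windows.

    ``N = floor(T * fs)``; the remainder at the end of each recording is
    dropped (logged).  Labels and subject ids are copied per segment in
    recording order.
    """
    if T <= 0:
        raise ValueError("segment duration T must be positive")
    if not recordings:
        raise ValueError("no recordings to segment")
    fs = recordings[0].fs
    ch = recordings[0].n_channels
    for rec in recordings:
        if rec.fs != fs:
            raise ValueError("all recordings must share one sampling rate")
        if rec.n_channels != ch:
            raise ValueError("all recordings must share one channel count")
    N = int(np.floor(T * fs))
    if N < 2:
        raise ValueError(f"segment length N={N} < 2 samples; covariance undefined")
    segs, labels, subjects = [], [], []
    for rec in recordings:
        m = rec.n_samples // N
        dropped = rec.n_samples - m * N
        if dropped:
            logger.debug("dropping %d trailing samples of %s", dropped, rec.subject_id)
        for i in range(m):
            segs.append(rec.data[:, i * N:(i + 1) * N])
            labels.append(rec.group.value)
            subjects.append(rec.subject_id)
    if not segs:
        raise ValueError(f"no recording is long enough for a single {T}-s segment")
    return SegmentSet(
        segments=np.stack(segs),
        labels=np.array(labels),
        T=T,
        fs=fs,
        band=band,
        subject_ids=np.array(subjects),
    )


def preprocess(recordings: Sequence[Recording], band: BandSpec, T: float) -> SegmentSet:
    """bandpass -> segment, the standard front end of the pipeline."""
    return segment([bandpass(r, band) for r in recordings], T, band=band)
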