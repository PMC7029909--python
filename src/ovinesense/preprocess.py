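"""Signal conditioning and windowing for ear-tag IMU recordings.

The raw tri-axial channels are collapsed to their Euclidean magnitude
(Ā = √(Ax² + Ay² + Az²), and likewise Ḡ for the gyroscope), and the
static gravity/orientation component is removed by first-differencing
the magnitude: a constant offset contributes nothing to the per-sample
rate of change.  The differenced streams are then cut into 7 s windows
(112 samples at 16 Hz) with 50 % overlap; each window inherits the
activity covering the majority of its samples and the per-recording
lameness label.  Windows of dead sensor signal (magnitude identically
zero) are discarded.

Differencing is applied once per contiguous recording *before*
windowing, so every window holds a full 112 differenced samples and the
window grid is indexed on the differenced stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ovinesense.simulate import ACTIVITIES, LAME_SCORE_THRESHOLD, TriaxialRecording

WINDOW_SECONDS = 7.0
WINDOW_OVERLAP = 0.5


@dataclass
class MagnitudeSeries:
    """Euclidean norm of one sensor modality, sample by sample."""

    values: np.ndarray
    modality: str  # "accel" | "gyro"
    sampling_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.modality not in ("accel", "gyro"):
            raise ValueError(f"modality must be 'accel' or 'gyro', got {self.modality!r}")
        if (self.values < 0).any():
            raise ValueError("magnitude values must be non-negative")


@dataclass
class DifferencedSeries:
    """Per-sample change of a magnitude series (signed)."""

    values: np.ndarray
    modality: str
    sampling_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class AnnotatedWindow:
    """One windowed observation: differenced accel + gyro magnitude,
    activity label, binary lameness label and provenance."""

    sheep_id: str
    window_index: int
    samples_accel_diff: np.ndarray
    samples_gyro_diff: np.ndarray
    activity: str
    lame: bool
    lameness_score: int
    accel_source_zero: bool = False  # raw accel magnitude identically 0
    gyro_source_zero: bool = False

    def __post_init__(self) -> None:
        self.samples_accel_diff = np.asarray(self.samples_accel_diff, dtype=float)
        self.samples_gyro_diff = np.asarray(self.samples_gyro_diff, dtype=float)
        if len(self.samples_accel_diff) != len(self.samples_gyro_diff):
            raise ValueError("accel and gyro windows must have equal length")
        if self.activity not in ACTIVITIES:
            raise ValueError(f"unknown activity {self.activity!r}")


def compute_magnitude(recording: TriaxialRecording, modality: str) -> MagnitudeSeries:
    """Pointwise Euclidean norm of the three channels of one modality."""
    if modality == "accel":
        channels = recording.accel
    elif modality == "gyro":
        channels = recording.gyro
    else:
        raise ValueError(f"modality must be 'accel' or 'gyro', got {modality!r}")
    values = np.linalg.norm(channels, axis=1)
    return MagnitudeSeries(values=values, modality=modality, sampling_rate=recording.sampling_rate)


def magnitude_difference(series: MagnitudeSeries) -> DifferencedSeries:
    """First difference d[i] = m[i+1] - m[i] of the magnitude.

    The difference is per sample (not divided by the time step), matching
    the convention that the differenced accelerometer signal stays in g
    and the gyroscope in deg/s.  A constant (static) component vanishes
    exactly.
    """
    if len(series.values) < 2:
        raise ValueError("magnitude series must have length >= 2 to difference")
    return DifferencedSeries(
        values=np.diff(series.values),
        modality=series.modality,
        sampling_rate=series.sampling_rate,
    )


def expected_window_count(n_samples: int, window_len: int, step: int) -> int:
    """Number of full windows of ``window_len`` with stride ``step``."""
    if n_samples < window_len:
        return 0
    return (n_samples - window_len) // step + 1


def _sample_activity_labels(
    n: int, sampling_rate: float, annotations, offset: float = 0.0
) -> np.ndarray:
    """Activity index per differenced sample (-1 = unannotated).

    Differenced sample i spans raw samples i and i+1; it is located at
    the time of raw sample i.
    """
    labels = np.full(n, -1, dtype=int)
    times = np.arange(n) / sampling_rate + offset
    for start, end, activity, _score in annotations:
        mask = (times >= start - 1e-9) & (times < end - 1e-9)
        labels[mask] = ACTIVITIES.index(activity)
    return labels


def segment_windows(
    accel_diff: DifferencedSeries,
    gyro_diff: DifferencedSeries,
    annotations: list[tuple[float, float, str, int]],
    window_s: float = WINDOW_SECONDS,
    overlap: float = WINDOW_OVERLAP,
    sheep_id: str = "unknown",
    accel_magnitude: MagnitudeSeries | None = None,
    gyro_magnitude: MagnitudeSeries | None = None,
) -> list[AnnotatedWindow]:
    """Cut the differenced streams into overlapping annotated windows.

    Windows are ``window_s * f_s`` differenced samples long (112 at 16 Hz
    for 7 s) and start every ``(1 - overlap)`` window (56 samples at 50 %
    overlap).  A window takes the activity label covering the strict
    majority (> 50 %) of its samples; windows without a majority label
    (ties, mostly-unannotated spans) are dropped.  The lameness label is
    per recording, taken from the annotations' locomotion score.

    When the source ``MagnitudeSeries`` are supplied, windows whose raw
    magnitude is identically zero over their span are flagged for
    :func:`remove_erroneous`.
    """
    if len(accel_diff.values) != len(gyro_diff.values):
        raise ValueError("accel and gyro differenced series must have equal length")
    if accel_diff.sampling_rate != gyro_diff.sampling_rate:
        raise ValueError("modalities must share a sampling rate")
    f_s = accel_diff.sampling_rate
    window_len_f = window_s * f_s
    window_len = int(round(window_len_f))
    if abs(window_len_f - window_len) > 1e-9:
        raise ValueError(f"window_s * sampling_rate must be integral, got {window_len_f}")
    if not (0 <= overlap < 1):
        raise ValueError("overlap must be in [0, 1)")
    step = int(round(window_len * (1 - overlap)))
    if step <= 0:
        raise ValueError("overlap too large: zero stride")

    n = len(accel_diff.values)
    labels = _sample_activity_labels(n, f_s, annotations)
    score = annotations[0][3] if annotations else 0

    windows: list[AnnotatedWindow] = []
    for w, start in enumerate(range(0, n - window_len + 1, step)):
        sl = slice(start, start + window_len)
        window_labels = labels[sl]
        counts = np.bincount(window_labels[window_labels >= 0], minlength=len(ACTIVITIES))
        if counts.sum() == 0:
            continue  # no annotation coverage
        best = int(np.argmax(counts))
        if counts[best] <= window_len / 2:
            continue  # no strict-majority label (includes exact ties at 50 %)
        if np.sum(counts == counts[best]) > 1:
            continue  # tie between activities
        accel_zero = (
            bool(np.all(accel_magnitude.values[start : start + window_len + 1] == 0.0))
            if accel_magnitude is not None
            else bool(np.all(accel_diff.values[sl] == 0.0))
        )
        gyro_zero = (
            bool(np.all(gyro_magnitude.values[start : start + window_len + 1] == 0.0))
            if gyro_magnitude is not None
            else bool(np.all(gyro_diff.values[sl] == 0.0))
        )
        windows.append(
            AnnotatedWindow(
                sheep_id=sheep_id,
                window_index=w,
                samples_accel_diff=accel_diff.values[sl].copy(),
                samples_gyro_diff=gyro_diff.values[sl].copy(),
                activity=ACTIVITIES[best],
                lame=score >= LAME_SCORE_THRESHOLD,
                lameness_score=score,
                accel_source_zero=accel_zero,
                gyro_source_zero=gyro_zero,
            )
        )
    return windows


def remove_erroneous(windows: list[AnnotatedWindow]) -> list[AnnotatedWindow]:
    """Drop windows of dead sensor signal.

    A window is erroneous when its source accelerometer magnitude (or,
    by the same rule, gyroscope magnitude) is identically zero across the
    whole window — a stuck or disconnected sensor, not a still animal
    (gravity keeps a live accelerometer's magnitude near 1 g).  Order is
    preserved.
    """
    return [w for w in windows if not (w.accel_source_zero or w.gyro_source_zero)]


def window_recording(
    recording: TriaxialRecording,
    window_s: float = WINDOW_SECONDS,
    overlap: float = WINDOW_OVERLAP,
) -> list[AnnotatedWindow]:
    """Full conditioning chain for one recording: magnitude → difference →
    windows → erroneous-window removal."""
    accel_mag = compute_magnitude(recording, "accel")
    gyro_mag = compute_magnitude(recording, "gyro")
    windows = segment_windows(
        magnitude_difference(accel_mag),
        magnitude_difference(gyro_mag),
        recording.annotations,
        window_s=window_s,
        overlap=overlap,
        sheep_id=recording.sheep_id,
        accel_magnitude=accel_mag,
        gyro_magnitude=gyro_mag,
    )
    return remove_erroneous(windows)


def windows_to_frame(windows: list[AnnotatedWindow]) -> pd.DataFrame:
    """Flatten windows into the on-disk sample-level table:
    ``sheep_id,window_index,activity,lame`` followed by the differenced
    accel and gyro sample columns."""
    if not windows:
        return pd.DataFrame(columns=["sheep_id", "window_index", "activity", "lame"])
    n = len(windows[0].samples_accel_diff)
    records = []
    for w in windows:
        rec = {
            "sheep_id": w.sheep_id,
            "window_index": w.window_index,
            "activity": w.activity,
            "lame": w.lame,
        }
        rec.update({f"ad_{i}": v for i, v in enumerate(w.samples_accel_diff)})
        rec.update({f"gd_{i}": v for i, v in enumerate(w.samples_gyro_diff)})
        records.append(rec)
    return pd.DataFrame.from_records(records)
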