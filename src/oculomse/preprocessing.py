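"""Epoch-level preprocessing of fixational eye-tracking recordings.

A 2-minute binocular recording (gaze position in degrees, pupil diameter in
mm, per-eye validity flags, 300 Hz) is cut into non-overlapping 10-s
epochs.  Samples around blinks are masked, epochs with more than half of
their samples missing are excluded, remaining gaps are linearly
interpolated, and the epochs are filtered: 0.1-30 Hz band-pass for gaze
(removes slow head/posture drift and tracker noise above the oculomotor
band) and 5 Hz low-pass for pupil diameter (the pupil is a slow actuator;
DC must be preserved because the feature of interest is the mean diameter).

The processing order is a contract: mask -> exclusion -> interpolation ->
filtering, so the filters never see missing samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "GazeRecording",
    "Epoch",
    "EpochSet",
    "segment_epochs",
    "mark_missing",
    "blink_mask",
    "select_valid_epochs",
    "interpolate_missing",
    "bandpass_eye",
    "lowpass_pupil",
    "preprocess_recording",
    "PreprocessingConfig",
]


@dataclass
class GazeRecording:
    """One participant's raw binocular recording."""

    participant_id: str
    time: np.ndarray  # seconds
    gaze_h: np.ndarray  # degrees of visual angle
    gaze_v: np.ndarray
    pupil_l: np.ndarray  # mm
    pupil_r: np.ndarray
    valid_l: np.ndarray  # bool
    valid_r: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        arrays = [self.time, self.gaze_h, self.gaze_v, self.pupil_l,
                  self.pupil_r, self.valid_l, self.valid_r]
        lengths = {np.asarray(a).shape[0] for a in arrays}
        if len(lengths) != 1:
            raise ValueError(
                f"recording {self.participant_id!r}: series lengths differ: {sorted(lengths)}"
            )
        self.time = np.asarray(self.time, dtype=float)
        self.gaze_h = np.asarray(self.gaze_h, dtype=float)
        self.gaze_v = np.asarray(self.gaze_v, dtype=float)
        self.pupil_l = np.asarray(self.pupil_l, dtype=float)
        self.pupil_r = np.asarray(self.pupil_r, dtype=float)
        self.valid_l = np.asarray(self.valid_l, dtype=bool)
        self.valid_r = np.asarray(self.valid_r, dtype=bool)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        self._check_uniform_sampling()

    def _check_uniform_sampling(self) -> None:
        if self.time.size < 2:
            return
        ideal = self.time[0] + np.arange(self.time.size) / self.fs_hz
        # tolerance: one sample period of cumulative drift over the recording
        if np.max(np.abs(self.time - ideal)) > 1.0 / self.fs_hz:
            raise ValueError(
                f"recording {self.participant_id!r}: non-uniform sampling "
                f"(timestamps deviate more than one sample period from a {self.fs_hz} Hz grid)"
            )

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


@dataclass
class Epoch:
    """A fixed-length segment of a recording with its missing mask."""

    eye_h: np.ndarray
    eye_v: np.ndarray
    pupil_l: np.ndarray
    pupil_r: np.ndarray
    missing: np.ndarray | None = None  # bool, shared across channels

    @property
    def missing_fraction(self) -> float:
        if self.missing is None:
            return 0.0
        return float(np.mean(self.missing))


@dataclass
class EpochSet:
    """Epochs of one participant plus exclusion bookkeeping."""

    participant_id: str
    epochs: list[Epoch]
    epoch_len_samples: int
    fs_hz: float
    excluded_count: int = 0
    segmented_count: int = field(default=0)

    def __post_init__(self) -> None:
        if self.segmented_count == 0:
            self.segmented_count = len(self.epochs) + self.excluded_count

    @property
    def excluded_fraction(self) -> float:
        if self.segmented_count == 0:
            return float("nan")
        return self.excluded_count / self.segmented_count

    @property
    def all_excluded(self) -> bool:
        return self.segmented_count > 0 and len(self.epochs) == 0


def segment_epochs(recording: GazeRecording, epoch_s: float = 10.0) -> EpochSet:
    """Cut a recording into consecutive non-overlapping epochs.

    The trailing partial epoch is discarded; a recording shorter than one
    epoch yields zero epochs.
    """
    n_len = epoch_s * recording.fs_hz
    if abs(n_len - round(n_len)) > 1e-9:
        raise ValueError(
            f"epoch_s * fs_hz = {n_len} is not an integer sample count"
        )
    n_len = int(round(n_len))
    n_epochs = recording.n_samples // n_len
    epochs = []
    for i in range(n_epochs):
        sl = slice(i * n_len, (i + 1) * n_len)
        epochs.append(
            Epoch(
                eye_h=recording.gaze_h[sl].copy(),
                eye_v=recording.gaze_v[sl].copy(),
                pupil_l=recording.pupil_l[sl].copy(),
                pupil_r=recording.pupil_r[sl].copy(),
            )
        )
    return EpochSet(
        participant_id=recording.participant_id,
        epochs=epochs,
        epoch_len_samples=n_len,
        fs_hz=recording.fs_hz,
        excluded_count=0,
        segmented_count=n_epochs,
    )


def blink_mask(
    valid: np.ndarray, pupil: np.ndarray | None = None
) -> np.ndarray:
    """Invalid-sample mask for one eye.

    A sample belongs to a blink when the tracker flags it invalid or
    reports a non-positive pupil diameter (vendor-neutral blink semantics).
    """
    invalid = ~np.asarray(valid, dtype=bool)
    if pupil is not None:
        invalid = invalid | (np.asarray(pupil, dtype=float) <= 0)
    return invalid


def mark_missing(invalid: np.ndarray, fs_hz: float, pad_ms: float = 10.0) -> np.ndarray:
    """Extend every maximal run of invalid samples by ``pad_ms`` on each side.

    Eye-tracker validity flags lag the true lid closure, so samples within
    the pad window before and after a blink are also treated as missing.
    """
    if pad_ms < 0:
        raise ValueError("pad_ms must be >= 0")
    invalid = np.asarray(invalid, dtype=bool)
    pad = math.ceil(pad_ms * fs_hz / 1000.0)
    if pad == 0 or not invalid.any():
        return invalid.copy()
    # dilate with a window of half-width `pad`
    kernel = np.ones(2 * pad + 1, dtype=int)
    return np.convolve(invalid.astype(int), kernel, mode="same") > 0


def select_valid_epochs(
    epoch_set: EpochSet, max_missing_frac: float = 0.5
) -> EpochSet:
    """Drop epochs whose missing fraction strictly exceeds ``max_missing_frac``.

    An epoch with exactly the threshold fraction missing is retained.  All
    epochs excluded leaves an empty set whose ``all_excluded`` flag marks
    the participant's features as missing downstream.
    """
    kept = [
        ep for ep in epoch_set.epochs if ep.missing_fraction <= max_missing_frac
    ]
    excluded = len(epoch_set.epochs) - len(kept)
    return EpochSet(
        participant_id=epoch_set.participant_id,
        epochs=kept,
        epoch_len_samples=epoch_set.epoch_len_samples,
        fs_hz=epoch_set.fs_hz,
        excluded_count=epoch_set.excluded_count + excluded,
        segmented_count=epoch_set.segmented_count,
    )


def interpolate_missing(series: np.ndarray, missing: np.ndarray) -> np.ndarray:
    """Fill missing samples by linear interpolation between valid neighbours.

    Leading/trailing gaps are filled by holding the nearest valid value
    (linear interpolation is undefined at the edges and extrapolating would
    invent trends).
    """
    x = np.asarray(series, dtype=float)
    missing = np.asarray(missing, dtype=bool)
    if not missing.any():
        return x.copy()
    if missing.all():
        raise ValueError("cannot interpolate a fully-missing epoch; it should have been excluded")
    idx = np.arange(x.size)
    valid = ~missing
    return np.interp(idx, idx[valid], x[valid])


def _sos_filter(series: np.ndarray, sos: np.ndarray) -> np.ndarray:
    return signal.sosfiltfilt(sos, np.asarray(series, dtype=float))


def bandpass_eye(
    series: np.ndarray, fs_hz: float, lo_hz: float = 0.1, hi_hz: float = 30.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass for gaze series (default 0.1-30 Hz).

    4th-order Butterworth applied forward-backward (zero phase distortion,
    so saccade timing is preserved); output length equals input length.
    """
    if not (0 < lo_hz < hi_hz < fs_hz / 2):
        raise ValueError(
            f"require 0 < lo ({lo_hz}) < hi ({hi_hz}) < Nyquist ({fs_hz / 2})"
        )
    sos = signal.butter(order, [lo_hz, hi_hz], btype="bandpass", fs=fs_hz, output="sos")
    return _sos_filter(series, sos)


def lowpass_pupil(
    series: np.ndarray, fs_hz: float, hi_hz: float = 5.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth low-pass for pupil series (default 5 Hz), DC preserved."""
    if not (0 < hi_hz < fs_hz / 2):
        raise ValueError(f"require 0 < hi ({hi_hz}) < Nyquist ({fs_hz / 2})")
    sos = signal.butter(order, hi_hz, btype="lowpass", fs=fs_hz, output="sos")
    return _sos_filter(series, sos)


@dataclass(frozen=True)
class PreprocessingConfig:
    epoch_s: float = 10.0
    blink_pad_ms: float = 10.0
    max_missing_frac: float = 0.5
    eye_band_hz: tuple[float, float] = (0.1, 30.0)
    pupil_low_hz: float = 5.0
    filter_order: int = 4


def preprocess_recording(
    recording: GazeRecording, config: PreprocessingConfig = PreprocessingConfig()
) -> EpochSet:
    """Full preprocessing chain for one recording.

    Segments the recording, computes a shared missing mask (union of both
    eyes' padded blink runs — blinks are binocular and the gaze signal is
    derived from both eyes), excludes epochs with more than
    ``max_missing_frac`` missing, interpolates the remaining gaps, and
    applies the gaze band-pass and pupil low-pass filters.
    """
    epoch_set = segment_epochs(recording, config.epoch_s)
    n_len = epoch_set.epoch_len_samples

    invalid = blink_mask(recording.valid_l, recording.pupil_l) | blink_mask(
        recording.valid_r, recording.pupil_r
    )
    for i, ep in enumerate(epoch_set.epochs):
        sl = slice(i * n_len, (i + 1) * n_len)
        ep.missing = mark_missing(invalid[sl], recording.fs_hz, config.blink_pad_ms)

    valid_set = select_valid_epochs(epoch_set, config.max_missing_frac)
    lo, hi = config.eye_band_hz
    for ep in valid_set.epochs:
        ep.eye_h = bandpass_eye(
            interpolate_missing(ep.eye_h, ep.missing), recording.fs_hz, lo, hi,
            config.filter_order,
        )
        ep.eye_v = bandpass_eye(
            interpolate_missing(ep.eye_v, ep.missing), recording.fs_hz, lo, hi,
            config.filter_order,
        )
        ep.pupil_l = lowpass_pupil(
            interpolate_missing(ep.pupil_l, ep.missing), recording.fs_hz,
            config.pupil_low_hz, config.filter_order,
        )
        ep.pupil_r = lowpass_pupil(
            interpolate_missing(ep.pupil_r, ep.missing), recording.fs_hz,
            config.pupil_low_hz, config.filter_order,
        )
    return valid_set
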