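"""Signal conditioning and sliding-window segmentation.

EMG channels are band-pass filtered 30-350 Hz with an 8th-order Chebyshev
type-I digital filter; wrist-angle traces are low-pass filtered at 10 Hz
with a 3rd-order Butterworth. Both filters are realised as cascaded
second-order sections and applied causally by default (matching real-time
use); a zero-phase mode is available for offline parity studies.

Conditioned trials are segmented into 200 ms analysis windows advanced in
20 ms steps. Windows never span trial boundaries, so no window mixes
repetitions or motion classes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .synthetic_emg import EmgTrial


@dataclass(frozen=True)
class FilterSpec:
    emg_band_hz: tuple[float, float] = (30.0, 350.0)
    emg_order: int = 8  # overall band-pass order (must be even)
    emg_passband_ripple_db: float = 0.5
    gonio_cutoff_hz: float = 10.0
    gonio_order: int = 3
    fs_hz: float = 1000.0

    def __post_init__(self):
        low, high = self.emg_band_hz
        nyq = self.fs_hz / 2.0
        if not (0 < low < high < nyq):
            raise ValueError("EMG band must satisfy 0 < low < high < fs/2")
        if not (0 < self.gonio_cutoff_hz < nyq):
            raise ValueError("goniometer cutoff outside (0, fs/2)")
        if self.emg_order <= 0 or self.emg_order % 2:
            raise ValueError("band-pass order must be positive and even")
        if self.gonio_order <= 0:
            raise ValueError("low-pass order must be positive")

    def emg_sos(self) -> np.ndarray:
        # scipy's band-pass of design order N has overall order 2N
        return sps.cheby1(
            self.emg_order // 2,
            self.emg_passband_ripple_db,
            self.emg_band_hz,
            btype="bandpass",
            fs=self.fs_hz,
            output="sos",
        )

    def gonio_sos(self) -> np.ndarray:
        return sps.butter(
            self.gonio_order,
            self.gonio_cutoff_hz,
            btype="low",
            fs=self.fs_hz,
            output="sos",
        )


@dataclass(frozen=True)
class WindowSpec:
    length_ms: float = 200.0
    increment_ms: float = 20.0

    def __post_init__(self):
        if self.length_ms <= 0 or self.increment_ms <= 0:
            raise ValueError("window length and increment must be positive")
        if self.increment_ms > self.length_ms:
            raise ValueError("increment must not exceed window length")

    def samples(self, fs_hz: float) -> tuple[int, int]:
        length = self.length_ms * fs_hz / 1000.0
        step = self.increment_ms * fs_hz / 1000.0
        if abs(length - round(length)) > 1e-9 or abs(step - round(step)) > 1e-9:
            raise ValueError("window spec not divisible by the sample period")
        return int(round(length)), int(round(step))


def _apply_sos(x: np.ndarray, sos: np.ndarray, zero_phase: bool) -> np.ndarray:
    if zero_phase:
        return sps.sosfiltfilt(sos, x, axis=-1)
    return sps.sosfilt(sos, x, axis=-1)


def filter_emg(
    trial: EmgTrial, spec: FilterSpec | None = None, *, zero_phase: bool = False
) -> EmgTrial:
    """Band-pass filter every EMG channel of a trial independently."""
    spec = spec or FilterSpec(fs_hz=trial.fs_hz)
    if spec.fs_hz != trial.fs_hz:
        raise ValueError("filter spec sampling rate does not match trial")
    filtered = _apply_sos(trial.signal, spec.emg_sos(), zero_phase)
    return replace(trial, signal=filtered)


def filter_gonio(
    gonio: np.ndarray, spec: FilterSpec | None = None, *, zero_phase: bool = False
) -> np.ndarray:
    """Low-pass filter wrist-angle traces (any (..., n_samples) array)."""
    spec = spec or FilterSpec()
    return _apply_sos(np.asarray(gonio, float), spec.gonio_sos(), zero_phase)


def preprocess_trial(
    trial: EmgTrial, spec: FilterSpec | None = None, *, zero_phase: bool = False
) -> EmgTrial:
    """Filter both the EMG channels and the goniometer trace of a trial."""
    spec = spec or FilterSpec(fs_hz=trial.fs_hz)
    out = filter_emg(trial, spec, zero_phase=zero_phase)
    out.gonio = filter_gonio(trial.gonio, spec, zero_phase=zero_phase)
    return out


def n_windows(n_samples: int, length: int, step: int) -> int:
    return (n_samples - length) // step + 1


def segment_windows(
    trial: EmgTrial, wspec: WindowSpec | None = None
) -> list[tuple[np.ndarray, np.ndarray, dict]]:
    """Cut one trial into time-aligned (EMG window, angle window, metadata).

    Windows start at multiples of the increment; a trial shorter than one
    window is an error.
    """
    wspec = wspec or WindowSpec()
    length, step = wspec.samples(trial.fs_hz)
    if trial.n_samples < length:
        raise ValueError(
            f"trial of {trial.n_samples} samples shorter than one "
            f"{length}-sample window"
        )
    out = []
    for w in range(n_windows(trial.n_samples, length, step)):
        start = w * step
        meta = {
            "class": trial.class_label,
            "position_index": trial.position_index,
            "rep_index": trial.rep_index,
            "window_index": w,
            "start_sample": start,
        }
        out.append(
            (
                trial.signal[:, start : start + length],
                trial.gonio[:, start : start + length],
                meta,
            )
        )
    return out


def window_views(
    trial: EmgTrial, wspec: WindowSpec | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Strided views of all windows: EMG (K, W, L) and angles (3, W, L).

    Equivalent to :func:`segment_windows` but without copying; used by the
    feature extractor.
    """
    wspec = wspec or WindowSpec()
    length, step = wspec.samples(trial.fs_hz)
    if trial.n_samples < length:
        raise ValueError("trial shorter than one window")
    emg = np.lib.stride_tricks.sliding_window_view(trial.signal, length, axis=1)
    gon = np.lib.stride_tricks.sliding_window_view(trial.gonio, length, axis=1)
    return emg[:, ::step, :], gon[:, ::step, :]
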