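"""Signal conditioning and sliding-window segmentation.

Raw sEMG is conditioned with a 4th-order Butterworth bandpass (10-500 Hz, the
band carrying muscle activity) and a 50 Hz IIR notch against power-line
interference.  Both filters are applied zero-phase (forward-backward) over the
whole session before windowing, so gesture boundaries are not shifted.

Windowing follows a grid of five window lengths (200..1000 samples) by four
increment fractions (25/50/75/100% of the window length, i.e. the *step*
between consecutive window starts).  Windows are cut exclusively from
gesture-hold runs — never across a gesture/rest boundary — and channels are
windowed independently.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import signal as _signal

from .protocol_sim import Session


@dataclasses.dataclass(frozen=True)
class FilterSpec:
    """Bandpass + notch settings (Hz)."""

    band_low: float = 10.0
    band_high: float = 500.0
    order: int = 4
    notch_freq: float = 50.0
    notch_quality: float = 30.0

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if not (0.0 < self.band_low < self.band_high):
            raise ValueError("need 0 < band_low < band_high")
        if self.notch_freq <= 0 or self.notch_quality <= 0:
            raise ValueError("notch_freq and notch_quality must be positive")

    def validate_for(self, fs: float) -> None:
        if self.band_high >= fs / 2.0:
            raise ValueError(
                f"band_high={self.band_high} must be below Nyquist ({fs / 2})"
            )
        if self.notch_freq >= fs / 2.0:
            raise ValueError(
                f"notch_freq={self.notch_freq} must be below Nyquist ({fs / 2})"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class WindowGrid:
    """Window lengths (samples) x increment fractions of the length."""

    window_lengths: tuple[int, ...] = (200, 400, 600, 800, 1000)
    increment_fractions: tuple[float, ...] = (0.25, 0.50, 0.75, 1.00)

    def __post_init__(self) -> None:
        if any(length < 2 for length in self.window_lengths):
            raise ValueError("window lengths must be >= 2")
        for f in self.increment_fractions:
            if not (0.0 < f <= 1.0):
                raise ValueError("increment fractions must lie in (0, 1]")
        for length in self.window_lengths:
            for f in self.increment_fractions:
                if step_size(length, f) < 1:
                    raise ValueError(f"step for (length={length}, fraction={f}) is < 1")

    def cells(self) -> list[tuple[int, float]]:
        return [(l, f) for l in self.window_lengths for f in self.increment_fractions]

    def to_dict(self) -> dict:
        return {
            "window_lengths": list(self.window_lengths),
            "increment_fractions": list(self.increment_fractions),
        }


@dataclasses.dataclass
class Window:
    """One fixed-length segment of one channel, inside one gesture hold.

    ``start`` is the 0-based start index in the session; the window covers
    the half-open interval ``[start, start + length)``.
    """

    samples: np.ndarray
    label: int
    channel: int
    start: int
    run_index: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()

    @property
    def length(self) -> int:
        return len(self.samples)


def step_size(length: int, increment_fraction: float) -> int:
    """Step between consecutive window starts: round(length * fraction)."""
    return int(round(length * increment_fraction))


def window_count(run_length: int, length: int, increment_fraction: float) -> int:
    """Closed-form number of windows in a run: floor((R - L)/step) + 1."""
    step = step_size(length, increment_fraction)
    if run_length < length:
        return 0
    return (run_length - length) // step + 1


def bandpass_filter(
    signal: np.ndarray, fs: float, spec: FilterSpec | None = None
) -> np.ndarray:
    """Zero-phase Butterworth bandpass of a 1-D signal."""
    spec = spec or FilterSpec()
    spec.validate_for(fs)
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if len(x) <= 3 * spec.order:
        raise ValueError("signal too short for the filter order")
    sos = _signal.butter(
        spec.order, [spec.band_low, spec.band_high], btype="bandpass",
        fs=fs, output="sos",
    )
    return _signal.sosfiltfilt(sos, x)


def notch_filter(
    signal: np.ndarray, fs: float, spec: FilterSpec | None = None
) -> np.ndarray:
    """Zero-phase second-order IIR notch at ``spec.notch_freq``."""
    spec = spec or FilterSpec()
    spec.validate_for(fs)
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if len(x) <= 3 * spec.order:
        raise ValueError("signal too short for the filter order")
    b, a = _signal.iirnotch(spec.notch_freq, spec.notch_quality, fs=fs)
    return _signal.filtfilt(b, a, x)


def filter_session(session: Session, spec: FilterSpec | None = None) -> Session:
    """Bandpass then notch every channel of a session (zero-phase)."""
    spec = spec or FilterSpec()
    out = np.empty_like(session.signal)
    for c in range(session.n_channels):
        y = bandpass_filter(session.signal[:, c], session.sampling_rate, spec)
        out[:, c] = notch_filter(y, session.sampling_rate, spec)
    manifest = dict(session.manifest)
    manifest["filter"] = spec.to_dict()
    return Session(
        signal=out,
        sampling_rate=session.sampling_rate,
        labels=session.labels.copy(),
        manifest=manifest,
    )


def segment_windows(
    session: Session,
    length: int,
    increment_fraction: float,
    channels: Sequence[int] | None = None,
) -> list[Window]:
    """Cut overlapping windows from every gesture-hold run of a session.

    Within a run of R samples the window starts are 0, step, 2*step, ... with
    ``step = round(length * increment_fraction)``, giving
    ``floor((R - length)/step) + 1`` windows, each carrying the run's gesture
    label.  Rest samples are never included.
    """
    if not (0.0 < increment_fraction <= 1.0):
        raise ValueError("increment_fraction must lie in (0, 1]")
    if length < 2:
        raise ValueError("window length must be >= 2")
    runs = session.gesture_runs()
    if not runs:
        raise ValueError("session contains no gesture runs")
    shortest = min(stop - start for _, start, stop in runs)
    if length > shortest:
        raise ValueError(
            f"window length {length} exceeds shortest gesture run ({shortest})"
        )
    step = step_size(length, increment_fraction)
    chans = range(session.n_channels) if channels is None else channels
    windows: list[Window] = []
    for run_index, (label, start, stop) in enumerate(runs):
        n = window_count(stop - start, length, increment_fraction)
        for c in chans:
            for k in range(n):
                s = start + k * step
                windows.append(
                    Window(
                        samples=session.signal[s:s + length, c],
                        label=label,
                        channel=int(c),
                        start=int(s),
                        run_index=run_index,
                    )
                )
    return windows
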