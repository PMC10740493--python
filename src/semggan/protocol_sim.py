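"""Synthetic surface-EMG session generator.

Real sEMG acquisitions follow a timed protocol: a subject holds a gesture for a
fixed number of seconds, rests, and repeats, cycling through all gestures in an
interleaved order.  This module emulates two such protocols — a 6-gesture,
2-channel, 2000 Hz protocol (3 s hold / 3 s rest, 15 repetitions) and a
10-gesture, 2-channel, 4000 Hz protocol (5 s hold, 6 repetitions) — so that the
whole downstream pipeline (filtering, windowing, feature extraction, GAN
training, evaluation) is exercisable without any recordings.

The gesture signal model is amplitude-modulated band-limited Gaussian noise:
sEMG during a steady contraction is well approximated by a stochastic process
whose power concentrates in a muscle- and gesture-dependent band of the
10-500 Hz range.  Distinct gestures get distinct spectral bands and amplitude
scales per channel, which makes the classes learnable by both classifiers and
the GAN.  Rest segments are low-amplitude white noise.  No physiological
realism beyond this (no motor-unit action-potential trains, electrode shift or
fatigue) is attempted.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import signal as _signal

#: Label used for rest (no gesture) samples.
REST_LABEL = -1

#: Rest-segment RMS as a fraction of the smallest gesture amplitude.
REST_AMPLITUDE_FRACTION = 0.05


@dataclasses.dataclass(frozen=True)
class ProtocolSpec:
    """Timing and layout of an acquisition session.

    ``gesture_order`` is the sequence of gesture ids performed; by default the
    gestures are interleaved (0..n-1 repeated ``repetitions`` times) rather
    than blocked, mimicking protocols that avoid consecutive repetitions of
    the same gesture.
    """

    sampling_rate: float
    n_channels: int
    n_gestures: int
    hold_duration: float
    rest_duration: float
    repetitions: int
    gesture_order: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.n_channels < 1 or self.n_gestures < 1 or self.repetitions < 1:
            raise ValueError("counts must be >= 1")
        if self.hold_duration <= 0 or self.rest_duration <= 0:
            raise ValueError("durations must be positive")
        if self.gesture_order is None:
            order = tuple(range(self.n_gestures)) * self.repetitions
            object.__setattr__(self, "gesture_order", order)
        else:
            order = tuple(self.gesture_order)
            object.__setattr__(self, "gesture_order", order)
            for g in range(self.n_gestures):
                if order.count(g) != self.repetitions:
                    raise ValueError(
                        f"gesture {g} must appear exactly {self.repetitions} times"
                    )

    @property
    def hold_samples(self) -> int:
        return int(round(self.hold_duration * self.sampling_rate))

    @property
    def rest_samples(self) -> int:
        return int(round(self.rest_duration * self.sampling_rate))

    @property
    def total_samples(self) -> int:
        return self.n_gestures * self.repetitions * (
            self.hold_samples + self.rest_samples
        )

    def to_dict(self) -> dict:
        return {
            "sampling_rate": self.sampling_rate,
            "n_channels": self.n_channels,
            "n_gestures": self.n_gestures,
            "hold_duration": self.hold_duration,
            "rest_duration": self.rest_duration,
            "repetitions": self.repetitions,
            "gesture_order": list(self.gesture_order),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolSpec":
        d = dict(d)
        if d.get("gesture_order") is not None:
            d["gesture_order"] = tuple(d["gesture_order"])
        return cls(**d)


def private_protocol() -> ProtocolSpec:
    """6 gestures, 2 channels, 3 s hold / 3 s rest, 15 repetitions, 2000 Hz."""
    return ProtocolSpec(
        sampling_rate=2000.0,
        n_channels=2,
        n_gestures=6,
        hold_duration=3.0,
        rest_duration=3.0,
        repetitions=15,
    )


def public_protocol(rest_duration: float = 3.0) -> ProtocolSpec:
    """10 gestures, 2 channels, 5 s hold, 6 repetitions, 4000 Hz.

    The source protocol does not document a rest period, so ``rest_duration``
    is a free parameter (default 3 s).
    """
    return ProtocolSpec(
        sampling_rate=4000.0,
        n_channels=2,
        n_gestures=10,
        hold_duration=5.0,
        rest_duration=rest_duration,
        repetitions=6,
    )


@dataclasses.dataclass(frozen=True)
class GestureModel:
    """Per-gesture generative parameters.

    ``bands``/``amplitudes`` have one entry per channel; ``envelope`` gives
    the attack/plateau/release fractions of the hold (summing to 1) of a
    trapezoidal amplitude envelope.  ``interference_amplitude`` optionally
    adds a power-line sinusoid at 50 Hz.
    """

    bands: tuple[tuple[float, float], ...]
    amplitudes: tuple[float, ...]
    envelope: tuple[float, float, float] = (0.15, 0.70, 0.15)
    interference_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if len(self.bands) != len(self.amplitudes):
            raise ValueError("bands and amplitudes must have one entry per channel")
        for lo, hi in self.bands:
            if not (0.0 < lo < hi):
                raise ValueError(f"invalid band ({lo}, {hi})")
        if any(a <= 0 for a in self.amplitudes):
            raise ValueError("amplitude scales must be positive")
        if not math.isclose(sum(self.envelope), 1.0, abs_tol=1e-9):
            raise ValueError("envelope fractions must sum to 1")


@dataclasses.dataclass
class Session:
    """A recorded (or simulated) multichannel session.

    ``signal`` is ``[n_samples, n_channels]`` in arbitrary units; ``labels``
    is a per-sample gesture id with :data:`REST_LABEL` marking rest.
    """

    signal: np.ndarray
    sampling_rate: float
    labels: np.ndarray
    manifest: dict

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D [n_samples, n_channels]")
        if self.labels.shape != (self.signal.shape[0],):
            raise ValueError("labels length must equal signal length")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[1]

    def gesture_runs(self) -> list[tuple[int, int, int]]:
        """Contiguous non-rest runs as ``(label, start, stop)`` half-open."""
        runs: list[tuple[int, int, int]] = []
        labels = self.labels
        n = len(labels)
        i = 0
        while i < n:
            if labels[i] == REST_LABEL:
                i += 1
                continue
            j = i
            while j < n and labels[j] == labels[i]:
                j += 1
            runs.append((int(labels[i]), i, j))
            i = j
        return runs


def make_default_gesture_models(
    n_gestures: int, n_channels: int, seed: int
) -> list[GestureModel]:
    """Deterministic, pairwise-distinct gesture models.

    Spectral bands are spread across the 10-500 Hz sEMG passband (so bandpass
    filtering does not erase class structure) and amplitude scales are spread
    over roughly [0.6, 1.8] a.u. with per-channel jitter.
    """
    if n_gestures < 2:
        raise ValueError("n_gestures must be >= 2 (classification needs >= 2 classes)")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    rng = np.random.default_rng(seed)
    centers = np.linspace(60.0, 420.0, n_gestures)
    amps = np.linspace(0.6, 1.8, n_gestures)
    models = []
    for g in range(n_gestures):
        bands = []
        amplitudes = []
        for _c in range(n_channels):
            center = centers[g] * (1.0 + 0.05 * rng.uniform(-1, 1))
            half_width = 30.0 * (1.0 + 0.3 * rng.uniform(-1, 1))
            lo = max(15.0, center - half_width)
            hi = min(495.0, center + half_width)
            bands.append((float(lo), float(hi)))
            amplitudes.append(float(amps[g] * (1.0 + 0.1 * rng.uniform(-1, 1))))
        models.append(GestureModel(bands=tuple(bands), amplitudes=tuple(amplitudes)))
    return models


def _envelope(n: int, fractions: tuple[float, float, float]) -> np.ndarray:
    na = int(round(fractions[0] * n))
    nr = int(round(fractions[2] * n))
    np_ = n - na - nr
    parts = []
    if na:
        parts.append(np.linspace(0.0, 1.0, na, endpoint=False))
    parts.append(np.ones(np_))
    if nr:
        parts.append(np.linspace(1.0, 0.0, nr, endpoint=False))
    env = np.concatenate(parts)
    return env[:n]


def _band_noise(rng: np.random.Generator, n: int, band: tuple[float, float],
                fs: float) -> np.ndarray:
    white = rng.standard_normal(n)
    nyq = fs / 2.0
    lo = min(band[0], nyq * 0.98)
    hi = min(band[1], nyq * 0.99)
    sos = _signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = _signal.sosfiltfilt(sos, white)
    r = float(np.sqrt(np.mean(x**2)))
    if r > 0:
        x = x / r
    return x


def simulate_session(
    protocol: ProtocolSpec, models: Sequence[GestureModel], seed: int
) -> Session:
    """Simulate one session following ``protocol`` with the given gesture models.

    Each entry of ``protocol.gesture_order`` contributes one hold segment
    (band-limited noise shaped by the gesture envelope) followed by one rest
    segment (white noise at 5% of the smallest gesture amplitude).  For a
    fixed seed the output is bit-reproducible.
    """
    if len(models) != protocol.n_gestures:
        raise ValueError(
            f"expected {protocol.n_gestures} gesture models, got {len(models)}"
        )
    rng = np.random.default_rng(seed)
    fs = protocol.sampling_rate
    nh, nr = protocol.hold_samples, protocol.rest_samples
    min_amp = min(min(m.amplitudes) for m in models)
    rest_sigma = REST_AMPLITUDE_FRACTION * min_amp

    total = protocol.total_samples
    signal = np.empty((total, protocol.n_channels))
    labels = np.empty(total, dtype=int)
    pos = 0
    for g in protocol.gesture_order:
        model = models[g]
        env = _envelope(nh, model.envelope)
        for c in range(protocol.n_channels):
            x = _band_noise(rng, nh, model.bands[c], fs)
            x = x * model.amplitudes[c] * env
            if model.interference_amplitude:
                t = (np.arange(nh) + pos) / fs
                x = x + model.interference_amplitude * np.sin(2 * np.pi * 50.0 * t)
            signal[pos:pos + nh, c] = x
        labels[pos:pos + nh] = g
        pos += nh
        signal[pos:pos + nr, :] = rest_sigma * rng.standard_normal(
            (nr, protocol.n_channels)
        )
        labels[pos:pos + nr] = REST_LABEL
        pos += nr

    manifest = {
        "subject": 0,
        "fs_hz": fs,
        "n_channels": protocol.n_channels,
        "protocol": protocol.to_dict(),
        "seed": int(seed),
    }
    return Session(signal=signal, sampling_rate=fs, labels=labels, manifest=manifest)


def inject_interference(session: Session, freq: float, amplitude: float) -> Session:
    """Return a copy of ``session`` with an added sinusoid at ``freq`` Hz.

    Models power-line interference; the original session is left unmodified.
    """
    if not (0.0 < freq < session.sampling_rate / 2.0):
        raise ValueError(
            f"freq must lie in (0, {session.sampling_rate / 2}) Hz, got {freq}"
        )
    t = np.arange(session.n_samples) / session.sampling_rate
    tone = amplitude * np.sin(2 * np.pi * freq * t)
    return Session(
        signal=session.signal + tone[:, None],
        sampling_rate=session.sampling_rate,
        labels=session.labels.copy(),
        manifest=dict(session.manifest),
    )


def windows_to_session(
    windows: Sequence[np.ndarray],
    labels: Sequence[int],
    sampling_rate: float,
    n_channels: int = 1,
    rest_gap: int = 64,
    windows_per_run: int = 1,
    manifest: dict | None = None,
) -> Session:
    """Assemble fixed-length segments (e.g. GAN output) into a Session.

    Consecutive same-class segments are concatenated ``windows_per_run`` at
    a time into gesture-hold runs (replicated across channels), separated by
    ``rest_gap`` zero rest samples, so that the standard windowing/feature
    machinery applies to generated data unchanged.
    """
    if len(windows) != len(labels):
        raise ValueError("one label per window required")
    if not windows:
        raise ValueError("need at least one window")
    by_class: dict[int, list[np.ndarray]] = {}
    for w, g in zip(windows, labels):
        by_class.setdefault(int(g), []).append(np.asarray(w, dtype=float).ravel())
    chunks = []
    labs = []
    for g, ws in by_class.items():
        for i in range(0, len(ws), windows_per_run):
            run = np.concatenate(ws[i:i + windows_per_run])
            chunks.append(np.tile(run[:, None], (1, n_channels)))
            labs.append(np.full(len(run), g))
            chunks.append(np.zeros((rest_gap, n_channels)))
            labs.append(np.full(rest_gap, REST_LABEL))
    return Session(
        signal=np.concatenate(chunks, axis=0),
        sampling_rate=sampling_rate,
        labels=np.concatenate(labs),
        manifest=manifest or {"subject": -1, "fs_hz": sampling_rate,
                              "n_channels": n_channels, "protocol": None,
                              "seed": None, "synthetic": True},
    )
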