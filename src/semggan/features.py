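"""Per-window sEMG features and feature-matrix assembly.

Time-domain features over a window x_1..x_T:

* MAV  — mean absolute value,           (1/T) sum |x_t|
* WL   — waveform length,               sum_{t=2..T} |x_t - x_{t-1}|
* MAVS — MAV slope between windows,     MAV(w+1) - MAV(w)
* IAV  — integrated absolute value,     sum |x_t|  (= T * MAV exactly)
* HIST — B-bin amplitude histogram over [min x, max x]
* RMS  — root mean square
* SSC  — slope-sign-change count (interior points where the slope product
         exceeds a threshold)
* ZC   — zero-crossing count (strict sign changes beyond a threshold)

Time-frequency feature:

* mDWT — marginal discrete wavelet transform: the sum of absolute detail
  coefficients per level of a Daubechies-7 decomposition, three levels deep
  by default, with symmetric signal extension at the boundaries.

``feature_matrix`` evaluates all of these per window and pairs consecutive
windows within each gesture run for MAVS; the final window of each run is
dropped so every retained row has a defined MAVS.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import pywt

from .sigproc import Window

#: Metadata columns of a feature matrix (everything else is a feature).
META_COLUMNS = ("label", "channel", "window_index")


@dataclasses.dataclass(frozen=True)
class FeatureSpec:
    histogram_bins: int = 10
    ssc_threshold: float = 0.0
    zc_threshold: float = 0.0
    wavelet_name: str = "db7"
    wavelet_levels: int = 3

    def __post_init__(self) -> None:
        if self.histogram_bins < 2:
            raise ValueError("histogram_bins must be >= 2")
        if self.ssc_threshold < 0 or self.zc_threshold < 0:
            raise ValueError("thresholds must be >= 0")
        if self.wavelet_levels < 1:
            raise ValueError("wavelet_levels must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def feature_names(self) -> list[str]:
        names = ["MAV", "WL", "MAVS", "IAV", "RMS", "SSC", "ZC"]
        names += [f"HIST_{i}" for i in range(1, self.histogram_bins + 1)]
        names += [f"mDWT_{l}" for l in range(1, self.wavelet_levels + 1)]
        return names


def _as1d(window) -> np.ndarray:
    x = np.asarray(getattr(window, "samples", window), dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty window")
    return x


def mav(window) -> float:
    """Mean absolute value."""
    x = _as1d(window)
    return float(np.mean(np.abs(x)))


def wl(window) -> float:
    """Waveform length (sum of absolute first differences)."""
    x = _as1d(window)
    if len(x) < 2:
        raise ValueError("waveform length needs T >= 2")
    return float(np.sum(np.abs(np.diff(x))))


def mavs(window_w, window_w_plus_1) -> float:
    """MAV slope between two adjacent windows: MAV(w+1) - MAV(w)."""
    return mav(window_w_plus_1) - mav(window_w)


def iav(window) -> float:
    """Integrated absolute value (T times the MAV)."""
    x = _as1d(window)
    return float(np.sum(np.abs(x)))


def rms(window) -> float:
    """Root mean square amplitude."""
    x = _as1d(window)
    return float(np.sqrt(np.mean(x**2)))


def hist(window, bins: int = 10) -> np.ndarray:
    """Amplitude histogram: ``bins`` equal-width bins over [min x, max x].

    The rightmost edge is inclusive (numpy convention).  For a constant
    window the range degenerates; all T counts are assigned to the bin
    containing the value under a unit-width range centred on it.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    x = _as1d(window)
    lo, hi = float(np.min(x)), float(np.max(x))
    if lo == hi:
        counts, _ = np.histogram(x, bins=bins, range=(lo - 0.5, hi + 0.5))
    else:
        counts, _ = np.histogram(x, bins=bins, range=(lo, hi))
    return counts.astype(int)


def ssc(window, threshold: float = 0.0) -> int:
    """Slope-sign-change count over interior points.

    Counts t with (x_t - x_{t-1}) * (x_t - x_{t+1}) > threshold.
    """
    x = _as1d(window)
    if len(x) < 3:
        raise ValueError("slope sign change needs T >= 3")
    left = x[1:-1] - x[:-2]
    right = x[1:-1] - x[2:]
    return int(np.sum(left * right > threshold))


def zc(window, threshold: float = 0.0) -> int:
    """Zero-crossing count: t with x_t * x_{t+1} < -threshold."""
    x = _as1d(window)
    if len(x) < 2:
        raise ValueError("zero crossing needs T >= 2")
    return int(np.sum(x[:-1] * x[1:] < -threshold))


def mdwt(window, spec: FeatureSpec | None = None) -> np.ndarray:
    """Marginal DWT: sum of |detail coefficients| per decomposition level.

    Returns one marginal per level, ordered level 1 (finest) to
    ``spec.wavelet_levels`` (deepest).  Daubechies-7 with symmetric signal
    extension by default.
    """
    spec = spec or FeatureSpec()
    x = _as1d(window)
    if 2**spec.wavelet_levels > len(x):
        raise ValueError(
            f"window of length {len(x)} too short for "
            f"{spec.wavelet_levels} decomposition levels"
        )
    coeffs = pywt.wavedec(
        x, spec.wavelet_name, mode="symmetric", level=spec.wavelet_levels
    )
    # coeffs = [cA_L, cD_L, ..., cD_1]; detail of level l is coeffs[-l]
    return np.array(
        [float(np.sum(np.abs(coeffs[-l]))) for l in range(1, spec.wavelet_levels + 1)]
    )


def feature_vector(window, next_window, spec: FeatureSpec) -> np.ndarray:
    x = _as1d(window)
    vals = [
        mav(x),
        wl(x),
        mavs(x, _as1d(next_window)),
        iav(x),
        rms(x),
        float(ssc(x, spec.ssc_threshold)),
        float(zc(x, spec.zc_threshold)),
    ]
    vals.extend(hist(x, spec.histogram_bins).astype(float))
    vals.extend(mdwt(x, spec))
    return np.array(vals)


def feature_matrix(
    windows: Sequence[Window], spec: FeatureSpec | None = None, **provenance
) -> pd.DataFrame:
    """One feature row per window, MAVS paired within each (channel, run).

    Windows are grouped by ``(channel, run_index)`` and ordered by start;
    within each group the last window is dropped so that MAVS (which needs
    the *next* window) is defined for every retained row.  Metadata columns
    ``label``, ``channel``, ``window_index`` follow the feature columns.
    Extra keyword arguments are stored in ``DataFrame.attrs`` as provenance.
    """
    spec = spec or FeatureSpec()
    groups: dict[tuple[int, int], list[Window]] = {}
    for w in windows:
        groups.setdefault((w.channel, w.run_index), []).append(w)
    rows = []
    meta = []
    for key in sorted(groups):
        group = sorted(groups[key], key=lambda w: w.start)
        for i in range(len(group) - 1):
            rows.append(feature_vector(group[i], group[i + 1], spec))
            meta.append((group[i].label, group[i].channel, i))
    if not rows:
        raise ValueError("no feature rows (each run needs >= 2 windows for MAVS)")
    df = pd.DataFrame(rows, columns=spec.feature_names())
    mdf = pd.DataFrame(meta, columns=list(META_COLUMNS))
    out = pd.concat([df, mdf], axis=1)
    out.attrs["feature_spec"] = spec.to_dict()
    out.attrs.update(provenance)
    return out


def feature_columns(df: pd.DataFrame) -> list[str]:
    """Names of feature (non-metadata) columns of a feature matrix."""
    return [c for c in df.columns if c not in META_COLUMNS]


def feature_array(df: pd.DataFrame) -> np.ndarray:
    """Feature values of a feature matrix as a float array."""
    return df[feature_columns(df)].to_numpy(dtype=float)
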