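"""One-dimensional deep convolutional GAN for sEMG window synthesis.

The generator maps a latent Gaussian vector through a dense projection and
six convolutional blocks (three of which double the temporal resolution by
nearest-neighbour upsampling), ending in a dense layer and a tanh, so every
output lies in [-1, 1] at exactly the configured length.

The discriminator scores a candidate window with two branches: a seven-block
convolutional stack over the raw signal, and a small convolutional branch
over a *side-feature* vector — minibatch-discrimination similarity, one-sided
FFT magnitudes, a DTW distance to a real exemplar, and Daubechies-7 wavelet
detail coefficients — concatenated before a dense head with a sigmoid output.

Training is the standard alternating scheme with binary cross-entropy and
one-sided label smoothing: real targets are softened to alpha (default 0.9)
while synthetic targets stay at beta (default 0).  The generator update uses
the non-saturating objective (BCE of D(G(z)) against 1) computed from
synthetic samples only.  Adversarial gradient reaches the generator through
the raw-signal branch and through the FFT branch (exact spectral adjoint);
the DTW, wavelet and minibatch components act as fixed signal descriptors.

One GAN is trained per gesture class; real windows are min-max normalised to
[-1, 1] per class and the constants stored with the model.
"""

from __future__ import annotations

import dataclasses
import json
import time
from typing import Sequence

import numpy as np
import pywt

from . import _nn
from ._nn import (
    Adam, BatchNorm1d, Conv1d, Dense, Dropout, Flatten, LeakyReLU, Param,
    ReLU, Reshape, Sequential, Sigmoid, Tanh, UpsampleNN, zero_grad,
)
from .features import FeatureSpec

EPS = 1e-7

try:  # numba accelerates the DTW recurrence when present
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None


# ---------------------------------------------------------------------------
# specs


@dataclasses.dataclass(frozen=True)
class GeneratorSpec:
    latent_dim: int = 100
    output_length: int = 1000
    n_blocks: int = 6
    upsample_blocks: int = 3
    channels: tuple[int, ...] = (32, 32, 16, 16, 8, 4)
    kernel_size: int = 5
    dropout: float = 0.1

    def __post_init__(self) -> None:
        if len(self.channels) != self.n_blocks:
            raise ValueError("one channel width per block required")
        factor = 2**self.upsample_blocks
        if self.output_length % factor:
            raise ValueError(
                f"output_length must be divisible by {factor} "
                f"(2^upsample_blocks)"
            )
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channels"] = list(self.channels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorSpec":
        d = dict(d)
        d["channels"] = tuple(d["channels"])
        return cls(**d)


@dataclasses.dataclass(frozen=True)
class DiscriminatorSpec:
    n_blocks: int = 7
    channels: tuple[int, ...] = (12, 12, 24, 24, 32, 32, 32)
    strides: tuple[int, ...] = (2, 2, 2, 2, 2, 1, 1)
    kernel_size: int = 5
    leaky_slope: float = 0.2
    dropout: float = 0.25
    side_channels: int = 8
    side_stride: int = 4
    minibatch_kernels: int = 8
    minibatch_dim: int = 8
    hidden: int = 64

    def __post_init__(self) -> None:
        if len(self.channels) != self.n_blocks or len(self.strides) != self.n_blocks:
            raise ValueError("one channel width and stride per block required")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channels"] = list(self.channels)
        d["strides"] = list(self.strides)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DiscriminatorSpec":
        d = dict(d)
        d["channels"] = tuple(d["channels"])
        d["strides"] = tuple(d["strides"])
        return cls(**d)


@dataclasses.dataclass(frozen=True)
class SmoothingSpec:
    """One-sided label smoothing targets: real -> alpha, synthetic -> beta."""

    alpha: float = 0.9
    beta: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta < self.alpha <= 1.0):
            raise ValueError("need 0 <= beta < alpha <= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    epochs: int = 200
    lr: float = 2e-4
    lr_d: float | None = 1e-4  # discriminator rate; None means same as lr
    lr_decay: bool = True  # hold for the first half, then exponential anneal
    g_steps: int = 1  # generator updates per discriminator update
    beta1: float = 0.5
    beta2: float = 0.999
    seed: int = 0
    reference_size: int = 8

    def __post_init__(self) -> None:
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (minibatch discrimination)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class TrainLog:
    d_losses: list[float]
    g_losses: list[float]
    seed: int
    config: dict
    wall_seconds: float = 0.0


@dataclasses.dataclass
class GanModel:
    generator: "Generator"
    discriminator: "Discriminator"
    gspec: GeneratorSpec
    dspec: DiscriminatorSpec
    smoothing: SmoothingSpec
    norm_lo: float
    norm_hi: float
    class_id: int | None = None
    feature_spec: FeatureSpec = dataclasses.field(default_factory=FeatureSpec)


class GanTrainingError(RuntimeError):
    """Raised when a training step produces a non-finite loss."""

    def __init__(self, message: str, diagnostics: dict):
        super().__init__(message)
        self.diagnostics = diagnostics


# ---------------------------------------------------------------------------
# losses and label handling


def bce_loss(predictions, targets) -> float:
    """Mean binary cross-entropy with predictions clipped to (eps, 1-eps)."""
    h = np.clip(np.asarray(predictions, dtype=float), EPS, 1.0 - EPS)
    y = np.asarray(targets, dtype=float)
    if h.shape != y.shape:
        raise ValueError("predictions and targets must have equal length")
    return float(-np.mean(y * np.log(h) + (1.0 - y) * np.log(1.0 - h)))


def bce_grad(predictions, targets) -> np.ndarray:
    """Gradient of :func:`bce_loss` with respect to the predictions."""
    h = np.clip(np.asarray(predictions, dtype=float), EPS, 1.0 - EPS)
    y = np.asarray(targets, dtype=float)
    return (h - y) / (h * (1.0 - h)) / h.size


def smooth_labels(targets, spec: SmoothingSpec | None = None) -> np.ndarray:
    """Map hard labels to soft targets: 1 -> alpha, 0 -> beta (one-sided)."""
    spec = spec or SmoothingSpec()
    t = np.asarray(targets)
    return np.where(t == 1, spec.alpha, spec.beta).astype(float)


def optimal_discriminator(
    p_data: float, p_model: float, spec: SmoothingSpec | None = None
) -> float:
    """Fixed point of the smoothed discriminator objective.

    D*(x) = (alpha p_data + beta p_model) / (p_data + p_model).
    """
    spec = spec or SmoothingSpec()
    if p_data < 0 or p_model < 0 or p_data + p_model <= 0:
        raise ValueError("densities must be non-negative with positive sum")
    return (spec.alpha * p_data + spec.beta * p_model) / (p_data + p_model)


# ---------------------------------------------------------------------------
# side features


def _dtw_core_py(a: np.ndarray, b: np.ndarray) -> float:
    n, m = len(a), len(b)
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            c = abs(ai - b[j - 1])
            d = D[i - 1, j]
            if D[i - 1, j - 1] < d:
                d = D[i - 1, j - 1]
            if D[i, j - 1] < d:
                d = D[i, j - 1]
            D[i, j] = c + d
    return float(D[n, m])


_dtw_core = _njit(cache=False)(_dtw_core_py) if _njit is not None else _dtw_core_py


def dtw_distance(a, b) -> float:
    """Classic dynamic-time-warping distance with |a_i - b_j| local cost.

    Full window (no band constraint); symmetric; zero iff the sequences are
    identical up to warping of repeated values.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("sequences must be non-empty")
    return float(_dtw_core(a, b))


def fft_magnitude(window) -> np.ndarray:
    """One-sided FFT magnitude spectrum, length floor(L/2) + 1."""
    x = np.asarray(getattr(window, "samples", window), dtype=float)
    return np.abs(np.fft.rfft(x, axis=-1))


def wavelet_bank(window, spec: FeatureSpec | None = None) -> np.ndarray:
    """Concatenated DWT detail coefficients, level 1 (finest) to deepest.

    Fixed length for a fixed input length; shares the decomposition
    convention (Daubechies-7, symmetric extension) with ``features.mdwt``.
    """
    spec = spec or FeatureSpec()
    x = np.asarray(getattr(window, "samples", window), dtype=float)
    coeffs = pywt.wavedec(
        x, spec.wavelet_name, mode="symmetric", level=spec.wavelet_levels, axis=-1
    )
    details = [coeffs[-l] for l in range(1, spec.wavelet_levels + 1)]
    return np.concatenate(details, axis=-1)


def wavelet_bank_length(L: int, spec: FeatureSpec | None = None) -> int:
    return wavelet_bank(np.zeros(L), spec).shape[-1]


def make_minibatch_kernel(
    input_dim: int, n_kernels: int, kernel_dim: int, seed: int
) -> np.ndarray:
    """Fixed random projection tensor (input_dim, n_kernels, kernel_dim)."""
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, 1.0 / np.sqrt(input_dim),
                      size=(input_dim, n_kernels, kernel_dim))


def minibatch_features(batch, kernel: np.ndarray | None = None, *,
                       n_kernels: int = 8, kernel_dim: int = 8,
                       seed: int = 0) -> np.ndarray:
    """Cross-sample similarity summary per batch element (anti mode-collapse).

    Each sample is projected by a fixed random kernel into ``n_kernels``
    rows; the per-kernel similarity to every other sample is
    exp(-mean |row_i - row_j|), averaged over kernels and partners.  Outputs
    are permutation-equivariant, and a batch of identical samples scores 1.
    """
    out, _ = minibatch_features_forward(batch, kernel, n_kernels=n_kernels,
                                        kernel_dim=kernel_dim, seed=seed)
    return out


def minibatch_features_forward(batch, kernel: np.ndarray | None = None, *,
                               n_kernels: int = 8, kernel_dim: int = 8,
                               seed: int = 0):
    """:func:`minibatch_features` plus the cache for its backward pass."""
    X = np.asarray(batch, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("batch must be 2-D with at least 2 samples")
    if kernel is None:
        kernel = make_minibatch_kernel(X.shape[1], n_kernels, kernel_dim, seed)
    B = X.shape[0]
    _, K, kernel_dim = kernel.shape
    M = np.tensordot(X, kernel, axes=1)                # (B, K, D)
    delta = M[:, None, :, :] - M[None, :, :, :]        # (B, B, K, D)
    diff = np.abs(delta).mean(axis=3)                  # (B, B, K)
    c = np.exp(-diff)
    sim = c.mean(axis=2)                               # (B, B)
    out = (sim.sum(axis=1) - 1.0) / (B - 1)
    return out, (kernel, np.sign(delta), c, B, K, kernel_dim)


def minibatch_features_backward(grad_out: np.ndarray, cache) -> np.ndarray:
    """Gradient of the similarity summary with respect to the batch.

    The score is symmetric in each pair, so sample i's projection receives
    contributions from both its own and its partners' upstream gradients.
    """
    kernel, sign, c, B, K, D = cache
    g = np.asarray(grad_out, dtype=float)
    pair_w = (g[:, None] + g[None, :]) / (B - 1) / K   # (B, B)
    gM = -(pair_w[:, :, None, None] * c[:, :, :, None] * sign / D).sum(axis=1)
    return np.tensordot(gM, kernel, axes=([1, 2], [1, 2]))


def side_feature_length(L: int, spec: FeatureSpec | None = None) -> int:
    """Length of the discriminator side-feature vector for window length L."""
    return (L // 2 + 1) + 1 + wavelet_bank_length(L, spec) + 1


class _SideFeatures:
    """Side-feature batch with the caches needed for generator gradients."""

    __slots__ = ("vec", "fft_cache", "fft_scale", "n_fft", "mb_cache")

    def __init__(self, vec, fft_cache, fft_scale, n_fft, mb_cache):
        self.vec = vec
        self.fft_cache = fft_cache
        self.fft_scale = fft_scale
        self.n_fft = n_fft
        self.mb_cache = mb_cache

    def backward_to_signal(self, grad_vec: np.ndarray) -> np.ndarray:
        """Pull the side-vector gradient back to the raw windows.

        The FFT-magnitude block uses its exact spectral adjoint; the DTW,
        wavelet and minibatch-similarity blocks are stop-gradient
        descriptors (for self-similar narrowband classes the similarity
        gradient rewards collapse, so it is deliberately not routed).
        """
        return _nn.rfft_magnitude_backward(
            grad_vec[:, :self.n_fft] * self.fft_scale, self.fft_cache
        )


def _side_features(X: np.ndarray, reference: np.ndarray,
                   ref_rng: np.random.Generator, mb_kernel: np.ndarray,
                   fspec: FeatureSpec) -> _SideFeatures:
    B, L = X.shape
    scale = 1.0 / np.sqrt(L)
    mag, cache = _nn.rfft_magnitude_forward(X)
    exemplar = reference[ref_rng.integers(len(reference))]
    dtw_col = np.array([dtw_distance(x, exemplar) for x in X])[:, None] / L
    wav = wavelet_bank(X, fspec) * scale
    mb, mb_cache = minibatch_features_forward(X, mb_kernel)
    vec = np.concatenate([mag * scale, dtw_col, wav, mb[:, None]], axis=1)
    return _SideFeatures(vec, cache, scale, mag.shape[1], mb_cache)


# ---------------------------------------------------------------------------
# networks


def _seed_int(seed_seq_or_int) -> int:
    if isinstance(seed_seq_or_int, np.random.SeedSequence):
        return int(seed_seq_or_int.generate_state(1)[0] & 0x7FFFFFFF)
    return int(seed_seq_or_int)


class Generator:
    """Dense projection + 6 conv blocks (3 upsampling) + dense + tanh."""

    def __init__(self, spec: GeneratorSpec, seed: int):
        self.spec = spec
        ss = np.random.SeedSequence(_seed_int(seed))
        init_rng = np.random.default_rng(ss.spawn(1)[0])
        self.dropout_rng = np.random.default_rng(ss.spawn(1)[0])
        L0 = spec.output_length // 2**spec.upsample_blocks
        up_at = {
            round(i * spec.n_blocks / spec.upsample_blocks)
            for i in range(spec.upsample_blocks)
        }
        layers: list[_nn.Layer] = [
            Dense(spec.latent_dim, spec.channels[0] * L0, init_rng),
            Reshape((spec.channels[0], L0)),
        ]
        prev = spec.channels[0]
        for b in range(spec.n_blocks):
            if b in up_at:
                layers.append(UpsampleNN(2))
            layers.append(Conv1d(prev, spec.channels[b], spec.kernel_size, init_rng))
            layers.append(BatchNorm1d(spec.channels[b]))
            layers.append(ReLU())
            layers.append(Dropout(spec.dropout, self.dropout_rng))
            prev = spec.channels[b]
        layers += [
            Flatten(),
            Dense(prev * spec.output_length, spec.output_length, init_rng),
            Tanh(),
        ]
        self.net = Sequential(layers)

    def params(self) -> list[Param]:
        return self.net.params()

    def forward(self, z: np.ndarray, training: bool = False) -> np.ndarray:
        return self.net.forward(np.asarray(z, dtype=float), training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(grad)


class Discriminator:
    """Raw-signal conv stack + side-feature conv branch + dense head."""

    def __init__(self, spec: DiscriminatorSpec, input_length: int, seed: int,
                 feature_spec: FeatureSpec | None = None):
        self.spec = spec
        self.input_length = input_length
        self.feature_spec = feature_spec or FeatureSpec()
        self.side_dim = side_feature_length(input_length, self.feature_spec)
        ss = np.random.SeedSequence(_seed_int(seed))
        init_rng = np.random.default_rng(ss.spawn(1)[0])
        self.dropout_rng = np.random.default_rng(ss.spawn(1)[0])

        main: list[_nn.Layer] = []
        prev, L = 1, input_length
        for b in range(spec.n_blocks):
            main.append(Conv1d(prev, spec.channels[b], spec.kernel_size,
                               init_rng, stride=spec.strides[b]))
            if b > 0:
                main.append(BatchNorm1d(spec.channels[b]))
            main.append(LeakyReLU(spec.leaky_slope))
            main.append(Dropout(spec.dropout, self.dropout_rng))
            prev = spec.channels[b]
            L = -(-L // spec.strides[b])
        main.append(Flatten())
        self.main = Sequential(main)
        self._main_out = prev * L

        side: list[_nn.Layer] = []
        prev, S = 1, self.side_dim
        for _ in range(2):
            side.append(Conv1d(prev, spec.side_channels, spec.kernel_size,
                               init_rng, stride=spec.side_stride))
            side.append(LeakyReLU(spec.leaky_slope))
            side.append(Dropout(spec.dropout, self.dropout_rng))
            prev = spec.side_channels
            S = -(-S // spec.side_stride)
        side.append(Flatten())
        self.side = Sequential(side)
        self._side_out = prev * S

        self.head = Sequential([
            Dense(self._main_out + self._side_out, spec.hidden, init_rng),
            LeakyReLU(spec.leaky_slope),
            Dense(spec.hidden, 1, init_rng),
            Sigmoid(),
        ])

    def params(self) -> list[Param]:
        return self.main.params() + self.side.params() + self.head.params()

    def forward(self, x: np.ndarray, side: np.ndarray,
                training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        h1 = self.main.forward(x[:, None, :], training)
        h2 = self.side.forward(np.asarray(side, dtype=float)[:, None, :], training)
        h = np.concatenate([h1, h2], axis=1)
        p = self.head.forward(h, training)
        return p[:, 0]

    def backward(self, grad_p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        g = self.head.backward(np.asarray(grad_p)[:, None])
        g1, g2 = g[:, :self._main_out], g[:, self._main_out:]
        gx = self.main.backward(g1)[:, 0, :]
        gside = self.side.backward(g2)[:, 0, :]
        return gx, gside


def build_generator(spec: GeneratorSpec, seed: int) -> Generator:
    """Deterministically initialised generator for ``spec``."""
    return Generator(spec, seed)


def build_discriminator(spec: DiscriminatorSpec, input_length: int, seed: int,
                        feature_spec: FeatureSpec | None = None) -> Discriminator:
    """Deterministically initialised discriminator for ``spec``."""
    return Discriminator(spec, input_length, seed, feature_spec)


# ---------------------------------------------------------------------------
# training / sampling


def _stack_windows(real_windows) -> np.ndarray:
    rows = [np.asarray(getattr(w, "samples", w), dtype=float).ravel()
            for w in real_windows]
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"all real windows must share one length, got {lengths}")
    return np.stack(rows)


def train(
    real_windows: Sequence,
    gspec: GeneratorSpec | None = None,
    dspec: DiscriminatorSpec | None = None,
    smoothing: SmoothingSpec | None = None,
    config: TrainConfig | None = None,
    feature_spec: FeatureSpec | None = None,
    class_id: int | None = None,
    callback=None,
) -> tuple[GanModel, TrainLog]:
    """Adversarially train one per-class GAN on real windows.

    Windows are min-max normalised to [-1, 1]; each step runs one
    discriminator update (real batch at target alpha, synthetic batch at
    target beta) followed by one generator update (synthetic batch at target
    1).  Raises :class:`GanTrainingError` on a non-finite loss.
    """
    dspec = dspec or DiscriminatorSpec()
    smoothing = smoothing or SmoothingSpec()
    config = config or TrainConfig()
    fspec = feature_spec or FeatureSpec()

    X = _stack_windows(real_windows)
    n, L = X.shape
    gspec = gspec or GeneratorSpec(output_length=L)
    if gspec.output_length != L:
        raise ValueError(
            f"generator output_length {gspec.output_length} != window length {L}"
        )
    if n < 2 * config.batch_size:
        raise ValueError("need at least 2 * batch_size real windows")

    lo, hi = float(X.min()), float(X.max())
    if hi <= lo:
        raise ValueError("real windows are constant; cannot normalise")
    Xn = 2.0 * (X - lo) / (hi - lo) - 1.0

    ss = np.random.SeedSequence(config.seed)
    s_g, s_d, s_shuffle, s_latent, s_ref, s_mb = ss.spawn(6)
    gen = Generator(gspec, s_g)
    disc = Discriminator(dspec, L, s_d, fspec)
    shuffle_rng = np.random.default_rng(s_shuffle)
    latent_rng = np.random.default_rng(s_latent)
    ref_rng = np.random.default_rng(s_ref)
    mb_kernel = make_minibatch_kernel(
        L, dspec.minibatch_kernels, dspec.minibatch_dim, _seed_int(s_mb)
    )
    reference = Xn[shuffle_rng.choice(n, size=min(config.reference_size, n),
                                      replace=False)]

    g_params, d_params = gen.params(), disc.params()
    adam_g = Adam(g_params, lr=config.lr, beta1=config.beta1, beta2=config.beta2)
    adam_d = Adam(d_params, lr=config.lr_d if config.lr_d is not None else config.lr,
                  beta1=config.beta1, beta2=config.beta2)

    m = config.batch_size
    base_lr_g = adam_g.lr
    base_lr_d = adam_d.lr
    d_losses: list[float] = []
    g_losses: list[float] = []
    t0 = time.time()
    for epoch in range(config.epochs):
        if config.lr_decay:
            # full rate for the first half (convergence dynamics untouched),
            # then exponential anneal (halflife epochs/20) so the converged
            # model is frozen instead of drifting into late-stage collapse
            half = config.epochs / 2
            if epoch >= half:
                halflife = max(config.epochs / 20.0, 1.0)
                scale = 2.0 ** (-(epoch - half) / halflife)
                adam_g.lr = base_lr_g * scale
                adam_d.lr = base_lr_d * scale
        order = shuffle_rng.permutation(n)
        for b0 in range(0, n - m + 1, m):
            xb = Xn[order[b0:b0 + m]]

            # --- discriminator step (separate real and synthetic passes)
            zero_grad(d_params)
            side_r = _side_features(xb, reference, ref_rng, mb_kernel, fspec)
            p_r = disc.forward(xb, side_r.vec, training=True)
            y_r = smooth_labels(np.ones(m), smoothing)
            loss_r = bce_loss(p_r, y_r)
            disc.backward(bce_grad(p_r, y_r) * 0.5)

            z = latent_rng.standard_normal((m, gspec.latent_dim))
            xf = gen.forward(z, training=True)
            side_f = _side_features(xf, reference, ref_rng, mb_kernel, fspec)
            p_f = disc.forward(xf, side_f.vec, training=True)
            y_f = smooth_labels(np.zeros(m), smoothing)
            loss_f = bce_loss(p_f, y_f)
            disc.backward(bce_grad(p_f, y_f) * 0.5)
            adam_d.step()
            d_loss = 0.5 * (loss_r + loss_f)

            # --- generator step(s)
            for _ in range(config.g_steps):
                zero_grad(g_params)
                zero_grad(d_params)
                z = latent_rng.standard_normal((m, gspec.latent_dim))
                xf = gen.forward(z, training=True)
                side_f = _side_features(xf, reference, ref_rng, mb_kernel, fspec)
                p = disc.forward(xf, side_f.vec, training=True)
                ones = np.ones(m)
                g_loss = bce_loss(p, ones)
                gx, gside = disc.backward(bce_grad(p, ones))
                gx = gx + side_f.backward_to_signal(gside)
                gen.backward(gx)
                adam_g.step()

            if not (np.isfinite(d_loss) and np.isfinite(g_loss)):
                raise GanTrainingError(
                    f"non-finite loss at epoch {epoch}",
                    diagnostics={
                        "epoch": epoch, "d_loss": d_loss, "g_loss": g_loss,
                        "p_real_range": [float(p_r.min()), float(p_r.max())],
                        "p_fake_range": [float(p_f.min()), float(p_f.max())],
                        "config": config.to_dict(),
                    },
                )
            d_losses.append(float(d_loss))
            g_losses.append(float(g_loss))
        if callback is not None:
            callback(epoch, gen)

    model = GanModel(
        generator=gen, discriminator=disc, gspec=gspec, dspec=dspec,
        smoothing=smoothing, norm_lo=lo, norm_hi=hi, class_id=class_id,
        feature_spec=fspec,
    )
    log = TrainLog(
        d_losses=d_losses, g_losses=g_losses, seed=config.seed,
        config=config.to_dict(), wall_seconds=time.time() - t0,
    )
    return model, log


def generate(model: GanModel, n: int, seed: int,
             denormalize: bool = False) -> np.ndarray:
    """Sample ``n`` synthetic windows of length L in [-1, 1] (seeded).

    With ``denormalize=True`` the outputs are mapped back to the amplitude
    range of the training windows.
    """
    L = model.gspec.output_length
    if n == 0:
        return np.empty((0, L))
    rng = np.random.default_rng(seed)
    outs = []
    for b0 in range(0, n, 64):
        nb = min(64, n - b0)
        z = rng.standard_normal((nb, model.gspec.latent_dim))
        outs.append(model.generator.forward(z, training=False))
    y = np.concatenate(outs, axis=0)
    if denormalize:
        y = (y + 1.0) / 2.0 * (model.norm_hi - model.norm_lo) + model.norm_lo
    return y


# ---------------------------------------------------------------------------
# persistence


def _walk_layers(seq: Sequential):
    for layer in seq.layers:
        if isinstance(layer, Sequential):
            yield from _walk_layers(layer)
        else:
            yield layer


def _collect_state(nets: dict[str, Sequential]) -> dict[str, np.ndarray]:
    arrays: dict[str, np.ndarray] = {}
    for name, net in nets.items():
        for i, p in enumerate(net.params()):
            arrays[f"{name}_p{i}"] = p.v
        for i, layer in enumerate(_walk_layers(net)):
            if isinstance(layer, BatchNorm1d):
                arrays[f"{name}_bn{i}_mean"] = layer.running_mean
                arrays[f"{name}_bn{i}_var"] = layer.running_var
    return arrays


def _restore_state(nets: dict[str, Sequential], arrays) -> None:
    for name, net in nets.items():
        for i, p in enumerate(net.params()):
            p.v[...] = arrays[f"{name}_p{i}"]
        for i, layer in enumerate(_walk_layers(net)):
            if isinstance(layer, BatchNorm1d):
                layer.running_mean = np.asarray(arrays[f"{name}_bn{i}_mean"])
                layer.running_var = np.asarray(arrays[f"{name}_bn{i}_var"])


def save_model(model: GanModel, path) -> None:
    """Persist a model as an npz archive of parameters plus a JSON spec echo."""
    meta = {
        "gspec": model.gspec.to_dict(),
        "dspec": model.dspec.to_dict(),
        "smoothing": model.smoothing.to_dict(),
        "feature_spec": model.feature_spec.to_dict(),
        "norm_lo": model.norm_lo,
        "norm_hi": model.norm_hi,
        "class_id": model.class_id,
        "input_length": model.discriminator.input_length,
    }
    nets = {
        "gen": model.generator.net,
        "dmain": model.discriminator.main,
        "dside": model.discriminator.side,
        "dhead": model.discriminator.head,
    }
    arrays = _collect_state(nets)
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    ).copy()
    np.savez(path, **arrays)


def load_model(path) -> GanModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"].tobytes()).decode("utf-8"))
        gspec = GeneratorSpec.from_dict(meta["gspec"])
        dspec = DiscriminatorSpec.from_dict(meta["dspec"])
        smoothing = SmoothingSpec(**meta["smoothing"])
        fspec = FeatureSpec(**meta["feature_spec"])
        gen = Generator(gspec, 0)
        disc = Discriminator(dspec, int(meta["input_length"]), 0, fspec)
        nets = {
            "gen": gen.net,
            "dmain": disc.main,
            "dside": disc.side,
            "dhead": disc.head,
        }
        _restore_state(nets, data)
    return GanModel(
        generator=gen, discriminator=disc, gspec=gspec, dspec=dspec,
        smoothing=smoothing, norm_lo=float(meta["norm_lo"]),
        norm_hi=float(meta["norm_hi"]), class_id=meta["class_id"],
        feature_spec=fspec,
    )
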