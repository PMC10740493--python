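"""File formats, run configuration and the end-to-end pipeline.

Sessions interchange as one wide CSV (``time, ch1..chN, label``) plus a JSON
manifest sidecar (``<stem>.manifest.json``) holding subject id, sampling
rate, channel count, protocol and seed.  Feature matrices are plain CSV with
a header.  Reports are JSON written atomically, embedding the resolved
configuration, its hash and every derived seed for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dcgan1d, evalsuite, protocol_sim, sigproc
from .features import FeatureSpec, feature_matrix
from .protocol_sim import ProtocolSpec, Session
from .sigproc import FilterSpec, WindowGrid


class SessionFormatError(ValueError):
    """A session file or its manifest is missing or malformed."""


def _manifest_path(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".manifest.json") \
        if path.suffix else path.with_name(path.name + ".manifest.json")


def write_session(session: Session, path) -> None:
    path = Path(path)
    n, c = session.signal.shape
    df = pd.DataFrame(
        {"time": np.arange(n) / session.sampling_rate}
        | {f"ch{i + 1}": session.signal[:, i] for i in range(c)}
        | {"label": session.labels}
    )
    df.to_csv(path, index=False, float_format="%.12e")
    _manifest_path(path).write_text(json.dumps(session.manifest, indent=1))


def read_session(path) -> Session:
    path = Path(path)
    mpath = _manifest_path(path)
    if not path.exists():
        raise SessionFormatError(f"session file not found: {path}")
    if not mpath.exists():
        raise SessionFormatError(f"missing session manifest: {mpath}")
    try:
        manifest = json.loads(mpath.read_text())
    except json.JSONDecodeError as e:
        raise SessionFormatError(f"malformed manifest {mpath}: {e}") from e
    df = pd.read_csv(path)
    channel_cols = [col for col in df.columns if col.startswith("ch")]
    if "label" not in df.columns or not channel_cols:
        raise SessionFormatError(
            f"{path} must have columns time, ch1..chN, label"
        )
    if "fs_hz" not in manifest:
        raise SessionFormatError(f"manifest {mpath} lacks fs_hz")
    signal = df[channel_cols].to_numpy(dtype=float)
    labels = df["label"].to_numpy(dtype=int)
    if len(labels) != len(signal):  # pragma: no cover - pandas guarantees this
        raise SessionFormatError("label/signal length mismatch")
    return Session(
        signal=signal, sampling_rate=float(manifest["fs_hz"]),
        labels=labels, manifest=manifest,
    )


def write_features(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.12e")


def read_features(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"feature file missing or empty: {path}")
    with open(path) as fh:
        header = fh.readline().strip().split(",")
    if len(header) != len(set(header)):
        raise ValueError(f"duplicate column names in {path}")
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"feature file has no rows: {path}")
    return df


# ---------------------------------------------------------------------------
# configuration


@dataclasses.dataclass
class RunConfig:
    """Fully serialisable configuration of one pipeline run."""

    protocol: ProtocolSpec = dataclasses.field(default_factory=protocol_sim.private_protocol)
    filter: FilterSpec = dataclasses.field(default_factory=FilterSpec)
    windows: WindowGrid = dataclasses.field(default_factory=WindowGrid)
    features: FeatureSpec = dataclasses.field(default_factory=FeatureSpec)
    generator: dcgan1d.GeneratorSpec = dataclasses.field(
        default_factory=lambda: dcgan1d.GeneratorSpec(output_length=1000))
    discriminator: dcgan1d.DiscriminatorSpec = dataclasses.field(
        default_factory=dcgan1d.DiscriminatorSpec)
    smoothing: dcgan1d.SmoothingSpec = dataclasses.field(
        default_factory=dcgan1d.SmoothingSpec)
    train: dcgan1d.TrainConfig = dataclasses.field(default_factory=dcgan1d.TrainConfig)
    eval_window_length: int = 1000
    eval_increment_fraction: float = 0.25
    n_generated_per_class: int = 64
    classes: list[int] | None = None
    mantel_permutations: int = 1000
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol.to_dict(),
            "filter": self.filter.to_dict(),
            "windows": self.windows.to_dict(),
            "features": self.features.to_dict(),
            "generator": self.generator.to_dict(),
            "discriminator": self.discriminator.to_dict(),
            "smoothing": self.smoothing.to_dict(),
            "train": self.train.to_dict(),
            "eval_window_length": self.eval_window_length,
            "eval_increment_fraction": self.eval_increment_fraction,
            "n_generated_per_class": self.n_generated_per_class,
            "classes": self.classes,
            "mantel_permutations": self.mantel_permutations,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        conv = {
            "protocol": ProtocolSpec.from_dict,
            "filter": lambda x: FilterSpec(**x),
            "windows": lambda x: WindowGrid(
                window_lengths=tuple(x["window_lengths"]),
                increment_fractions=tuple(x["increment_fractions"])),
            "features": lambda x: FeatureSpec(**x),
            "generator": dcgan1d.GeneratorSpec.from_dict,
            "discriminator": dcgan1d.DiscriminatorSpec.from_dict,
            "smoothing": lambda x: dcgan1d.SmoothingSpec(**x),
            "train": lambda x: dcgan1d.TrainConfig(**x),
        }
        for key, fn in conv.items():
            if key in d and isinstance(d[key], dict):
                d[key] = fn(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def write_json_atomic(obj: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            json.dump(obj, fh, indent=1, default=_json_default)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


# ---------------------------------------------------------------------------
# pipeline


def _derived_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(n)]


def run_pipeline(config: RunConfig, out_dir=None) -> dict:
    """Simulate -> filter -> train GAN per class -> generate -> features -> evaluate.

    Every stage seed derives from the global seed; the report echoes the
    resolved configuration and is written atomically when ``out_dir`` is
    given.  Running the same configuration twice yields an identical report
    modulo timing fields.
    """
    s_models, s_session, s_train, s_gen, s_eval = _derived_seeds(config.seed, 5)

    models = protocol_sim.make_default_gesture_models(
        config.protocol.n_gestures, config.protocol.n_channels, s_models
    )
    session = protocol_sim.simulate_session(config.protocol, models, s_session)
    session = sigproc.filter_session(session, config.filter)

    length = config.eval_window_length
    frac = config.eval_increment_fraction
    windows = sigproc.segment_windows(session, length, frac)
    fm_real = feature_matrix(windows, config.features, origin="real")

    classes = config.classes
    if classes is None:
        classes = sorted({w.label for w in windows})
    gen_windows, gen_labels = [], []
    train_summaries = {}
    for i, cls in enumerate(classes):
        cls_windows = [w for w in windows if w.label == cls]
        tc = dcgan1d.TrainConfig(**{**config.train.to_dict(),
                                    "seed": (s_train + i) % (2**31)})
        model, log = dcgan1d.train(
            cls_windows, gspec=config.generator, dspec=config.discriminator,
            smoothing=config.smoothing, config=tc,
            feature_spec=config.features, class_id=cls,
        )
        out = dcgan1d.generate(model, config.n_generated_per_class,
                               seed=(s_gen + i) % (2**31), denormalize=True)
        gen_windows.extend(out)
        gen_labels.extend([cls] * len(out))
        train_summaries[str(cls)] = {
            "final_d_loss": log.d_losses[-1],
            "final_g_loss": log.g_losses[-1],
            "steps": len(log.d_losses),
        }

    syn_session = protocol_sim.windows_to_session(
        gen_windows, gen_labels, session.sampling_rate,
        n_channels=1, rest_gap=max(64, length // 4), windows_per_run=8,
    )
    syn_windows = sigproc.segment_windows(syn_session, length, frac)
    fm_syn = feature_matrix(syn_windows, config.features, origin="synthetic")

    mantel = evalsuite.mantel_test(
        evalsuite.feature_correlation(fm_real).to_numpy(),
        evalsuite.feature_correlation(fm_syn).to_numpy(),
        permutations=config.mantel_permutations, seed=s_eval,
    )
    c2 = evalsuite.c2st(fm_real, fm_syn, seed=s_eval)
    acc_real = evalsuite.classify(fm_real, classifier="adaboost", seed=s_eval)
    acc_syn = (evalsuite.classify(fm_syn, classifier="adaboost", seed=s_eval)
               if len(set(gen_labels)) > 1 else None)

    report = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seeds": {"models": s_models, "session": s_session, "train": s_train,
                  "generate": s_gen, "eval": s_eval},
        "train": train_summaries,
        "mantel": {"r": mantel.r, "p_value": mantel.p_value,
                   "strength": evalsuite.correlation_strength(mantel.r),
                   "permutations": mantel.permutations},
        "c2st": {"accuracy": c2.accuracy, "n_train": c2.n_train,
                 "n_test": c2.n_test},
        "classification": {"real_accuracy": acc_real,
                           "synthetic_accuracy": acc_syn},
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        tag = f"{config.config_hash()}_seed{config.seed}"
        write_session(session, out_dir / f"session_{tag}.csv")
        write_features(fm_real, out_dir / f"features_real_{tag}.csv")
        write_features(fm_syn, out_dir / f"features_synthetic_{tag}.csv")
        write_json_atomic(report, out_dir / f"report_{tag}.json")
    return report
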