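import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from semggan import dcgan1d, protocol_sim, sigproc

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_session():
    """Filtered 6-gesture session at 2000 Hz, 3 repetitions (fast fixture)."""
    proto = protocol_sim.ProtocolSpec(
        sampling_rate=2000.0, n_channels=2, n_gestures=6,
        hold_duration=3.0, rest_duration=1.0, repetitions=3,
    )
    models = protocol_sim.make_default_gesture_models(6, 2, seed=11)
    session = protocol_sim.simulate_session(proto, models, seed=11)
    return sigproc.filter_session(session)


def _narrowband_windows(band, seed, n=128, length=256):
    proto = protocol_sim.ProtocolSpec(
        sampling_rate=2000.0, n_channels=1, n_gestures=2,
        hold_duration=3.0, rest_duration=1.0, repetitions=6,
    )
    models = [
        protocol_sim.GestureModel(bands=(band,), amplitudes=(1.0,)),
        protocol_sim.GestureModel(bands=((280.0, 320.0),), amplitudes=(1.0,)),
    ]
    session = protocol_sim.simulate_session(proto, models, seed=seed)
    wins = [w for w in sigproc.segment_windows(session, length, 0.25)
            if w.label == 0]
    return wins[:n]


@pytest.fixture(scope="session")
def narrowband_gan():
    """GAN trained 200 epochs on a single 90-110 Hz class (fs=2000, L=256).

    Session-scoped: shared by the trainability, contract and acceptance
    tests to avoid repeated multi-minute training runs.
    """
    windows = _narrowband_windows((90.0, 110.0), seed=3)
    model, log = dcgan1d.train(
        windows,
        gspec=dcgan1d.GeneratorSpec(output_length=256),
        config=dcgan1d.TrainConfig(epochs=200, seed=3),
        class_id=0,
    )
    return {"model": model, "log": log, "windows": windows}


@pytest.fixture(scope="session")
def narrowband_other_class_windows():
    """Real windows of a 280-320 Hz class for class-identity comparisons."""
    proto = protocol_sim.ProtocolSpec(
        sampling_rate=2000.0, n_channels=1, n_gestures=2,
        hold_duration=3.0, rest_duration=1.0, repetitions=6,
    )
    models = [
        protocol_sim.GestureModel(bands=((90.0, 110.0),), amplitudes=(1.0,)),
        protocol_sim.GestureModel(bands=((280.0, 320.0),), amplitudes=(1.0,)),
    ]
    session = protocol_sim.simulate_session(proto, models, seed=3)
    return [w for w in sigproc.segment_windows(session, 256, 0.25)
            if w.label == 1][:128]
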