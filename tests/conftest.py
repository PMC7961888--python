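import numpy as np
import pytest

import myofeedback as mf

try:
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "default",
        derandomize=True,
        deadline=None,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("default")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def model() -> mf.SensorModel:
    return mf.SensorModel()


@pytest.fixture(scope="session")
def grip_rec(model) -> mf.EmgRecording:
    """A reference grip at full level with leading/trailing rest."""
    return mf.simulate_grip_recording(model, grip_level=1.0, seed=101)


@pytest.fixture(scope="session")
def profile(grip_rec) -> mf.CalibrationProfile:
    return mf.calibrate_grip(grip_rec)


@pytest.fixture(scope="session")
def small_protocol() -> mf.TrainingProtocol:
    """Shortened session used where trial count is not the point."""
    return mf.TrainingProtocol(blocks=1, reps_per_block=6, inter_trial_rest_s=1.0,
                               inter_block_rest_s=0.0)


@pytest.fixture(scope="session")
def rest_rec(model) -> mf.EmgRecording:
    env = mf.build_envelope(mf.ActivationScript(duration_s=10.0), fs_hz=model.fs_hz)
    return mf.synthesize_emg(env, model, seed=7)
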