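import numpy as np
import pytest

from speckleflow import (
    DecorrelationSpec,
    SimulationConfig,
    generate_field_sequence,
    simulate_mesi_stack,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim_config():
    """Desk-scale homogeneous simulation: tau_c = 0.5 ms, 96x96 px."""
    return SimulationConfig(
        decorrelation=DecorrelationSpec(tau_c=0.5),
        image_shape=(96, 96),
        exposure_times=(0.05, 0.2, 1.0, 5.0, 20.0, 60.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_stack(small_sim_config):
    return simulate_mesi_stack(small_sim_config)


def siegert_gaps(tau_c=1.0, dt_rule=1 / 20, shape=(96, 96), n_frames=240, seed=11, lags_ms=(0.05, 0.5, 1.0, 2.0)):
    """Empirical g2(tau) - 1 minus the Siegert prediction |g1(tau)|^2.

    Uses a single-polarization raw field sequence, for which the Siegert
    relation holds with unit coherence factor.
    """
    config = SimulationConfig(
        decorrelation=DecorrelationSpec(tau_c=tau_c),
        image_shape=shape,
        exposure_times=(1.0,),
        dt_rule=dt_rule,
        n_polarization=1,
        seed=seed,
    )
    dt = config.dt
    stack = generate_field_sequence(config, duration=n_frames * dt)
    frames = stack.frames[:n_frames]
    mean_sq = frames.mean() ** 2
    gaps = []
    for lag in lags_ms:
        m = int(round(lag / dt))
        g2 = float(np.mean(frames[:-m] * frames[m:]) / mean_sq) if m > 0 else float(
            np.mean(frames * frames) / mean_sq
        )
        theory = np.exp(-2.0 * lag / tau_c)
        gaps.append(g2 - 1.0 - theory)
    return np.asarray(gaps)
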