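import numpy as np
import pytest

from tstscore import bout_scoring, calibration, segmentation, synthetic


@pytest.fixture(scope="session")
def default_session():
    """One synthetic session at the default study conditions."""
    return synthetic.simulate_session(synthetic.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def detected(default_session):
    """Segmentation + filtered window for the default session."""
    return segmentation.detect_session(default_session.trace)


@pytest.fixture(scope="session")
def scored_window(detected):
    """(FilteredWindow, movement envelope) for the default session."""
    _, win = detected
    return win, bout_scoring.movement_envelope(win)


@pytest.fixture(scope="session")
def calibration_cohort():
    """A 16-mouse cohort scored at the candidate thresholds.

    Manual times are the automated times at the generating threshold
    0.8 g plus Gaussian observer noise (SD 1 s), the construction under
    which the calibration should recover 0.8.
    """
    rng = np.random.default_rng(2024)
    theta_star = 0.8
    cohort, manual, envs = {}, {}, {}
    for i in range(16):
        cfg = synthetic.SimulationConfig(
            seed=500 + i,
            weight_g=float(rng.uniform(20.0, 30.0)),
            hang_time_s=float(rng.uniform(60.0, 180.0)),
        )
        ses = synthetic.simulate_session(cfg)
        _, win = segmentation.detect_session(ses.trace)
        env = bout_scoring.movement_envelope(win)
        mouse = f"M{i + 1:02d}"
        envs[mouse] = (env, win.rate)
        cohort[mouse] = [
            (th, bout_scoring.classify_states(env, th, win.rate).total_immobility)
            for th in bout_scoring.CANDIDATE_THRESHOLDS
        ]
        auto_star = bout_scoring.classify_states(env, theta_star, win.rate).total_immobility
        manual[mouse] = float(np.clip(auto_star + rng.normal(0.0, 1.0), 0.0, 360.0))

    def auto_time_fn(mouse, threshold):
        env, rate = envs[mouse]
        return int(np.sum(~(env > threshold))) / rate

    return {
        "dataset": calibration.build_dataset(cohort, manual),
        "auto_time_fn": auto_time_fn,
        "theta_star": theta_star,
    }
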