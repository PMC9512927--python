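import numpy as np
import pytest

from compcal import ElementCalibration, simulate_design, simulate_survey


@pytest.fixture
def oracle_calibration() -> ElementCalibration:
    """Reference calibration with hand-picked parameters and (co)variances."""
    return ElementCalibration(
        background=10.0, sensitivity=100.0, residual_sd=3.0,
        var_background=4.0, var_sensitivity=25.0, cov_bg_sens=-5.0,
        n_points=5, channel="63Cu", element="Cu", c0=200.0,
    )


@pytest.fixture
def noiseless_run():
    """A 9-element synthetic run with zero measurement noise."""
    design, truth = simulate_design(n_elements=9, seed=7, noise_cv=0.0)
    matrix = simulate_survey(truth, seed=7)
    return design, truth, matrix


@pytest.fixture
def noisy_run():
    """A 9-element synthetic run at the generator's default noise level."""
    design, truth = simulate_design(n_elements=9, seed=11)
    matrix = simulate_survey(truth, seed=11)
    return design, truth, matrix


def mc_inversion_sd(calib: ElementCalibration, intensity: float, m: int,
                    n_draws: int = 1_000_000, seed: int = 0) -> float:
    """Monte-Carlo propagation oracle for the inverse-prediction SD.

    Draws (b, s) from the calibration's estimated covariance and the sample
    intensity from its σ²/m noise, inverts each draw, and returns the
    empirical SD of r — independent of the delta-method path it checks.
    """
    rng = np.random.default_rng(seed)
    cov = np.array([[calib.var_background, calib.cov_bg_sens],
                    [calib.cov_bg_sens, calib.var_sensitivity]])
    bs = rng.multivariate_normal([calib.background, calib.sensitivity], cov, size=n_draws)
    I = rng.normal(intensity, calib.residual_sd / np.sqrt(m), size=n_draws)
    r = (I - bs[:, 0]) / bs[:, 1]
    return float(np.std(r, ddof=1))
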