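import numpy as np
import pytest

from wristbia import (
    CalibrationConfig,
    CohortConfig,
    ImpedanceSeries,
    default_groups,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def default_cohort():
    """One default 163-subject cohort, shared read-only across tests."""
    return simulate_cohort(CohortConfig(seed=42))


@pytest.fixture(scope="session")
def clean_linear_cohort():
    """Noise-free cohort restricted to the two General groups.

    With all generator noise off and the nonlinear term disabled, the
    ground-truth body fat is affine in the observed features up to the tiny
    curvature of BMI in height/weight, so linear models should be essentially
    exact on it.
    """
    groups = tuple(g for g in default_groups() if g.label == "General")
    cfg = CohortConfig(
        groups=groups,
        meas_noise_sd=0.0,
        pbf_noise_sd=0.0,
        nonlinearity_strength=0.0,
        r50_rel_noise_sd=0.0,
        seed=11,
    )
    return simulate_cohort(cfg, n_per_group=100)


@pytest.fixture()
def exact_series():
    """Noise-free transient 1000 + 200*exp(-0.5 t) sampled at t = 1..5 s."""
    t = np.arange(1.0, 6.0)
    return ImpedanceSeries(t, 1000.0 + 200.0 * np.exp(-0.5 * t))


@pytest.fixture()
def no_gate_config():
    """Calibration config with the already-settled shortcut disabled.

    Forces every decaying exponential onto the extrapolation path so the
    estimator's exactness can be probed even for fast transients whose last
    inter-sample gap is below the production 5-ohm gate.
    """
    return CalibrationConfig(settle_threshold=1e-9)
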