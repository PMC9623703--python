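"""Shared fixtures: the printed dose-response, zero-noise configs and small
synthetic datasets."""
import numpy as np
import pytest

from npartition import SimulationConfig, predict_true_milk

#: The phase-1 dose levels actually fed (g urea/d).
PHASE1_DOSES = np.array([0.0, 88.0, 176.0, 351.0, 450.0, 600.0, 690.0])

#: True dose-response parameters of the milk-yield split-line model.
TRUE_SPLITLINE = (20.5, 0.0029, -0.0235, 350.0)

#: True urinary-N line: intercept (g/d) and slope on N intake.
TRUE_URINE_LINE = (-174.2, 0.86)


@pytest.fixture
def fig_doses():
    return PHASE1_DOSES.copy()


@pytest.fixture
def noise_free_milk(fig_doses):
    """Noise-free milk yields at the fed dose levels, replicated 3x so the
    fit has n >= 5 with honest degrees of freedom."""
    x = np.repeat(fig_doses, 3)
    y = np.array([predict_true_milk(d, TRUE_SPLITLINE) for d in x])
    return x, y


@pytest.fixture
def default_config():
    return SimulationConfig(seed=42)


@pytest.fixture
def noise_free_config():
    return SimulationConfig(seed=42).noise_free()
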