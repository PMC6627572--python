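import math

import numpy as np
import pytest

from btpp.design import ExperimentDesign, TemperatureGradient


@pytest.fixture(scope="session")
def gradient() -> TemperatureGradient:
    return TemperatureGradient()


@pytest.fixture(scope="session")
def design() -> ExperimentDesign:
    return ExperimentDesign()


def curve_params(tm: float, plateau: float, slope_at_tm: float) -> tuple[float, float]:
    """(a, b) of a melting curve with the given Tm, plateau and at-Tm slope."""
    a = 2.0 * slope_at_tm * tm**2 * (1.0 - plateau) / (0.5 - plateau)
    b = a / tm + math.log(0.5 / (0.5 - plateau))
    return a, b


def random_valid_params(rng: np.random.Generator, n: int) -> np.ndarray:
    """n rows of (a, b, plateau) with Tm in a sensible 40-60 °C range."""
    tm = rng.uniform(40.0, 60.0, n)
    plateau = rng.uniform(0.0, 0.3, n)
    slope = rng.uniform(0.065, 0.13, n)
    a = 2.0 * slope * tm**2 * (1.0 - plateau) / (0.5 - plateau)
    b = a / tm + np.log(0.5 / (0.5 - plateau))
    return np.column_stack([a, b, plateau])
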