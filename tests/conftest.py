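import numpy as np
import pytest

import baroreset as br


@pytest.fixture
def textbook_params() -> br.LogisticParams:
    """A representative baroreflex curve: 100 a.u. range over ~59 mmHg."""
    return br.LogisticParams(a1=100.0, a2=0.1, a3=120.0, a4=10.0)


@pytest.fixture
def circuit() -> br.CircuitParams:
    return br.DEFAULT_CIRCUIT


@pytest.fixture
def grid() -> np.ndarray:
    """Analysis grid spanning the full reflex range of the default circuit."""
    return br.default_pressure_grid()


@pytest.fixture
def rest_fit(circuit, grid) -> br.FitResult:
    series = br.simulate_curve(circuit, br.preset_state("rest"), grid)
    fit = br.fit_logistic(series)
    assert fit.converged
    return fit
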