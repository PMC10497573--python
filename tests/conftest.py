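import numpy as np
import pytest

from fibrocontrol import (GLLBasis, ModelParams, assemble_system,
                          build_operators)


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def small_system(params):
    """2-D semi-discrete system at a cheap order (uniform-state studies
    are order-independent, so N=4 suffices for dynamics tests)."""
    ops = build_operators(params, 4)
    return assemble_system(params, ops)


@pytest.fixture(scope="session")
def basis8():
    return GLLBasis.of_order(8)


def rk4(rhs, y0, times):
    """Classical 4th-order Runge-Kutta on a fixed grid (test oracle)."""
    y = np.array(y0, dtype=float)
    out = [y.copy()]
    for k in range(len(times) - 1):
        t, dt = times[k], times[k + 1] - times[k]
        k1 = rhs(t, y)
        k2 = rhs(t + dt / 2, y + dt / 2 * k1)
        k3 = rhs(t + dt / 2, y + dt / 2 * k2)
        k4 = rhs(t + dt, y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        out.append(y.copy())
    return np.array(out)
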