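import numpy as np
import pytest

import jargas as jg
from jargas.io import packaged_test_log


@pytest.fixture(scope="session")
def reference_model():
    """The packaged six-step Pd(111) mechanism."""
    return jg.build_reference_model()


@pytest.fixture(scope="session")
def catalyst_conditions():
    """Catalyst-test gas atmosphere at laboratory temperature."""
    return jg.reference_conditions(295.15)


@pytest.fixture(scope="session")
def exchange_config():
    """Reference jar: 2.385 L, 80 kPa vacuum depth, anaerobic refill."""
    return jg.reference_config()


@pytest.fixture(scope="session")
def test_log():
    """The six packaged real-time catalyst tests."""
    return packaged_test_log()


@pytest.fixture(scope="session")
def test4_k_system(test_log):
    """Measured-rate curve of the fourth catalyst test on the 0.5 K grid."""
    test = test_log[3]
    tof = jg.turnover_frequency(test).tof
    return jg.build_k_system(tof, test.t_tof, 8.38e-6, jg.default_grid())


def scalar_cycle_oracle(x, cyl, masses_m, p_atm, p_vac, v, r, t):
    """Independent per-species recursion of one exchange cycle.

    Plain Python loops, no vectorization: retained moles keep the old
    mole fractions, the refill adds cylinder gas, masses are moles times
    molar mass, and the readout is mass over total mass.
    """
    a = (p_atm - p_vac) * v / (r * t)
    b = p_vac * v / (r * t)
    masses = []
    moles = []
    for i in range(len(x)):
        n_i = a * x[i] + b * cyl[i]
        moles.append(n_i)
        masses.append(a * x[i] * masses_m[i] + b * cyl[i] * masses_m[i])
    total_mass = sum(masses)
    total_moles = sum(moles)
    w = [m / total_mass for m in masses]
    x_next = [n / total_moles for n in moles]
    return x_next, w, masses, total_mass
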