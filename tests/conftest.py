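import numpy as np
import pytest

import deglypk as d


@pytest.fixture(scope="session")
def ref_params() -> d.ParameterSet:
    """Published rat reference estimates, no variability."""
    return d.rat_reference_parameters()


@pytest.fixture(scope="session")
def ref_params_var() -> d.ParameterSet:
    """Reference estimates with the assumed omega/sigma terms attached."""
    return d.rat_reference_parameters(variability=True)


@pytest.fixture(scope="session")
def study_grid() -> np.ndarray:
    """The emulated Rh2-group sampling schedule with a 24 h final sample."""
    return np.array([0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 16.0, 24.0])


@pytest.fixture(scope="session")
def noise_free_study(ref_params):
    """One complete synthetic study without variability or noise."""
    return d.generate_study(d.default_design(), ref_params, seed=1)


@pytest.fixture(scope="session")
def perturbed_init():
    """Stage starting values: truth alternately scaled by 1.5 and 0.7."""
    return {
        "A": {"V_rh2_plasma": 2.39 * 1.5, "k_e": 4.67 * 0.7, "k_47": 2.08 * 1.5, "k_74": 0.48 * 0.7},
        "B": {"V_ppd_plasma": 0.29 * 1.5, "k_50": 4.88 * 0.7, "k_58": 27.3 * 1.5, "k_85": 3.38 * 0.7},
        "C": {"k_45": 0.09 * 1.5, "k_t": 0.63 * 0.7, "k_60": 1.38 * 1.5},
        "D": {"k_13": 0.22 * 1.5, "k_12": 0.14 * 0.7, "k_20": 22.2 * 1.5},
    }
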