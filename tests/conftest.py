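import numpy as np
import pytest
from hypothesis import settings

from azocoil import synthetic, thermo

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def default_melt():
    """Noisy default melt design (4 concentrations, sigma=0.3, seed 1)."""
    return synthetic.gen_melt_curves()


@pytest.fixture(scope="session")
def noiseless_melt():
    return synthetic.gen_melt_curves(synthetic.MeltSpec(sigma=0.0))


@pytest.fixture(scope="session")
def small_melt_spec():
    """Compact two-concentration design used for repeated fits."""
    return synthetic.MeltSpec(Ct_list=(25e-6, 100e-6), t_step_C=5.0)


@pytest.fixture(scope="session")
def default_toy_trajectory():
    """Paired trans/cis toy ensembles at generator defaults (seed 1)."""
    return synthetic.gen_toy_trajectory()


@pytest.fixture(scope="session")
def apgly_dark_params():
    """Fitted dark-state thermodynamics of the phenylglycine switch."""
    return thermo.UnfoldingParams(dH0=285.2,
                                  T0=thermo.celsius_to_kelvin(113.0),
                                  dCp=2.80)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
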