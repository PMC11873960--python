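import numpy as np
import pytest

from morebind import (
    AssayConditions,
    BindingParameters,
    GeneratorSpec,
    generate_titration,
)


@pytest.fixture
def canonical_params() -> BindingParameters:
    """Low-salt reference truth: kd = 3.8 nM, phi = 2.6e4 /M."""
    return BindingParameters(kd=3.8e-9, n_hill=2.0, phi=2.6e4,
                             r_unbound=0.0, r_specific=0.08)


@pytest.fixture
def probe_conditions() -> AssayConditions:
    return AssayConditions(probe_total=5e-9, na_conc=0.15)


@pytest.fixture
def log_grid() -> np.ndarray:
    """16-point log-spaced design, 1 nM to 10 uM."""
    return np.logspace(-9, -5, 16)


@pytest.fixture
def noiseless_curve(canonical_params, probe_conditions, log_grid):
    spec = GeneratorSpec(truth=canonical_params, conditions=probe_conditions,
                         grid=log_grid, noise_sd=0.0)
    return generate_titration(spec)
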