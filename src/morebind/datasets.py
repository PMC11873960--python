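"""Reference salt-dependence measurements for the OCT2 POU-domain dimer.

These are the published equilibrium results for the OCT2 DNA-binding
domain titrated against a HEX-labeled 22-bp MORE duplex (5 nM probe,
pH 6.5, 25 C), with and without an excess (~7 mM bp) of the nonspecific
competitor poly[d(I-C)]: fitted dissociation constants K_D and
excess-loading coefficients phi over 0.15-0.35 M Na+.  They are the
canonical inputs for the linkage analysis and serve as realistic
ground-truth values for the synthetic-data generator.
"""

from __future__ import annotations

import numpy as np

from .linkage import SaltSeries

__all__ = [
    "NA_GRID", "kd_salt_series", "phi_salt_series",
    "KD_REF_LOW_SALT", "PHI_REF_LOW_SALT", "SK_SPECIFIC", "SK_WITH_NS",
]

#: Na+ concentrations of the published series (mol/L)
NA_GRID = np.array([0.15, 0.175, 0.20, 0.25, 0.30, 0.35])

# K_D (M): without / with poly[d(I-C)], means and SDs of log10 K_D
_KD_MINUS = np.array([3.8e-9, 9.7e-9, 2.9e-8, 8.8e-8, 5.6e-7, 1.2e-6])
_KD_MINUS_LOGSD = np.array([0.35, 0.38, 0.32, 0.20, 0.17, 0.23])
_KD_PLUS = np.array([5.5e-9, 1.1e-8, 1.6e-8, 4.1e-8, 7.1e-8, 1.9e-7])
_KD_PLUS_LOGSD = np.array([0.10, 0.17, 0.18, 0.14, 0.12, 0.15])

# phi (M^-1): without / with poly[d(I-C)]
_PHI_MINUS = np.array([2.6e4, 2.1e4, 1.0e4, 3.8e3, 0.52e3, 0.34e3])
_PHI_MINUS_SD = np.array([0.1e4, 0.1e4, 0.1e4, 1.2e3, 0.07e3, 0.03e3])
_PHI_PLUS = np.array([0.93e4, 0.94e4, 0.92e4, 4.8e3, 1.6e3, 1.2e3])
_PHI_PLUS_SD = np.array([0.09e4, 0.08e4, 0.10e4, 0.6e3, 0.2e3, 0.1e3])

#: canonical specific-binding constant at 0.15 M Na+ (M)
KD_REF_LOW_SALT = 3.8e-9
#: canonical excess-loading coefficient at 0.15 M Na+ (M^-1)
PHI_REF_LOW_SALT = 2.6e4
#: published SK without / with nonspecific competitor
SK_SPECIFIC = -6.8
SK_WITH_NS = -4.0


def kd_salt_series(with_nonspecific: bool = False) -> SaltSeries:
    """K_D vs Na+ series, without (default) or with poly[d(I-C)]."""
    if with_nonspecific:
        return SaltSeries("kd_+poly(dI-C)", NA_GRID.copy(), _KD_PLUS.copy(),
                          _KD_PLUS_LOGSD.copy())
    return SaltSeries("kd_-poly(dI-C)", NA_GRID.copy(), _KD_MINUS.copy(),
                      _KD_MINUS_LOGSD.copy())


def phi_salt_series(with_nonspecific: bool = False) -> SaltSeries:
    """Excess-loading phi vs Na+ series, without or with poly[d(I-C)]."""
    if with_nonspecific:
        return SaltSeries("phi_+poly(dI-C)", NA_GRID.copy(), _PHI_PLUS.copy(),
                          _PHI_PLUS_SD.copy())
    return SaltSeries("phi_-poly(dI-C)", NA_GRID.copy(), _PHI_MINUS.copy(),
                      _PHI_MINUS_SD.copy())
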