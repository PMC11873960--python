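"""Linkage-thermodynamics analysis of salt-dependent binding constants.

Binding of a charged protein to DNA releases condensed counterions, so
log10 K_D is linear in log10 [Na+].  The slope in the association-constant
convention (SK, the negative of the log K_D slope) measures net ion
release.  Polyelectrolyte theory predicts the phosphate-neutralization
part as dm_PE = psi * Z, where psi is the charge-screening/condensation
parameter of the oligonucleotide and Z the signed count of phosphate
contacts; the remainder dm_other = SK - dm_PE reports protein-side ion
uptake or release (for example salt-bridge changes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "GAS_CONSTANT", "PSI_OLIGO", "PSI_POLYMER",
    "SaltSeries", "LinkageResult", "SaltDependenceModel",
    "fit_salt_dependence", "counterion_release", "decompose_ion_release",
    "crossover_concentration", "deltag_pe", "phi_change", "linkage_analysis",
    "ExtrapolationWarning",
]

GAS_CONSTANT = 8.314  # J mol^-1 K^-1

#: charge-screening parameter of a short (20 phosphate-pair) duplex,
#: end-effect corrected relative to polymeric B-DNA
PSI_OLIGO = 0.75
#: limiting value for polymeric B-DNA
PSI_POLYMER = 0.88


class ExtrapolationWarning(UserWarning):
    """The crossover lies outside the salt range of the fitted data."""


@dataclass(frozen=True)
class SaltSeries:
    """One salt series: equilibrium constants (or phi) vs Na+ concentration."""

    label: str
    na_conc: np.ndarray
    value: np.ndarray
    sd: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        na = np.asarray(self.na_conc, dtype=float)
        v = np.asarray(self.value, dtype=float)
        if na.ndim != 1 or na.shape != v.shape:
            raise ValueError("na_conc and value must be 1-d and equal length")
        if np.any(na <= 0) or np.any(np.diff(na) <= 0):
            raise ValueError("na_conc must be positive and strictly increasing")
        if np.any(v <= 0):
            raise ValueError("values must be positive")
        sd = np.full_like(na, np.nan) if self.sd is None else np.asarray(self.sd, float)
        if sd.shape != na.shape:
            raise ValueError("sd must match na_conc in length")
        object.__setattr__(self, "na_conc", na)
        object.__setattr__(self, "value", v)
        object.__setattr__(self, "sd", sd)

    def __len__(self) -> int:
        return self.na_conc.size


@dataclass(frozen=True)
class LinkageResult:
    """SK decomposition for one salt series.

    sk is reported in the association-constant convention: net ion release
    gives sk < 0.  dm_other = sk - dm_pe holds exactly by construction.
    """

    sk: float
    sk_stderr: float
    intercept: float
    dm_pe: float
    dm_other: float
    psi: float
    z: float


class SaltDependenceModel(BaseEstimator, RegressorMixin):
    """log10-log10 regression of an equilibrium constant on [Na+].

    fit(X, y) regresses log10(y) on log10(X) by ordinary (or
    inverse-variance weighted) least squares.

    Attributes
    ----------
    sk_ : float
        Negative of the fitted slope (association-constant convention).
    slope_, intercept_ : float
        Fitted line for log10 K_D; intercept at log10[Na+] = 0.
    sk_stderr_ : float
        Standard error of the slope (and of sk).
    """

    def __init__(self, weighting: str = "none"):
        self.weighting = weighting

    def fit(self, X, y, sample_weight=None):
        na = np.asarray(X, dtype=float).reshape(-1)
        val = np.asarray(y, dtype=float).reshape(-1)
        if na.size != val.size:
            raise ValueError("X and y must have equal length")
        if na.size < 3:
            raise ValueError("at least 3 salt points are required")
        if np.any(na <= 0) or np.any(val <= 0):
            raise ValueError("concentrations and constants must be > 0")
        x = np.log10(na)
        if np.ptp(x) == 0:
            raise ValueError("na_conc has zero variance")
        ylog = np.log10(val)

        if self.weighting == "none" and sample_weight is None:
            res = stats.linregress(x, ylog)
            slope, intercept, stderr = res.slope, res.intercept, res.stderr
        elif self.weighting in ("none", "inverse-variance"):
            w = (np.asarray(sample_weight, dtype=float).reshape(-1)
                 if sample_weight is not None else None)
            if w is None:
                raise ValueError(
                    "inverse-variance weighting needs sample_weight = 1/sd^2 "
                    "of the log10 values")
            slope, intercept, stderr = _wls_line(x, ylog, w)
        else:
            raise ValueError(f"unknown weighting {self.weighting!r}")

        self.slope_ = float(slope)
        self.intercept_ = float(intercept)
        self.sk_ = -float(slope)
        self.sk_stderr_ = float(stderr)
        self.x_range_ = (float(x.min()), float(x.max()))
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted K_D (linear scale) at Na+ concentrations X."""
        check_is_fitted(self, "slope_")
        x = np.log10(np.asarray(X, dtype=float))
        return 10.0 ** (self.intercept_ + self.slope_ * x)


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least-squares line via the normal equations."""
    sw = w.sum()
    xb = (w * x).sum() / sw
    yb = (w * y).sum() / sw
    sxx = (w * (x - xb) ** 2).sum()
    slope = (w * (x - xb) * (y - yb)).sum() / sxx
    intercept = yb - slope * xb
    dof = max(x.size - 2, 1)
    s2 = (w * (y - intercept - slope * x) ** 2).sum() / dof
    return slope, intercept, np.sqrt(s2 / sxx)


def fit_salt_dependence(series: SaltSeries, weighting: str = "none"):
    """Fit log10(K_D) vs log10([Na+]); returns (sk, sk_stderr, intercept).

    sk is the negative of the regression slope so that net ion release on
    binding appears as sk < 0.
    """
    est = SaltDependenceModel(weighting=weighting)
    if weighting == "inverse-variance":
        if np.any(~np.isfinite(series.sd)) or np.any(series.sd <= 0):
            raise ValueError("inverse-variance weighting requires finite positive sd")
        est.fit(series.na_conc, series.value, sample_weight=1.0 / series.sd**2)
    else:
        est.fit(series.na_conc, series.value)
    return est.sk_, est.sk_stderr_, est.intercept_


def counterion_release(psi: float, z: float) -> float:
    """Polyelectrolyte counterion-release term dm_PE = psi * z (ions).

    z carries its sign (negative for phosphates contacted by basic protein
    residues), so release comes out negative.
    """
    if not (0 < psi <= 1):
        raise ValueError(f"psi must be in (0, 1], got {psi}")
    return psi * z


def decompose_ion_release(sk: float, dm_pe: float) -> float:
    """Non-polyelectrolyte remainder dm_other = sk - dm_pe (ions)."""
    if not (np.isfinite(sk) and np.isfinite(dm_pe)):
        raise ValueError("sk and dm_pe must be finite")
    return sk - dm_pe


def crossover_concentration(line_a: tuple[float, float],
                            line_b: tuple[float, float],
                            data_range: tuple[float, float] | None = None) -> float:
    """Na+ concentration (mol/L) at which two salt-dependence lines meet.

    Each line is (sk, intercept) as returned by fit_salt_dependence, i.e.
    log10 K_D = intercept - sk * log10 [Na+].  Raises on parallel lines;
    warns if the intersection lies outside ``data_range`` (mol/L).
    """
    sk_a, b_a = line_a
    sk_b, b_b = line_b
    slope_a, slope_b = -sk_a, -sk_b
    if slope_a == slope_b:
        raise ValueError("lines are parallel: no crossover")
    x = (b_b - b_a) / (slope_a - slope_b)
    na = 10.0**x
    if data_range is not None and not (data_range[0] <= na <= data_range[1]):
        warnings.warn(
            f"crossover at {na:.3g} M lies outside the data range "
            f"[{data_range[0]:g}, {data_range[1]:g}] M", ExtrapolationWarning,
            stacklevel=2)
    return na


def deltag_pe(psi: float, temperature: float, na_conc: float) -> float:
    """Per-ion polyelectrolyte free energy -psi*R*T*ln[Na+], kJ/(mol ion)."""
    if not (0 < psi <= 1):
        raise ValueError(f"psi must be in (0, 1], got {psi}")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if na_conc <= 0:
        raise ValueError("na_conc must be > 0")
    return -psi * GAS_CONSTANT * temperature * np.log(na_conc) / 1000.0


def phi_change(series_minus: SaltSeries, series_plus: SaltSeries) -> np.ndarray:
    """Relative change of phi on adding nonspecific DNA, percent per salt."""
    if not np.allclose(series_minus.na_conc, series_plus.na_conc, rtol=1e-12):
        raise ValueError("salt grids of the two series must match")
    return 100.0 * (series_plus.value - series_minus.value) / series_minus.value


def linkage_analysis(series: SaltSeries, psi: float = PSI_OLIGO,
                     z: float = -11.0, weighting: str = "none") -> LinkageResult:
    """Full SK regression and polyelectrolyte decomposition of one series."""
    sk, stderr, intercept = fit_salt_dependence(series, weighting=weighting)
    dm_pe = counterion_release(psi, z)
    return LinkageResult(sk=sk, sk_stderr=stderr, intercept=intercept,
                         dm_pe=dm_pe, dm_other=decompose_ion_release(sk, dm_pe),
                         psi=psi, z=z)
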