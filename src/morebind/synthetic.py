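"""Synthetic titration and salt-series generation with known ground truth.

Emulates the study design the package analyzes: a 5 nM labeled cognate
probe titrated with 2-fold dilutions of protein from 1 uM, replicate
anisotropy measurements with homoscedastic Gaussian noise (SD ~0.002
anisotropy units, three replicates), competition by unlabeled cognate
site, and power-law K_D(Na+) salt series.  Every generator is
deterministic given its seed and returns the generating truth alongside
the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .linkage import SaltSeries
from .model import (
    AssayConditions,
    BindingParameters,
    TitrationCurve,
    simulate_curve,
)

__all__ = ["GeneratorSpec", "SaltModel", "IdentifiabilityWarning",
           "generate_titration", "generate_salt_series",
           "generate_competition_curve", "default_grid"]


class IdentifiabilityWarning(UserWarning):
    """The design grid does not bracket the true kd by a factor of 10."""


def default_grid(n_points: int = 16, top: float = 1e-6,
                 dilution: float = 2.0) -> np.ndarray:
    """Serial-dilution design: ``n_points`` 2-fold dilutions from 1 uM."""
    return top / dilution ** np.arange(n_points)[::-1]


@dataclass(frozen=True)
class SaltModel:
    """Power-law salt dependence kd(na) = kd_ref * (na/ref_na) ** (-sk_true)."""

    kd_ref: float
    ref_na: float
    sk_true: float

    def kd_at(self, na_conc) -> np.ndarray:
        return self.kd_ref * (np.asarray(na_conc, float) / self.ref_na) ** (-self.sk_true)


@dataclass(frozen=True)
class GeneratorSpec:
    """Ground truth plus experimental design for one synthetic experiment."""

    truth: BindingParameters
    conditions: AssayConditions = field(default_factory=AssayConditions)
    grid: np.ndarray = field(default_factory=default_grid)
    noise_sd: float = 0.002
    n_replicates: int = 3
    seed: int = 0
    salt_model: SaltModel | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if g.size < 2 or np.any(np.diff(g) <= 0):
            raise ValueError("grid must have >= 2 strictly increasing points")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        object.__setattr__(self, "grid", g)

    def replace(self, **changes) -> "GeneratorSpec":
        return replace(self, **changes)


def _check_identifiable(spec: GeneratorSpec) -> None:
    pos = spec.grid[spec.grid > 0]
    kd = spec.truth.kd
    if pos.size == 0 or not (pos.min() <= kd * 10 and pos.max() >= kd / 10):
        warnings.warn(
            f"design grid [{pos.min() if pos.size else 0:g}, "
            f"{pos.max() if pos.size else 0:g}] M does not come within 10x of "
            f"kd = {kd:g} M; the fit may be unidentifiable",
            IdentifiabilityWarning, stacklevel=3)


def generate_titration(spec: GeneratorSpec) -> TitrationCurve:
    """Noisy replicate-averaged titration curve from the forward model.

    Per point, ``n_replicates`` i.i.d. Gaussian readings (SD = noise_sd)
    around the noiseless model are averaged; the sd column carries the
    replicate sample SD (NaN for a single replicate).  The generating
    truth is ``spec.truth`` / ``spec.conditions``.
    """
    _check_identifiable(spec)
    clean = simulate_curve(spec.grid, spec.conditions, spec.truth)
    if spec.noise_sd == 0:
        return TitrationCurve(conditions=spec.conditions, o_total=spec.grid,
                              anisotropy=clean.anisotropy,
                              sd=np.zeros_like(spec.grid),
                              n_rep=np.full(spec.grid.size, spec.n_replicates))
    rng = np.random.default_rng(spec.seed)
    reps = clean.anisotropy[None, :] + rng.normal(
        0.0, spec.noise_sd, size=(spec.n_replicates, spec.grid.size))
    mean = reps.mean(axis=0)
    sd = (reps.std(axis=0, ddof=1) if spec.n_replicates > 1
          else np.full(spec.grid.size, np.nan))
    return TitrationCurve(conditions=spec.conditions, o_total=spec.grid,
                          anisotropy=mean, sd=sd,
                          n_rep=np.full(spec.grid.size, spec.n_replicates))


def generate_salt_series(spec: GeneratorSpec, na_grid,
                         jitter_log_sd: float = 0.0,
                         label: str = "synthetic") -> SaltSeries:
    """Power-law K_D(Na+) series with optional lognormal jitter.

    With no jitter, a log10-log10 regression of the output recovers
    ``spec.salt_model.sk_true`` exactly.
    """
    if spec.salt_model is None:
        raise ValueError("spec.salt_model is required for salt-series generation")
    na = np.asarray(na_grid, dtype=float)
    if na.size < 2:
        raise ValueError("na_grid must have >= 2 points")
    if np.any(na <= 0) or np.any(np.diff(na) <= 0):
        raise ValueError("na_grid must be positive and strictly increasing")
    kd = spec.salt_model.kd_at(na)
    if jitter_log_sd > 0:
        rng = np.random.default_rng(spec.seed)
        kd = kd * 10.0 ** rng.normal(0.0, jitter_log_sd, size=na.size)
    sd = np.full(na.size, jitter_log_sd)
    return SaltSeries(label=label, na_conc=na, value=kd, sd=sd)


def generate_competition_curve(spec: GeneratorSpec,
                               competitor_total: float) -> TitrationCurve:
    """Titration in the presence of unlabeled cognate competitor.

    The competitor shares the probe's binding constants (it is the same
    site, unlabeled) and enters the titrant mass balance; at saturating
    competitor the saturable probe signal is quantitatively suppressed and
    only the linear phi term remains.
    """
    if competitor_total < 0:
        raise ValueError("competitor_total must be >= 0")
    cond = spec.conditions.replace(competitor_total=competitor_total)
    return generate_titration(spec.replace(conditions=cond))
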