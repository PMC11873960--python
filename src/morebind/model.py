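"""Forward equilibrium model for cooperative dimeric protein-DNA binding.

The observable is steady-state fluorescence anisotropy of a labeled DNA
probe carrying a single palindromic (MORE-type) site that is bound
cooperatively by two protein subunits.  The saturable component follows a
Hill isotherm in the *free* titrant concentration (n_H = 2 by default for
the 2:1 complex); an additional unsaturable "excess binding" signal grows
linearly in free titrant with coefficient phi.  Because the probe, an
unlabeled competitor carrying the same site, and a nonspecific DNA lattice
all deplete the titrant, the free concentration is obtained by solving the
mass balance numerically at every titration point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "BindingParameters",
    "AssayConditions",
    "SpeciationState",
    "TitrationCurve",
    "SpeciationError",
    "hill_fraction",
    "solve_speciation",
    "predict_anisotropy",
    "simulate_curve",
]

#: absolute + relative mass-balance tolerance (mol/L): tol = ABS + REL * o_total
RESIDUAL_ABS = 1e-15
RESIDUAL_REL = 1e-10


class SpeciationError(RuntimeError):
    """Raised when the mass-balance root find cannot be completed."""


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class BindingParameters:
    """Parameter vector of the anisotropy titration model.

    Attributes
    ----------
    kd : float
        Half-saturation constant of the Hill isotherm (mol/L).  This is the
        per-event constant of the fitting equation; the macroscopic 2:1
        dissociation constant is ``kd ** n_hill`` (M^2 for a dimer).
    n_hill : float
        Hill coefficient; 2 for the cooperative dimer.
    phi : float
        Excess-binding coefficient (1/(mol/L)) multiplying the free titrant
        concentration in the observable.
    r_unbound, r_specific : float
        Anisotropy of the unbound and specifically bound probe.
    """

    kd: float
    n_hill: float = 2.0
    phi: float = 0.0
    r_unbound: float = 0.0
    r_specific: float = 0.08

    def __post_init__(self) -> None:
        for name in ("kd", "n_hill", "phi", "r_unbound", "r_specific"):
            _require_finite(name, getattr(self, name))
        if self.kd <= 0:
            raise ValueError(f"kd must be > 0, got {self.kd}")
        if self.n_hill < 1:
            raise ValueError(f"n_hill must be >= 1, got {self.n_hill}")
        if self.phi < 0:
            raise ValueError(f"phi must be >= 0, got {self.phi}")
        if self.r_specific < self.r_unbound:
            raise ValueError("r_specific must be >= r_unbound")

    @property
    def kd_macroscopic(self) -> float:
        """Macroscopic dissociation constant of the n:1 complex (M^n_hill)."""
        return self.kd**self.n_hill

    def replace(self, **changes) -> "BindingParameters":
        return replace(self, **changes)


@dataclass(frozen=True)
class AssayConditions:
    """Solution context of one titration.

    Concentrations are mol/L throughout; ``ns_bp_total`` is mol/L of base
    pairs of nonspecific lattice DNA, which is converted to independent
    protein-binding sites by ``ns_site_size`` (bp occluded per bound dimer).
    """

    probe_total: float = 5e-9
    competitor_total: float = 0.0
    ns_bp_total: float = 0.0
    ns_site_size: float = 14.0
    ns_kd: float | None = None
    na_conc: float = 0.15
    temperature: float = 298.15

    def __post_init__(self) -> None:
        for name in ("probe_total", "competitor_total", "ns_bp_total"):
            if _require_finite(name, getattr(self, name)) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ns_site_size < 1:
            raise ValueError("ns_site_size must be >= 1 bp")
        if self.na_conc <= 0:
            raise ValueError("na_conc must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.ns_kd is not None and self.ns_kd <= 0:
            raise ValueError("ns_kd must be > 0 when given")

    @property
    def ns_sites(self) -> float:
        """Concentration of independent nonspecific sites (mol/L)."""
        return self.ns_bp_total / self.ns_site_size

    def replace(self, **changes) -> "AssayConditions":
        return replace(self, **changes)


@dataclass(frozen=True)
class SpeciationState:
    """Solved species concentrations (mol/L) at one titration point."""

    o_free: float
    p_specific: float
    p_unbound: float
    c_specific: float
    o_ns_bound: float
    o_total: float
    residual: float


@dataclass(frozen=True)
class TitrationCurve:
    """Ordered titration points under one set of assay conditions.

    ``points`` rows are (o_total, anisotropy, sd, n_rep); sd may be NaN when
    unknown.  o_total must be strictly increasing.
    """

    conditions: AssayConditions
    o_total: np.ndarray
    anisotropy: np.ndarray
    sd: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_rep: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        o = np.asarray(self.o_total, dtype=float)
        r = np.asarray(self.anisotropy, dtype=float)
        if o.ndim != 1 or o.shape != r.shape:
            raise ValueError("o_total and anisotropy must be 1-d and equal length")
        if np.any(o < 0) or np.any(~np.isfinite(o)):
            raise ValueError("o_total must be finite and >= 0")
        if np.any(np.diff(o) <= 0):
            raise ValueError("o_total must be strictly increasing")
        sd = np.full_like(o, np.nan) if self.sd is None else np.asarray(self.sd, float)
        n = np.ones_like(o) if self.n_rep is None else np.asarray(self.n_rep, float)
        if sd.shape != o.shape or n.shape != o.shape:
            raise ValueError("sd and n_rep must match o_total in length")
        object.__setattr__(self, "o_total", o)
        object.__setattr__(self, "anisotropy", r)
        object.__setattr__(self, "sd", sd)
        object.__setattr__(self, "n_rep", n)

    def __len__(self) -> int:
        return self.o_total.size


def hill_fraction(o_free, kd: float, n_hill: float = 2.0):
    """Fractional saturation of the cooperative site, o^n / (kd^n + o^n).

    Vectorized over ``o_free``.  Strictly increasing, 0 at 0, -> 1 as
    o_free -> infinity; equals 1/2 at o_free = kd for any Hill coefficient.
    """
    o = np.asarray(o_free, dtype=float)
    if np.any(~np.isfinite(o)) or np.any(o < 0):
        raise ValueError("o_free must be finite and >= 0")
    if not (math.isfinite(kd) and kd > 0):
        raise ValueError("kd must be finite and > 0")
    if not (math.isfinite(n_hill) and n_hill >= 1):
        raise ValueError("n_hill must be finite and >= 1")
    # (o/kd)^n / (1 + (o/kd)^n) avoids overflow of o^n for large o
    x = (o / kd) ** n_hill
    out = x / (1.0 + x)
    out = np.where(np.isinf(x), 1.0, out)
    return out if out.ndim else float(out)


def _mass_balance(o_free: float, o_total: float, conditions: AssayConditions,
                  params: BindingParameters, deplete_secondary: bool) -> float:
    """Total-minus-accounted titrant at a trial free concentration.

    Strictly increasing in o_free, negative at 0 (for o_total > 0) and
    o_total - accounted >= 0 at o_free = o_total is impossible to violate,
    guaranteeing a unique bracketed root.
    """
    theta = hill_fraction(o_free, params.kd, params.n_hill)
    bound = params.n_hill * theta * (conditions.probe_total + conditions.competitor_total)
    if conditions.ns_sites > 0:
        bound += conditions.ns_sites * o_free / (conditions.ns_kd + o_free)
    if deplete_secondary:
        dr = params.r_specific - params.r_unbound
        if dr > 0:
            bound += conditions.probe_total * params.phi * o_free / dr
    return o_free + bound - o_total


def solve_speciation(o_total: float, conditions: AssayConditions,
                     params: BindingParameters,
                     deplete_secondary: bool = False) -> SpeciationState:
    """Solve the coupled mass balance for the free titrant concentration.

    Finds the unique ``o_free`` in [0, o_total] at which the total titrant
    equals free plus n_hill-weighted specific occupancy of probe and
    competitor sites (both obeying the same Hill isotherm) plus Langmuir
    occupancy of the nonspecific lattice.  With ``deplete_secondary`` the
    titrant held in phi-type secondary complexes is also subtracted,
    converting excess anisotropy to protein equivalents through
    (r_specific - r_unbound) per probe; by default it is not (the probe is
    nM against uM titrant, so the contribution is negligible).
    """
    o_total = _require_finite("o_total", o_total)
    if o_total < 0:
        raise ValueError("o_total must be >= 0")
    if conditions.ns_bp_total > 0 and conditions.ns_kd is None:
        raise ValueError("ns_kd is required when ns_bp_total > 0")

    def finish(o_free: float) -> SpeciationState:
        theta = hill_fraction(o_free, params.kd, params.n_hill)
        p_sp = conditions.probe_total * theta
        c_sp = conditions.competitor_total * theta
        ns = 0.0
        if conditions.ns_sites > 0:
            ns = conditions.ns_sites * o_free / (conditions.ns_kd + o_free)
        res = abs(_mass_balance(o_free, o_total, conditions, params, deplete_secondary))
        return SpeciationState(
            o_free=o_free, p_specific=p_sp,
            p_unbound=conditions.probe_total - p_sp,
            c_specific=c_sp, o_ns_bound=ns, o_total=o_total, residual=res,
        )

    if o_total == 0.0:
        return finish(0.0)

    f0 = _mass_balance(0.0, o_total, conditions, params, deplete_secondary)
    f1 = _mass_balance(o_total, o_total, conditions, params, deplete_secondary)
    if f1 < 0 or f0 > 0:  # pragma: no cover - monotone balance makes this unreachable
        raise SpeciationError(
            f"root not bracketed on [0, {o_total:g}]: f(0)={f0:g}, f(o_total)={f1:g}"
        )
    try:
        o_free = brentq(
            _mass_balance, 0.0, o_total,
            args=(o_total, conditions, params, deplete_secondary),
            xtol=1e-300, rtol=4 * np.finfo(float).eps, maxiter=300,
        )
    except RuntimeError as exc:  # pragma: no cover
        raise SpeciationError(
            f"brentq failed on [0, {o_total:g}] (f(0)={f0:g}, f(o_total)={f1:g}): {exc}"
        ) from exc

    state = finish(o_free)
    tol = RESIDUAL_ABS + RESIDUAL_REL * o_total
    if state.residual > tol:  # pragma: no cover
        raise SpeciationError(
            f"mass-balance residual {state.residual:g} exceeds tolerance {tol:g}"
        )
    return state


def predict_anisotropy(state: SpeciationState, params: BindingParameters,
                       probe_total: float) -> float:
    """Population-weighted anisotropy plus the linear excess-binding term.

    r = (r_sp * [P]_sp + r_0 * [P]_0) / [P]_t + phi * [O]
    """
    if probe_total <= 0:
        raise ValueError("probe_total must be > 0")
    r = (params.r_specific * state.p_specific
         + params.r_unbound * state.p_unbound) / probe_total
    return r + params.phi * state.o_free


def simulate_curve(o_grid, conditions: AssayConditions,
                   params: BindingParameters,
                   deplete_secondary: bool = False) -> TitrationCurve:
    """Noiseless forward evaluation of the model on a concentration grid."""
    o = np.asarray(o_grid, dtype=float)
    if o.size == 0:
        raise ValueError("o_grid must be nonempty")
    r = np.empty_like(o)
    for i, ot in enumerate(o):
        try:
            state = solve_speciation(ot, conditions, params, deplete_secondary)
        except (SpeciationError, ValueError) as exc:
            raise SpeciationError(f"speciation failed at grid index {i} "
                                  f"(o_total={ot:g}): {exc}") from exc
        r[i] = predict_anisotropy(state, params, conditions.probe_total)
    return TitrationCurve(conditions=conditions, o_total=o, anisotropy=r)
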