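"""Weighted nonlinear least-squares estimation of titration parameters.

The estimator couples the mass-balance speciation solve to the anisotropy
observable and minimizes the (optionally inverse-variance weighted) sum of
squared residuals over (kd, phi, r_specific) and optionally (r_unbound,
n_hill).  kd and phi are optimized on log10 scale so positivity is
structural.  Uncertainty comes from the Jacobian at the optimum; a
residual-resampling bootstrap is available as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .model import (
    AssayConditions,
    BindingParameters,
    TitrationCurve,
    predict_anisotropy,
    solve_speciation,
)

__all__ = ["FitResult", "AnisotropyTitrationModel", "fit_titration",
           "bootstrap_uncertainty", "confidence_interval"]

_PARAM_NAMES = ("kd", "n_hill", "phi", "r_unbound", "r_specific")
_LOG_PARAMS = frozenset({"kd", "phi"})
_PHI_FLOOR = 1e-12  # M^-1; phi is log-scaled, exact zero handled by fixing


@dataclass(frozen=True)
class FitResult:
    """Point estimates with curvature-based uncertainty for one titration."""

    params: BindingParameters
    stderr: dict[str, float]
    covariance: np.ndarray
    free_names: tuple[str, ...]
    residuals: np.ndarray
    rss: float
    converged: bool
    n_points: int
    fixed: frozenset[str] = field(default_factory=frozenset)
    message: str = ""

    @property
    def dof(self) -> int:
        return self.n_points - len(self.free_names)


class AnisotropyTitrationModel(BaseEstimator, RegressorMixin):
    """Anisotropy titration curve fit with explicit titrant depletion.

    Parameters
    ----------
    conditions : AssayConditions
        Probe/competitor/nonspecific/salt context; the probe concentration
        enters the mass balance and the observable.
    init : BindingParameters, optional
        Starting values; defaults to a mid-range guess derived from the data.
    fixed : iterable of str
        Parameter names held at their ``init`` values.  By default
        ``n_hill`` (cooperative dimer, n = 2) and ``r_unbound`` (0 for
        baseline-subtracted data) are fixed.
    weighting : {"none", "inverse-variance"}
        Weight residuals by 1/sd when replicate SDs are available.
    n_starts : int
        Deterministic multi-start count over log10 kd within the data range.

    Attributes
    ----------
    params_ : BindingParameters
        Best-fit parameter vector.
    result_ : FitResult
        Full fit record (stderr, covariance, residuals, convergence).
    kd_, phi_, r_specific_, r_unbound_, n_hill_ : float
        Convenience copies of the fitted values.
    """

    def __init__(self, conditions: AssayConditions | None = None,
                 init: BindingParameters | None = None,
                 fixed: tuple = ("n_hill", "r_unbound"),
                 weighting: str = "none",
                 n_starts: int = 5,
                 deplete_secondary: bool = False):
        self.conditions = conditions
        self.init = init
        self.fixed = fixed
        self.weighting = weighting
        self.n_starts = n_starts
        self.deplete_secondary = deplete_secondary

    # -- forward model ----------------------------------------------------

    def _predict_with(self, o_total: np.ndarray, params: BindingParameters,
                      conditions: AssayConditions) -> np.ndarray:
        out = np.empty(o_total.shape, dtype=float)
        for i, ot in enumerate(o_total):
            st = solve_speciation(ot, conditions, params, self.deplete_secondary)
            out[i] = predict_anisotropy(st, params, conditions.probe_total)
        return out

    # -- parameter packing -------------------------------------------------

    @staticmethod
    def _pack(params: BindingParameters, free: tuple[str, ...]) -> np.ndarray:
        vals = []
        for name in free:
            v = getattr(params, name)
            vals.append(np.log10(max(v, _PHI_FLOOR)) if name in _LOG_PARAMS else v)
        return np.asarray(vals)

    @staticmethod
    def _unpack(x: np.ndarray, base: BindingParameters,
                free: tuple[str, ...]) -> SimpleNamespace:
        """Trial parameter vector without invariant checks.

        Optimizer steps may transiently propose e.g. r_specific < r_unbound;
        the invariants are enforced only on the final estimate.
        """
        trial = SimpleNamespace(kd=base.kd, n_hill=base.n_hill, phi=base.phi,
                                r_unbound=base.r_unbound,
                                r_specific=base.r_specific)
        for name, v in zip(free, x):
            v = float(np.clip(np.nan_to_num(v, nan=0.0), -300.0, 300.0))
            setattr(trial, name, 10.0**v if name in _LOG_PARAMS else v)
        return trial

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y, sample_weight=None):
        """Fit to total titrant concentrations X (mol/L) and anisotropies y."""
        o_total = np.asarray(X, dtype=float).reshape(-1)
        r_obs = np.asarray(y, dtype=float).reshape(-1)
        if o_total.shape != r_obs.shape:
            raise ValueError("X and y must have the same length")
        conditions = self.conditions if self.conditions is not None else AssayConditions()
        if self.weighting not in ("none", "inverse-variance"):
            raise ValueError(f"unknown weighting {self.weighting!r}")

        fixed = frozenset(self.fixed)
        unknown = fixed - set(_PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter names in fixed: {sorted(unknown)}")
        free = tuple(n for n in _PARAM_NAMES if n not in fixed)
        if o_total.size < len(free):
            raise ValueError(
                f"{o_total.size} points cannot constrain {len(free)} free parameters")
        if o_total.size < 6:
            raise ValueError("at least 6 titration points are required")

        if sample_weight is not None:
            w = np.sqrt(np.asarray(sample_weight, dtype=float).reshape(-1))
        elif self.weighting == "inverse-variance" and self._sd is not None \
                and np.all(np.isfinite(self._sd)) and np.all(self._sd > 0):
            w = 1.0 / self._sd
        else:
            w = np.ones_like(r_obs)

        init = self.init if self.init is not None else self._default_init(o_total, r_obs)
        if "phi" in free and init.phi <= _PHI_FLOOR:
            # a start at the positivity floor has zero gradient on log scale;
            # seed from the high-concentration slope of the data instead
            init = init.replace(phi=self._phi_guess(o_total, r_obs))

        def resid(x: np.ndarray, base: BindingParameters) -> np.ndarray:
            p = self._unpack(x, base, free)
            out = w * (r_obs - self._predict_with(o_total, p, conditions))
            return np.nan_to_num(out, nan=1e6, posinf=1e6, neginf=-1e6)

        positive = o_total[o_total > 0]
        lo = np.log10(positive.min()) if positive.size else -9.0
        hi = np.log10(positive.max()) if positive.size else -5.0
        kd_starts = (np.logspace(lo, hi, self.n_starts)
                     if "kd" in free and self.n_starts > 1 else [init.kd])

        best = None
        for kd0 in kd_starts:
            base = init.replace(kd=float(kd0)) if "kd" in free else init
            x0 = self._pack(base, free)
            sol = least_squares(resid, x0, args=(base,), method="lm", xtol=1e-14,
                                ftol=1e-14, gtol=1e-14, max_nfev=400 * len(free))
            if best is None or sol.cost < best[0].cost - 1e-30:
                best = (sol, base)
        sol, base = best

        trial = self._unpack(sol.x, base, free)
        try:
            params = BindingParameters(kd=trial.kd, n_hill=trial.n_hill,
                                       phi=trial.phi, r_unbound=trial.r_unbound,
                                       r_specific=trial.r_specific)
            valid = True
        except ValueError:
            # optimum violates an invariant (e.g. flat curve pulls r_specific
            # below r_unbound): report the clipped vector, flagged unconverged
            params = BindingParameters(
                kd=trial.kd, n_hill=trial.n_hill, phi=max(trial.phi, 0.0),
                r_unbound=trial.r_unbound,
                r_specific=max(trial.r_specific, trial.r_unbound))
            valid = False
        raw_resid = r_obs - self._predict_with(o_total, params, conditions)
        rss = float(np.sum((w * raw_resid) ** 2))

        cov, stderr, identifiable = self._covariance(sol, params, free,
                                                     o_total.size, rss)
        converged = bool(sol.success) and identifiable and valid
        self.result_ = FitResult(
            params=params, stderr=stderr, covariance=cov, free_names=free,
            residuals=raw_resid, rss=rss, converged=converged,
            n_points=int(o_total.size), fixed=fixed,
            message=sol.message if identifiable else
            f"{sol.message}; near-singular Jacobian (unidentifiable parameters)",
        )
        self.params_ = params
        for name in _PARAM_NAMES:
            setattr(self, f"{name}_", getattr(params, name))
        self.conditions_ = conditions
        self._weights = w
        return self

    def _covariance(self, sol, params: BindingParameters, free, n_points, rss):
        """Covariance of the free parameters on their natural scale.

        Computed from the Jacobian at the optimum; the log10(kd)/log10(phi)
        coordinates are mapped back by the delta method.
        """
        dof = max(n_points - len(free), 1)
        s2 = rss / dof
        # SVD pseudo-inverse of J^T J: near-singular directions get large,
        # finite variances instead of a failed inversion
        U, sv, Vt = np.linalg.svd(sol.jac, full_matrices=False)
        cutoff = np.finfo(float).eps * max(sol.jac.shape) * sv.max()
        inv_s2 = np.where(sv > cutoff, 1.0 / np.maximum(sv, cutoff) ** 2, np.inf)
        inv_s2 = np.minimum(inv_s2, 1e60)
        cov_internal = s2 * (Vt.T * inv_s2) @ Vt
        identifiable = bool(sv.min() > 1e-6 * sv.max())
        # d(natural)/d(internal): 10^x -> ln10 * value for log-scaled params
        scale = np.array([np.log(10.0) * getattr(params, n)
                          if n in _LOG_PARAMS else 1.0 for n in free])
        cov = cov_internal * np.outer(scale, scale)
        stderr = {n: float(np.sqrt(cov[i, i])) if cov[i, i] >= 0 else np.nan
                  for i, n in enumerate(free)}
        return cov, stderr, identifiable

    def _default_init(self, o_total: np.ndarray, r_obs: np.ndarray) -> BindingParameters:
        positive = o_total[o_total > 0]
        kd0 = float(np.sqrt(positive.min() * positive.max())) if positive.size else 1e-8
        r_hi = float(np.quantile(r_obs, 0.9))
        return BindingParameters(kd=kd0, n_hill=2.0,
                                 phi=self._phi_guess(o_total, r_obs),
                                 r_unbound=0.0, r_specific=max(r_hi, 1e-3))

    @staticmethod
    def _phi_guess(o_total: np.ndarray, r_obs: np.ndarray) -> float:
        """Excess-binding slope estimated from the top of the titration."""
        top = max(2, o_total.size // 4)
        o, r = o_total[-top:], r_obs[-top:]
        span = o[-1] - o[0]
        slope = (r[-1] - r[0]) / span if span > 0 else 0.0
        return max(slope, 1e-2)

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        o_total = np.asarray(X, dtype=float).reshape(-1)
        return self._predict_with(o_total, self.params_, self.conditions_)

    # fit() pulls replicate SDs from here when weighting="inverse-variance"
    _sd: np.ndarray | None = None

    def fit_curve(self, curve: TitrationCurve):
        """Fit a TitrationCurve, using its conditions and replicate SDs."""
        self.conditions = curve.conditions
        self._sd = curve.sd
        try:
            return self.fit(curve.o_total, curve.anisotropy)
        finally:
            self._sd = None


def fit_titration(curve: TitrationCurve,
                  init: BindingParameters | None = None,
                  fixed: tuple = ("n_hill", "r_unbound"),
                  weighting: str = "none",
                  deplete_secondary: bool = False) -> FitResult:
    """Fit one titration curve; thin wrapper over AnisotropyTitrationModel."""
    est = AnisotropyTitrationModel(conditions=curve.conditions, init=init,
                                   fixed=fixed, weighting=weighting,
                                   deplete_secondary=deplete_secondary)
    est.fit_curve(curve)
    return est.result_


def confidence_interval(fit: FitResult, name: str,
                        level: float = 0.95) -> tuple[float, float]:
    """Wald confidence interval for one fitted parameter.

    kd and phi intervals are formed on the log10 scale (where the fit is
    parameterized and sampling distributions are closer to normal) and
    mapped back; the Student-t quantile at the fit's residual degrees of
    freedom is used.
    """
    from scipy.stats import t as student_t

    if name not in fit.free_names:
        raise ValueError(f"{name!r} was not a free parameter")
    value = getattr(fit.params, name)
    se = fit.stderr[name]
    q = student_t.ppf(0.5 + level / 2.0, max(fit.dof, 1))
    if name in _LOG_PARAMS:
        se_log = se / (value * np.log(10.0))
        center = np.log10(value)
        return 10.0 ** (center - q * se_log), 10.0 ** (center + q * se_log)
    return value - q * se, value + q * se


def bootstrap_uncertainty(curve: TitrationCurve, fit: FitResult,
                          n_boot: int = 500, seed: int = 0,
                          level: float = 0.95) -> dict[str, tuple[float, float]]:
    """Residual-resampling bootstrap percentile intervals per free parameter.

    Fitted values are perturbed by resampled fit residuals and refit;
    the (1-level)/2 and 1-(1-level)/2 percentiles of the replicate
    estimates are returned for each free parameter.  Reproducible given
    ``seed``.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200 for stable percentiles")
    if not fit.converged:
        raise ValueError("refusing to bootstrap a non-converged fit")
    rng = np.random.default_rng(seed)
    fitted = curve.anisotropy - fit.residuals
    draws: dict[str, list[float]] = {n: [] for n in fit.free_names}
    for _ in range(n_boot):
        resampled = fitted + rng.choice(fit.residuals, size=fit.residuals.size,
                                        replace=True)
        est = AnisotropyTitrationModel(conditions=curve.conditions,
                                       init=fit.params, fixed=tuple(fit.fixed),
                                       n_starts=1)
        est.fit(curve.o_total, resampled)
        for n in fit.free_names:
            draws[n].append(getattr(est.params_, n))
    alpha = (1.0 - level) / 2.0
    return {n: (float(np.quantile(v, alpha)), float(np.quantile(v, 1 - alpha)))
            for n, v in draws.items()}
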