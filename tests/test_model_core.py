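"""Forward-model unit and property tests: Hill isotherm, speciation, observable."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from morebind import (
    AssayConditions,
    BindingParameters,
    SpeciationState,
    hill_fraction,
    predict_anisotropy,
    simulate_curve,
    solve_speciation,
)


def bisection_oracle(o_total, probe_total, competitor_total, ns_sites, ns_kd,
                     kd, n_hill, iters=200):
    """Independent bisection on the scalar mass-balance function."""

    def balance(o):
        theta = (o / kd) ** n_hill / (1.0 + (o / kd) ** n_hill) if o > 0 else 0.0
        ns = ns_sites * o / (ns_kd + o) if ns_sites > 0 else 0.0
        return o + n_hill * theta * (probe_total + competitor_total) + ns - o_total

    lo, hi = 0.0, o_total
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if balance(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


class TestHillFraction:
    @pytest.mark.parametrize("n", [1.0, 2.0, 3.5])
    def test_half_saturation_identity(self, n):
        assert hill_fraction(2.5e-9, 2.5e-9, n) == pytest.approx(0.5, abs=1e-15)

    def test_boundary_values(self):
        assert hill_fraction(0.0, 1e-9, 2) == 0.0
        assert hill_fraction(3e-9, 1e-9, 2) == pytest.approx(0.9, abs=1e-15)
        assert hill_fraction(1e30, 1e-9, 2) == pytest.approx(1.0)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            hill_fraction(-1e-9, 1e-9, 2)
        with pytest.raises(ValueError):
            hill_fraction(1e-9, 0.0, 2)
        with pytest.raises(ValueError):
            hill_fraction(np.nan, 1e-9, 2)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.floats(1e-2, 1e2), st.floats(1e-2, 1e2),
           st.floats(1e-12, 1e-3), st.floats(1.0, 4.0))
    def test_strictly_increasing(self, r1, r2, kd, n):
        # ratios to kd keep both points away from the flat saturated tails
        lo, hi = kd * min(r1, r2), kd * max(r1, r2)
        if lo == hi:
            return
        assert hill_fraction(lo, kd, n) < hill_fraction(hi, kd, n)


class TestSolveSpeciation:
    def test_zero_titrant(self, probe_conditions, canonical_params):
        st_ = solve_speciation(0.0, probe_conditions, canonical_params)
        assert st_.o_free == 0.0
        assert st_.p_specific == 0.0
        assert st_.residual == 0.0
        assert st_.p_unbound == probe_conditions.probe_total

    def test_no_depletion_limit(self, canonical_params):
        kd = canonical_params.kd
        cond = AssayConditions(probe_total=1e-16)
        st_ = solve_speciation(kd, cond, canonical_params)
        assert st_.o_free == pytest.approx(kd, rel=1e-6)
        assert st_.p_specific / cond.probe_total == pytest.approx(0.5, rel=1e-6)

    def test_agrees_with_bisection_oracle_example(self):
        params = BindingParameters(kd=1e-8, n_hill=2.0, phi=0.0,
                                   r_specific=0.08)
        cond = AssayConditions(probe_total=1e-7)
        st_ = solve_speciation(5e-8, cond, params)
        oracle = bisection_oracle(5e-8, 1e-7, 0.0, 0.0, None, 1e-8, 2.0)
        assert st_.o_free == pytest.approx(oracle, rel=1e-12)

    def test_oracle_equivalence_randomized(self):
        """Brent solve matches exhaustive bisection over 1000 random draws."""
        rng = np.random.default_rng(1234)
        for _ in range(1000):
            kd = 10.0 ** rng.uniform(-9.5, -6)
            probe = 10.0 ** rng.uniform(-9.5, -7)
            comp = rng.choice([0.0, 10.0 ** rng.uniform(-8, -5)])
            ns_bp = rng.choice([0.0, 10.0 ** rng.uniform(-5, -2)])
            ns_kd = 10.0 ** rng.uniform(-7, -4)
            o_total = 10.0 ** rng.uniform(-9, -5)
            params = BindingParameters(kd=kd, n_hill=2.0, phi=0.0,
                                       r_specific=0.08)
            cond = AssayConditions(probe_total=probe, competitor_total=comp,
                                   ns_bp_total=ns_bp, ns_kd=ns_kd)
            st_ = solve_speciation(o_total, cond, params)
            oracle = bisection_oracle(o_total, probe, comp, cond.ns_sites,
                                      ns_kd, kd, 2.0)
            assert st_.o_free == pytest.approx(oracle, rel=1e-12, abs=1e-30)

    def test_requires_ns_kd_with_lattice(self, canonical_params):
        cond = AssayConditions(probe_total=5e-9, ns_bp_total=7e-3)
        with pytest.raises(ValueError, match="ns_kd"):
            solve_speciation(1e-7, cond, canonical_params)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.floats(-10, -5), st.floats(-10, -6), st.floats(-9.5, -6.5))
    def test_mass_conservation(self, log_o, log_probe, log_kd):
        o_total, probe, kd = 10.0**log_o, 10.0**log_probe, 10.0**log_kd
        params = BindingParameters(kd=kd, n_hill=2.0, phi=0.0, r_specific=0.08)
        cond = AssayConditions(probe_total=probe)
        st_ = solve_speciation(o_total, cond, params)
        lhs = st_.o_free + 2 * st_.p_specific + 2 * st_.c_specific + st_.o_ns_bound
        assert lhs == pytest.approx(o_total, rel=1e-9, abs=1e-15)
        assert st_.p_specific + st_.p_unbound == pytest.approx(probe, rel=1e-12)

    def test_bound_probe_monotone_in_titrant(self, probe_conditions,
                                             canonical_params):
        grid = np.logspace(-10, -5, 40)
        bound = [solve_speciation(o, probe_conditions, canonical_params).p_specific
                 for o in grid]
        assert np.all(np.diff(bound) >= -1e-18)

    def test_competition_capacity_bound(self, canonical_params):
        """Saturating unlabeled cognate site quantitatively inhibits probe binding.

        Probe and competitor share the isotherm, so probe saturation cannot
        exceed the titrant-to-capacity ratio o_total / (2 * competitor).
        """
        cond = AssayConditions(probe_total=5e-9, competitor_total=1e-5)
        for o_total in np.logspace(-8, np.log10(2e-6), 8):
            st_ = solve_speciation(o_total, cond, canonical_params)
            theta = st_.p_specific / cond.probe_total
            assert theta <= o_total / (2 * cond.competitor_total) + 1e-12
        # at the 1 uM top of the titration design, saturation stays ~5%
        st_top = solve_speciation(1e-6, cond, canonical_params)
        assert st_top.p_specific / cond.probe_total < 0.06


class TestPredictAnisotropy:
    def test_population_weighting(self):
        params = BindingParameters(kd=1e-9, phi=0.0, r_unbound=0.0,
                                   r_specific=0.10)
        st_ = SpeciationState(o_free=0.0, p_specific=2.5e-9, p_unbound=2.5e-9,
                              c_specific=0.0, o_ns_bound=0.0, o_total=0.0,
                              residual=0.0)
        assert predict_anisotropy(st_, params, 5e-9) == pytest.approx(0.050)

    def test_excess_binding_term(self):
        params = BindingParameters(kd=1e-9, phi=1.0e4, r_unbound=0.0,
                                   r_specific=0.08)
        st_ = SpeciationState(o_free=1.0e-6, p_specific=0.0, p_unbound=5e-9,
                              c_specific=0.0, o_ns_bound=0.0, o_total=1e-6,
                              residual=0.0)
        assert predict_anisotropy(st_, params, 5e-9) == pytest.approx(0.010)

    def test_low_salt_phi_arithmetic(self):
        # phi = 2.6e4 /M at 0.15 M Na+, saturated probe: 0.08 + 0.013
        params = BindingParameters(kd=1e-9, phi=2.6e4, r_unbound=0.0,
                                   r_specific=0.08)
        st_ = SpeciationState(o_free=5e-7, p_specific=5e-9, p_unbound=0.0,
                              c_specific=0.0, o_ns_bound=0.0, o_total=1e-6,
                              residual=0.0)
        assert predict_anisotropy(st_, params, 5e-9) == pytest.approx(0.093)

    def test_rejects_zero_probe(self, canonical_params):
        st_ = SpeciationState(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            predict_anisotropy(st_, canonical_params, 0.0)


class TestSimulateCurve:
    def test_zero_point_gives_baseline(self, probe_conditions):
        params = BindingParameters(kd=1e-9, phi=0.0, r_unbound=0.012,
                                   r_specific=0.08)
        curve = simulate_curve([0.0], probe_conditions, params)
        assert curve.anisotropy[0] == pytest.approx(0.012)

    def test_saturation_limit(self, probe_conditions):
        params = BindingParameters(kd=1e-9, phi=0.0, r_specific=0.08)
        curve = simulate_curve([1e-3], probe_conditions, params)
        assert curve.anisotropy[0] == pytest.approx(0.08, rel=1e-5)

    def test_monotone_when_phi_nonnegative(self, probe_conditions,
                                           canonical_params):
        curve = simulate_curve(np.logspace(-9, -5, 25), probe_conditions,
                               canonical_params)
        assert np.all(np.diff(curve.anisotropy) >= -1e-15)

    def test_half_transition_at_kd_free(self, probe_conditions):
        """Inverting the isotherm at each point recovers theta(o_free) = 1/2 at kd."""
        params = BindingParameters(kd=3.8e-9, phi=0.0, r_specific=0.08)
        grid = np.logspace(-9, -5, 100)
        curve = simulate_curve(grid, probe_conditions, params)
        theta = curve.anisotropy / params.r_specific
        o_free = np.array([solve_speciation(o, probe_conditions, params).o_free
                           for o in grid])
        # fractional saturation matches the closed-form isotherm in o_free
        expected = o_free**2 / (params.kd**2 + o_free**2)
        np.testing.assert_allclose(theta, expected, rtol=1e-9)
        # and crosses 1/2 where o_free = kd (log-space numerical inversion)
        crossing = 10.0 ** np.interp(0.5, theta, np.log10(o_free))
        assert crossing == pytest.approx(params.kd, rel=0.01)


class TestInvariants:
    def test_binding_parameters_invariants(self):
        with pytest.raises(ValueError):
            BindingParameters(kd=-1e-9)
        with pytest.raises(ValueError):
            BindingParameters(kd=1e-9, n_hill=0.5)
        with pytest.raises(ValueError):
            BindingParameters(kd=1e-9, phi=-1.0)
        with pytest.raises(ValueError):
            BindingParameters(kd=1e-9, r_unbound=0.1, r_specific=0.05)

    def test_macroscopic_kd_mapping(self):
        p = BindingParameters(kd=3.8e-9, n_hill=2.0)
        assert p.kd_macroscopic == pytest.approx((3.8e-9) ** 2)

    def test_conditions_invariants(self):
        with pytest.raises(ValueError):
            AssayConditions(probe_total=-1e-9)
        with pytest.raises(ValueError):
            AssayConditions(na_conc=0.0)
        with pytest.raises(ValueError):
            AssayConditions(ns_site_size=0.5)
        cond = AssayConditions(ns_bp_total=7e-3, ns_site_size=14, ns_kd=1e-6)
        assert cond.ns_sites == pytest.approx(5e-4)
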