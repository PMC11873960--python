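"""Coupled mass-action network for protein partitioning among DNA species.

Five macroscopic protein species are in dynamic equilibrium:

1. unbound protein
2. site-specific complex (two subunits on one cognate MORE site)
3. secondary, oversaturated MORE complex (one extra protein on 2)
4. nonspecific complex (one protein per lattice site)
5. cross-linked intermediate (a protein bridging a nonspecific site and a
   MORE-bound complex, the intersegmental-transfer conduit)

Each transition carries an ion stoichiometry dm so its equilibrium
constant follows a power law in [Na+]; cycle (thermodynamic) consistency
is enforced before solving.  The module is a qualitative/semiquantitative
simulator: transition constants touching species 3-5 are not measured
quantities, only their salt-response signs are constrained, so default
magnitudes are illustrative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import root

__all__ = ["Transition", "EquilibriumNetwork", "NetworkConsistencyError",
           "k_at_salt", "solve_network", "salt_scan", "default_network",
           "FREE_SPECIES", "DEFAULT_COMPOSITIONS"]

#: free "component" species: protein, cognate (MORE) site, nonspecific site
FREE_SPECIES = ("unbound", "more_site", "ns_site")

#: composition of each species as (protein, MORE sites, NS sites)
DEFAULT_COMPOSITIONS: dict[str, tuple[int, int, int]] = {
    "unbound": (1, 0, 0),
    "more_site": (0, 1, 0),
    "ns_site": (0, 0, 1),
    "specific": (2, 1, 0),
    "secondary": (3, 1, 0),
    "nonspecific": (1, 0, 1),
    "bridged": (3, 1, 1),
}


class NetworkConsistencyError(ValueError):
    """The transition set violates element balance or cycle consistency."""


@dataclass(frozen=True)
class Transition:
    """One reversible reaction with a salt-dependent equilibrium constant.

    ``reactants`` and ``products`` map species names to stoichiometric
    counts.  ``k_ref`` is the equilibrium constant (products over
    reactants, molar units implied by the stoichiometry) at ``ref_na``;
    at other salts K(na) = k_ref * (na / ref_na) ** dm, so dm < 0 means
    net ion release in the forward direction.  k_ref = 0 switches the
    transition off (its product complex is treated as unpopulated).
    """

    reactants: dict[str, int]
    products: dict[str, int]
    k_ref: float
    ref_na: float = 0.175
    dm: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.k_ref < 0:
            raise ValueError("k_ref must be >= 0")
        if self.ref_na <= 0:
            raise ValueError("ref_na must be > 0")
        for side in (self.reactants, self.products):
            for name, count in side.items():
                if count <= 0:
                    raise ValueError(f"stoichiometric count for {name} must be > 0")

    def net_stoich(self, species: tuple[str, ...]) -> np.ndarray:
        """Signed stoichiometry vector (products positive) over ``species``."""
        nu = np.zeros(len(species))
        idx = {s: i for i, s in enumerate(species)}
        for name, count in self.reactants.items():
            if name not in idx:
                raise NetworkConsistencyError(f"unknown species {name!r}")
            nu[idx[name]] -= count
        for name, count in self.products.items():
            if name not in idx:
                raise NetworkConsistencyError(f"unknown species {name!r}")
            nu[idx[name]] += count
        return nu


def k_at_salt(t: Transition, na_conc: float) -> float:
    """Equilibrium constant of ``t`` at the given Na+ concentration.

    log10 K is linear in log10 [Na+] with slope dm.
    """
    if na_conc <= 0:
        raise ValueError("na_conc must be > 0")
    return t.k_ref * (na_conc / t.ref_na) ** t.dm


@dataclass(frozen=True)
class EquilibriumNetwork:
    """Species, transitions and conserved totals of the coupled system.

    totals are (protein, MORE sites, nonspecific sites) in mol/L.
    Validation checks element balance of every transition and overall
    thermodynamic consistency: ln K and dm must both be expressible
    through per-species formation potentials, which is equivalent to
    every reaction cycle having a unity constant product and zero net dm
    at every salt.
    """

    transitions: tuple[Transition, ...]
    protein_total: float
    more_total: float
    ns_total: float
    compositions: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITIONS))

    def __post_init__(self) -> None:
        if min(self.protein_total, self.more_total, self.ns_total) < 0:
            raise ValueError("totals must be >= 0")
        object.__setattr__(self, "transitions", tuple(self.transitions))
        self.validate()

    # -- structural queries ------------------------------------------------

    @property
    def complex_species(self) -> tuple[str, ...]:
        active = self._active_transitions()
        names = []
        for t in active:
            for name in (*t.reactants, *t.products):
                if name not in FREE_SPECIES and name not in names:
                    names.append(name)
        return tuple(names)

    def _active_transitions(self) -> tuple[Transition, ...]:
        return tuple(t for t in self.transitions if t.k_ref > 0)

    def _formation_matrix(self):
        """Reaction matrix over complex species; rows are active transitions."""
        active = self._active_transitions()
        complexes = self.complex_species
        all_species = FREE_SPECIES + complexes
        comp = np.array([self.compositions[s] for s in all_species])
        rows = []
        for t in active:
            nu = t.net_stoich(all_species)
            if not np.allclose(nu @ comp, 0.0, atol=1e-12):
                raise NetworkConsistencyError(
                    f"transition {t.label or (t.reactants, t.products)} does not "
                    "conserve protein/site composition")
            rows.append(nu[len(FREE_SPECIES):])
        M = np.array(rows) if rows else np.zeros((0, len(complexes)))
        return active, complexes, M

    def validate(self) -> None:
        """Reject element-unbalanced or cycle-inconsistent transition sets."""
        for name in self.compositions:
            if len(self.compositions[name]) != 3:
                raise NetworkConsistencyError(f"composition of {name!r} must be a triple")
        active, complexes, M = self._formation_matrix()
        if not active:
            return
        lnk = np.array([np.log(t.k_ref) for t in active])
        # reference salts may differ; put all ln K on a common salt first
        na0 = active[0].ref_na
        lnk0 = lnk + np.array([t.dm * np.log(na0 / t.ref_na) for t in active])
        dm = np.array([t.dm for t in active])
        for vec, what in ((lnk0, "equilibrium constants"), (dm, "ion stoichiometries")):
            x, *_ = np.linalg.lstsq(M, vec, rcond=None)
            resid = M @ x - vec
            if np.max(np.abs(resid)) > 1e-8:
                raise NetworkConsistencyError(
                    f"cycle-inconsistent {what}: residual {np.max(np.abs(resid)):.3g} "
                    "(product of constants around a cycle must be 1 and net dm 0)")
        if np.linalg.matrix_rank(M) < len(complexes):
            raise NetworkConsistencyError(
                "underdetermined network: some complex has no formation route")

    # -- formation constants at a salt ------------------------------------

    def formation_log_betas(self, na_conc: float) -> dict[str, float]:
        """ln beta of each complex from free components at the given salt.

        [complex] = beta * [P]^a [M]^b [N]^c with (a, b, c) its composition.
        """
        active, complexes, M = self._formation_matrix()
        if not active:
            return {}
        lnk = np.array([np.log(k_at_salt(t, na_conc)) for t in active])
        x, *_ = np.linalg.lstsq(M, lnk, rcond=None)
        return dict(zip(complexes, x))


def _conservation(free: np.ndarray, net: EquilibriumNetwork,
                  log_betas: dict[str, float], complexes: tuple[str, ...]):
    """Totals accounted for by free species plus complexes, per component."""
    conc = {s: 0.0 for s in complexes}
    for s in complexes:
        ln = log_betas[s]
        for count, conc_free in zip(net.compositions[s], free):
            if count == 0:
                continue
            if conc_free <= 0:  # complex needs a component that is absent
                ln = -np.inf
                break
            ln += count * np.log(conc_free)
        conc[s] = float(np.exp(ln)) if ln > -np.inf else 0.0
    totals = np.array(free, dtype=float)
    for s in complexes:
        totals += np.array(net.compositions[s], dtype=float) * conc[s]
    return totals, conc


def solve_network(net: EquilibriumNetwork, na_conc: float,
                  tol: float = 1e-12, max_fixed_point: int = 4000) -> dict[str, float]:
    """Equilibrium concentrations of every species at one salt.

    Works on log free-component concentrations (positivity structural):
    a damped fixed point brings the iterate into the basin, then a Newton
    polish (scipy root) drives relative conservation residuals below
    ``tol`` (default 1e-12, always <= 1e-10 as guaranteed accuracy).
    Components whose total is zero are dropped from the solve.
    """
    targets = np.array([net.protein_total, net.more_total, net.ns_total])
    complexes = net.complex_species
    log_betas = net.formation_log_betas(na_conc)
    out = {s: 0.0 for s in (*FREE_SPECIES, *complexes)}
    if np.all(targets == 0):
        return out
    mask = targets > 0  # active components

    def accounted(free_masked: np.ndarray):
        free = np.zeros(3)
        free[mask] = free_masked
        return _conservation(free, net, log_betas, complexes)

    # damped multiplicative fixed point on the active free concentrations
    free = 0.5 * targets[mask]
    damp = 0.5
    for _ in range(max_fixed_point):
        tot, _ = accounted(free)
        ratio = targets[mask] / tot[mask]
        free = free * ratio**damp
        if np.max(np.abs(ratio - 1.0)) < 1e-6:
            break

    def residual(logc: np.ndarray) -> np.ndarray:
        tot, _ = accounted(np.exp(logc))
        return tot[mask] / targets[mask] - 1.0

    sol = root(residual, np.log(free), method="hybr", tol=1e-15)
    res = np.max(np.abs(residual(sol.x)))
    if res > max(tol, 1e-10):
        raise RuntimeError(
            f"network solve did not converge at [Na+]={na_conc:g} M: "
            f"max relative conservation residual {res:.3g}")
    free_full = np.zeros(3)
    free_full[mask] = np.exp(sol.x)
    _, conc = accounted(np.exp(sol.x))
    out.update(dict(zip(FREE_SPECIES, free_full)))
    out.update(conc)
    return out


def default_network(protein_total: float = 5e-8,
                    more_total: float = 5e-9,
                    ns_bp_total: float = 7e-3,
                    ns_site_size: float = 14.0,
                    kd_ref: float = 9.7e-9,
                    ref_na: float = 0.175,
                    dm_specific: float = -6.8,
                    dm_nonspecific: float = -9.0,
                    k_nonspecific: float = 1.0e4,
                    k_extra: float = 2.0e4,
                    k_bridge: float = 5.0e8) -> EquilibriumNetwork:
    """Default five-species parameterization.

    The specific-binding edge carries the measured dm = -6.8 and the
    measured kd at the reference salt (K = 1/kd^2 for the 2-protein
    reaction).  Edges touching species 3-5 follow the scheme's sign
    assignments: dm ~ 0 for 4<->5 (bridging, no net occupancy change) and
    3<->2 (extra-protein release), nonspecific binding releases more ions
    than specific (|dm| = 9), and cycle closure then forces ion uptake
    (dm = +9) on 5 -> 3.  Magnitudes of the unmeasured constants are
    illustrative, placed so nonspecific DNA inhibits specific occupancy
    at low salt and stimulates it at high salt.
    """
    transitions = (
        Transition({"unbound": 2, "more_site": 1}, {"specific": 1},
                   k_ref=1.0 / kd_ref**2, ref_na=ref_na, dm=dm_specific,
                   label="1->2 specific"),
        Transition({"unbound": 1, "ns_site": 1}, {"nonspecific": 1},
                   k_ref=k_nonspecific, ref_na=ref_na, dm=dm_nonspecific,
                   label="1->4 nonspecific"),
        Transition({"specific": 1, "nonspecific": 1}, {"bridged": 1},
                   k_ref=k_bridge, ref_na=ref_na, dm=0.0,
                   label="2+4->5 bridge"),
        # cycle closure 1->4->5->3->2->1 fixes K(5->3) and dm(5->3) = -dm(1->4)
        Transition({"bridged": 1}, {"secondary": 1, "ns_site": 1},
                   k_ref=(k_extra / (k_bridge * k_nonspecific)
                          if min(k_extra, k_bridge, k_nonspecific) > 0 else 0.0),
                   ref_na=ref_na, dm=-dm_nonspecific,
                   label="5->3 transfer"),
        Transition({"secondary": 1}, {"specific": 1, "unbound": 1},
                   k_ref=1.0 / k_extra if k_extra > 0 else 0.0,
                   ref_na=ref_na, dm=0.0,
                   label="3->2 release"),
    )
    return EquilibriumNetwork(transitions=transitions,
                              protein_total=protein_total,
                              more_total=more_total,
                              ns_total=ns_bp_total / ns_site_size)


def salt_scan(net: EquilibriumNetwork, na_grid, with_ns: bool = True) -> pd.DataFrame:
    """Speciation vs salt, with and without the nonspecific lattice.

    Returns one row per salt with fractional specific occupancy of the
    cognate sites (species 2 + 3 + 5 per MORE site), secondary and
    nonspecific loads, and the with-minus-without difference in specific
    occupancy.  The attribute ``df.attrs["crossover_na"]`` holds the salt
    at which that difference changes sign (linear interpolation), or None.
    """
    na_grid = np.asarray(na_grid, dtype=float)
    if np.any(np.diff(na_grid) <= 0):
        raise ValueError("na_grid must be strictly increasing")
    bare = EquilibriumNetwork(transitions=net.transitions,
                              protein_total=net.protein_total,
                              more_total=net.more_total, ns_total=0.0,
                              compositions=net.compositions)
    rows = []
    for na in na_grid:
        w = solve_network(net if with_ns else bare, na)
        wo = solve_network(bare, na)
        mt = net.more_total
        occ_w = (w["specific"] + w.get("secondary", 0) + w.get("bridged", 0)) / mt
        occ_wo = (wo["specific"] + wo.get("secondary", 0) + wo.get("bridged", 0)) / mt
        ns_load = ((w.get("nonspecific", 0) + w.get("bridged", 0)) / net.ns_total
                   if (with_ns and net.ns_total > 0) else 0.0)
        rows.append({
            "na_conc": na,
            "specific_occupancy": occ_w,
            "specific_occupancy_no_ns": occ_wo,
            "secondary_load": w.get("secondary", 0) / mt,
            "ns_load": ns_load,
            "free_protein": w["unbound"],
            "ns_effect": occ_w - occ_wo,
        })
    df = pd.DataFrame(rows)
    eff = df["ns_effect"].to_numpy()
    crossover = None
    sign_change = np.nonzero(np.sign(eff[:-1]) * np.sign(eff[1:]) < 0)[0]
    if with_ns and sign_change.size:
        i = sign_change[0]
        x0, x1 = df["na_conc"].iloc[i], df["na_conc"].iloc[i + 1]
        y0, y1 = eff[i], eff[i + 1]
        crossover = float(x0 - y0 * (x1 - x0) / (y1 - y0))
    df.attrs["crossover_na"] = crossover
    return df
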