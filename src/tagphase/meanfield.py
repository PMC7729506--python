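"""Mean-field solution of the two-state model: branches, spinodals, enthalpy.

The mean-field self-consistency condition for the average pseudo-spin is

    sigma = tanh((z J sigma + H(T)) / T)          (energies in kelvin)

which can have one or three fixed points.  With three, the middle one is
unstable and the two extremal ones are the stable phase and a metastable
branch (superheated solid above T*, supercooled liquid below it).  The
temperatures at which a metastable branch merges with the unstable root —
the spinodals — bound the regions where the metastable states exist at all.

The transition is discontinuous when T* < Tc = z J, continuous (critical)
when T* = Tc, and a mere crossover when T* > Tc; only the discontinuous
case has metastable branches and a latent heat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model import GAS_CONSTANT, GEParams, ModelDomainError, field_at, tc, tstar

__all__ = [
    "Root",
    "MeanFieldSolution",
    "PhaseSummary",
    "solve_sigma",
    "free_energy_per_chain",
    "enthalpy",
    "spinodals",
    "transition_enthalpy",
    "phase_summary",
]

#: relative tolerance |T* - Tc| / Tc below which the model is classed critical
CRITICAL_RTOL = 1e-6

#: temperature resolution (kelvin) of the spinodal bisection
SPINODAL_TOL = 1e-6

_SCAN_POINTS = 2001


@dataclass(frozen=True)
class Root:
    sigma: float
    stability: str  # "stable" | "metastable" | "unstable"


@dataclass(frozen=True)
class MeanFieldSolution:
    """All fixed points of the self-consistency map at one temperature.

    ``coexistence`` is set when the two extremal roots have numerically equal
    free energy (i.e. T = T*); the positive root is then reported stable by
    convention.
    """

    T: float
    roots: tuple[Root, ...]
    coexistence: bool = False

    @property
    def stable(self) -> Root:
        return next(r for r in self.roots if r.stability == "stable")

    @property
    def metastable(self) -> Root | None:
        return next((r for r in self.roots if r.stability == "metastable"), None)


@dataclass(frozen=True)
class PhaseSummary:
    T_star: float
    T_c: float
    transition_class: str  # "discontinuous" | "critical" | "crossover"
    spinodal_low: float | None
    spinodal_high: float | None
    delta_U: float  # kJ per mole of molecule

    def to_dict(self) -> dict:
        return {
            "T_star": self.T_star,
            "T_c": self.T_c,
            "transition_class": self.transition_class,
            "spinodal_low": self.spinodal_low,
            "spinodal_high": self.spinodal_high,
            "delta_U": self.delta_U,
        }


def _fixed_points(p: GEParams, T: float) -> list[float]:
    """All solutions of sigma = tanh((zJ sigma + H)/T) on [-1, 1].

    Brackets by scanning a uniform grid, then refines by Brent's method.
    The map has at most three fixed points, so a 2001-point scan cannot
    miss a sign change except exactly at a tangency (measure zero).
    """
    a = p.z * p.J
    h = field_at(p, T)

    def g(s: float) -> float:
        return s - math.tanh((a * s + h) / T)

    grid = np.linspace(-1.0, 1.0, _SCAN_POINTS)
    vals = np.array([g(s) for s in grid])
    roots: list[float] = []
    for i in range(len(grid) - 1):
        lo, hi = vals[i], vals[i + 1]
        if lo == 0.0:
            roots.append(grid[i])
        elif lo * hi < 0.0:
            roots.append(brentq(g, grid[i], grid[i + 1], xtol=1e-14, rtol=8.9e-16))
    if vals[-1] == 0.0:
        roots.append(grid[-1])
    # merge numerically identical roots
    out: list[float] = []
    for r in sorted(roots):
        if not out or r - out[-1] > 1e-9:
            out.append(r)
    return out


def solve_sigma(p: GEParams, T: float) -> MeanFieldSolution:
    """Solve the self-consistency equation, labelling branch stability.

    With three roots the middle one is unstable (slope of the tanh map > 1);
    of the two extremal roots, the one with lower variational free energy is
    the stable phase and the other the metastable branch.  Equal free
    energies (T = T*) are reported with ``coexistence=True`` and the positive
    root labelled stable by convention.
    """
    if T <= 0:
        raise ModelDomainError(f"temperature must be > 0 K, got {T}")
    sigmas = _fixed_points(p, T)
    if len(sigmas) == 1:
        return MeanFieldSolution(T=T, roots=(Root(sigmas[0], "stable"),))
    if len(sigmas) != 3:
        raise RuntimeError(f"unexpected number of fixed points ({len(sigmas)}) at T={T}")
    lo, mid, hi = sigmas
    f_lo = free_energy_per_chain(p, T, lo)
    f_hi = free_energy_per_chain(p, T, hi)
    scale = max(abs(f_lo), abs(f_hi), 1.0)
    coexist = abs(f_lo - f_hi) <= 1e-9 * scale
    if coexist:
        stable_sigma = hi  # positive root stable by convention at coexistence
    else:
        stable_sigma = lo if f_lo < f_hi else hi
    roots = tuple(
        Root(s, "unstable" if s == mid else ("stable" if s == stable_sigma else "metastable"))
        for s in (lo, mid, hi)
    )
    return MeanFieldSolution(T=T, roots=roots, coexistence=coexist)


def _xlogx(x: float) -> float:
    return 0.0 if x <= 0.0 else x * math.log(x)


def free_energy_per_chain(p: GEParams, T: float, sigma: float) -> float:
    """Variational mean-field free energy per chain, in kelvin.

    f(sigma) = -(zJ/2) sigma^2 - H(T) sigma
               + T [ (1+sigma)/2 ln((1+sigma)/2) + (1-sigma)/2 ln((1-sigma)/2) ]

    The entropy-of-mixing term makes f stationary exactly at the fixed points
    of the tanh map, so it ranks coexisting branches consistently.
    """
    if not -1.0 <= sigma <= 1.0:
        raise ModelDomainError(f"sigma must lie in [-1, 1], got {sigma}")
    a = p.z * p.J
    h = field_at(p, T)
    entropy = -(_xlogx((1.0 + sigma) / 2.0) + _xlogx((1.0 - sigma) / 2.0))
    return -0.5 * a * sigma * sigma - h * sigma - T * entropy


def enthalpy(p: GEParams, T: float, sigma: float) -> float:
    """Enthalpy per mole of molecule on the branch ``sigma``, kJ/mol.

    Only the energy terms of the Hamiltonian count: per chain (kelvin)
    u = -(zJ/2) sigma^2 - H0 sigma.  The degeneracy term -kB T ln D is
    entropic and excluded.  Multiplying by R and the number of chains per
    molecule gives J/mol; divided by 1000 -> kJ/mol.
    """
    if not -1.0 <= sigma <= 1.0:
        raise ModelDomainError(f"sigma must lie in [-1, 1], got {sigma}")
    u_chain = -0.5 * p.z * p.J * sigma * sigma - p.H0 * sigma
    return p.chains_per_molecule * GAS_CONSTANT * u_chain / 1000.0


def _n_roots(p: GEParams, T: float) -> int:
    return len(_fixed_points(p, T))


def spinodals(p: GEParams) -> tuple[float | None, float | None]:
    """Temperatures bounding the supercooled / superheated metastable regimes.

    Returns ``(spinodal_low, spinodal_high)``: the temperatures at which the
    metastable extremal root merges with the unstable root and disappears
    (found by bisection on the 3-root -> 1-root change).  Both are ``None``
    when T* >= Tc (no discontinuity, hence no metastability).
    """
    ts = tstar(p)
    t_crit = tc(p)
    if ts >= t_crit or _n_roots(p, ts) < 3:
        return (None, None)

    def bisect(lo: float, hi: float, three_at_lo: bool) -> float:
        # invariant: root count differs between lo and hi
        while hi - lo > SPINODAL_TOL:
            mid = 0.5 * (lo + hi)
            if (_n_roots(p, mid) == 3) == three_at_lo:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    # march up from T* until the upper metastable branch is gone
    step = max(1.0, 0.01 * ts)
    hi = ts
    while _n_roots(p, hi) == 3:
        hi = min(hi + step, t_crit)
        if hi >= t_crit:
            break
    spin_high = bisect(ts, hi, True) if _n_roots(p, hi) != 3 else t_crit

    lo = ts
    while _n_roots(p, lo) == 3 and lo > SPINODAL_TOL:
        lo = max(lo - step, 0.5 * SPINODAL_TOL)
    spin_low = bisect(lo, ts, False) if _n_roots(p, lo) != 3 else lo
    return (spin_low, spin_high)


def transition_enthalpy(p: GEParams) -> float:
    """Latent heat of the transition, kJ per mole of molecule.

    Zero unless the transition is discontinuous (T* < Tc).  At T* the
    coexisting roots are +/- sigma0, so the enthalpy jump between the two
    equilibrium branches is chains * R * 2 H0 sigma0 / 1000 (the sigma^2
    terms cancel).
    """
    ts = tstar(p)
    if ts >= tc(p):
        return 0.0
    sol = solve_sigma(p, ts)
    sigma0 = max(r.sigma for r in sol.roots)
    if sigma0 <= 0:
        return 0.0
    return p.chains_per_molecule * GAS_CONSTANT * 2.0 * p.H0 * sigma0 / 1000.0


def phase_summary(p: GEParams) -> PhaseSummary:
    """Classify the transition and assemble T*, Tc, spinodals and latent heat."""
    ts = tstar(p)
    t_crit = tc(p)
    if t_crit > 0 and abs(ts - t_crit) / t_crit <= CRITICAL_RTOL:
        cls = "critical"
    elif ts < t_crit:
        cls = "discontinuous"
    else:
        cls = "crossover"
    if cls == "discontinuous":
        s_lo, s_hi = spinodals(p)
        du = transition_enthalpy(p)
    else:
        s_lo, s_hi, du = None, None, 0.0
    return PhaseSummary(
        T_star=ts,
        T_c=t_crit,
        transition_class=cls,
        spinodal_low=s_lo,
        spinodal_high=s_hi,
        delta_U=du,
    )
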