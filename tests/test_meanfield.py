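"""Mean-field branches, free energy, spinodals and the latent heat."""

import math

import numpy as np
import pytest

from tagphase import (
    GEParams,
    ModelDomainError,
    enthalpy,
    field_at,
    free_energy_per_chain,
    phase_summary,
    solve_sigma,
    spinodals,
    tc,
    transition_enthalpy,
    tstar,
)
from tagphase.model import GAS_CONSTANT


def brute_force_roots(p: GEParams, T: float, n: int = 100_000) -> list[float]:
    """Independent oracle: sign-change scan of sigma - tanh((zJ sigma + H)/T),
    each bracketing cell refined by plain bisection."""
    a, h = p.z * p.J, field_at(p, T)
    s = np.linspace(-1.0, 1.0, n)
    r = s - np.tanh((a * s + h) / T)
    idx = np.nonzero(np.sign(r[:-1]) * np.sign(r[1:]) < 0)[0]
    out = []
    for i in idx:
        lo, hi = float(s[i]), float(s[i + 1])
        f_lo = lo - math.tanh((a * lo + h) / T)
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            f_mid = mid - math.tanh((a * mid + h) / T)
            if f_lo * f_mid <= 0:
                hi = mid
            else:
                lo, f_lo = mid, f_mid
        out.append(0.5 * (lo + hi))
    # saturated roots: tanh rounds to +/-1 in floats, leaving no sign change
    if r[0] == 0.0:
        out.insert(0, -1.0)
    if r[-1] == 0.0:
        out.append(1.0)
    return out


def field_free(J: float, z: int, T_zero: float) -> GEParams:
    """Parameters whose field vanishes exactly at the probe temperature."""
    return GEParams(J=J, H0=T_zero / 2.0, ln_deg=1.0, z=z)


def test_field_free_roots_at_half_tc():
    """sigma = tanh(2 sigma) has roots {-s, 0, +s} with s ~ 0.9575."""
    p = field_free(50.0, 4, T_zero=100.0)  # Tc = 200, probe at 100
    sol = solve_sigma(p, 100.0)
    sigmas = sorted(r.sigma for r in sol.roots)
    assert sigmas[1] == pytest.approx(0.0, abs=1e-10)
    assert sigmas[2] == pytest.approx(0.95750, abs=1e-4)
    assert sigmas[0] == pytest.approx(-sigmas[2], abs=1e-10)
    mid = [r for r in sol.roots if abs(r.sigma) < 1e-8][0]
    assert mid.stability == "unstable"


def test_above_tc_single_paramagnetic_root():
    p = field_free(50.0, 4, T_zero=300.0)
    sol = solve_sigma(p, 300.0)  # T = 1.5 Tc, field zero there
    assert len(sol.roots) == 1
    assert sol.roots[0].sigma == pytest.approx(0.0, abs=1e-10)
    assert sol.roots[0].stability == "stable"


def test_low_temperature_saturation():
    p = GEParams(J=50.0, H0=100.0, ln_deg=1.0, z=4)  # H(T) > 0 at low T
    sol = solve_sigma(p, 2.0)
    assert max(r.sigma for r in sol.roots) == pytest.approx(1.0, abs=1e-6)


def test_solver_rejects_nonpositive_temperature():
    p = GEParams(J=50.0, H0=100.0, ln_deg=1.0, z=4)
    with pytest.raises(ModelDomainError):
        solve_sigma(p, 0.0)


def test_roots_satisfy_fixed_point_residual(trilaurin):
    for T in (300.0, 319.4, 322.0, 340.0):
        for r in solve_sigma(trilaurin, T).roots:
            resid = r.sigma - math.tanh((trilaurin.z * trilaurin.J * r.sigma
                                         + field_at(trilaurin, T)) / T)
            assert abs(resid) <= 1e-10


def test_root_finder_matches_brute_force_scan():
    """200 random parameter/temperature draws against the dense-scan oracle."""
    rng = np.random.default_rng(12345)
    for _ in range(200):
        p = GEParams(
            J=float(rng.uniform(5.0, 200.0)),
            H0=float(rng.uniform(10.0, 3000.0)),
            ln_deg=float(rng.uniform(0.1, 20.0)),
            z=int(rng.integers(2, 9)),
        )
        T = float(rng.uniform(0.2, 2.0) * tstar(p))
        got = sorted(r.sigma for r in solve_sigma(p, T).roots)
        want = brute_force_roots(p, T)
        assert len(got) == len(want)
        for g, w in zip(got, want):
            assert abs(g - w) <= 1e-6


def test_free_energy_stationary_at_roots():
    rng = np.random.default_rng(7)
    eps = 1e-6
    for _ in range(20):
        p = GEParams(J=float(rng.uniform(10, 150)), H0=float(rng.uniform(50, 2000)),
                     ln_deg=float(rng.uniform(0.5, 15)), z=4)
        T = float(rng.uniform(0.5, 1.5) * tstar(p))
        for r in solve_sigma(p, T).roots:
            if abs(r.sigma) > 1 - 1e-3:
                continue  # entropy-term curvature blows up the finite difference
            df = (free_energy_per_chain(p, T, r.sigma + eps)
                  - free_energy_per_chain(p, T, r.sigma - eps)) / (2 * eps)
            scale = max(abs(free_energy_per_chain(p, T, r.sigma)), 1.0)
            assert abs(df) <= 1e-4 * scale


def test_coexistence_at_tstar(trilaurin):
    """H(T*) = 0 makes the free energy even: extremal roots tie exactly."""
    ts = tstar(trilaurin)
    sol = solve_sigma(trilaurin, ts)
    assert sol.coexistence
    lo, hi = min(r.sigma for r in sol.roots), max(r.sigma for r in sol.roots)
    assert hi == pytest.approx(-lo, abs=1e-10)
    f_lo = free_energy_per_chain(trilaurin, ts, lo)
    f_hi = free_energy_per_chain(trilaurin, ts, hi)
    assert f_lo == pytest.approx(f_hi, rel=1e-10)
    assert sol.stable.sigma > 0  # positive branch stable by convention


def test_melt_branch_wins_above_tstar(trilaurin):
    sol = solve_sigma(trilaurin, tstar(trilaurin) + 0.5)
    assert sol.stable.sigma < 0
    assert sol.metastable.sigma > 0  # superheated solid


def test_enthalpy_closed_forms(trilaurin):
    assert enthalpy(trilaurin, 300.0, 0.0) == 0.0
    chains, R = trilaurin.chains_per_molecule, GAS_CONSTANT
    expect = chains * R * (-trilaurin.z * trilaurin.J / 2 - trilaurin.H0) / 1000.0
    assert enthalpy(trilaurin, 1.0, 1.0) == pytest.approx(expect, rel=1e-12)


def test_latent_heat_equals_numeric_branch_jump():
    """2 H0 sigma0 closed form vs the difference of the two enthalpy branches."""
    for p in (
        GEParams(J=100.0, H0=150.0, ln_deg=2.0, z=4),
        GEParams(J=75.7, H0=2105.4, ln_deg=13.183, z=6),
    ):
        ts = tstar(p)
        sol = solve_sigma(p, ts)
        lo = min(r.sigma for r in sol.roots)
        hi = max(r.sigma for r in sol.roots)
        jump = enthalpy(p, ts, lo) - enthalpy(p, ts, hi)
        assert transition_enthalpy(p) == pytest.approx(jump, rel=1e-6)


def test_crossover_has_no_latent_heat(toy_crossover):
    assert transition_enthalpy(toy_crossover) == 0.0
    assert spinodals(toy_crossover) == (None, None)


def test_trilaurin_spinodal_window(trilaurin):
    s_lo, s_hi = spinodals(trilaurin)
    ts = tstar(trilaurin)
    assert s_lo < ts < s_hi
    assert 5.0 <= s_hi - ts <= 10.0  # superheated extent, dense-scan verified


def test_root_count_changes_only_at_spinodals(trilaurin):
    """Scan: three roots strictly inside the spinodal window, one outside."""
    s_lo, s_hi = spinodals(trilaurin)
    for T in np.linspace(s_lo + 0.05, s_hi - 0.05, 25):
        assert len(solve_sigma(trilaurin, float(T)).roots) == 3
    for T in (s_lo - 0.05, s_hi + 0.05, s_lo - 5.0, s_hi + 5.0):
        assert len(solve_sigma(trilaurin, float(T)).roots) == 1


def test_equilibrium_enthalpy_nondecreasing(trilaurin):
    grid = np.linspace(250.0, 420.0, 120)
    u = [enthalpy(trilaurin, float(T), solve_sigma(trilaurin, float(T)).stable.sigma)
         for T in grid]
    assert all(b - a >= -1e-9 for a, b in zip(u, u[1:]))


@pytest.mark.parametrize(
    "H0, expected",
    [
        (100.0, "discontinuous"),  # T* = 100 < Tc = 200
        (400.0, "crossover"),  # T* = 400 > Tc = 200
        (200.0, "critical"),  # T* = Tc exactly
    ],
)
def test_transition_classification(H0, expected):
    p = GEParams(J=50.0, H0=H0, ln_deg=2.0, z=4)
    s = phase_summary(p)
    assert s.transition_class == expected
    if expected == "discontinuous":
        assert s.spinodal_low < s.T_star < s.spinodal_high
        assert s.delta_U > 0
    else:
        assert s.delta_U == 0.0
        assert s.spinodal_low is None and s.spinodal_high is None
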