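"""Metropolis dynamics against exact enumeration; hysteresis; MC lifetimes."""

import itertools
import math

import numpy as np
import pytest

from tagphase import (
    GEParams,
    MCConfig,
    ModelDomainError,
    RampSchedule,
    enumerate_exact,
    estimate_lifetime_mc,
    field_at,
    hysteresis_ramp,
    loop_area,
    metropolis,
    spinodals,
    tstar,
)


def hand_enumerate_2x2_square(p: GEParams, T: float) -> float:
    """Independent 2x2 oracle: explicit 16-state sum with doubled periodic bonds."""
    bonds = [(0, 1), (0, 1), (2, 3), (2, 3), (0, 2), (0, 2), (1, 3), (1, 3)]
    h = field_at(p, T)
    num = den = 0.0
    for s in itertools.product((-1, 1), repeat=4):
        e = -p.J * sum(s[i] * s[j] for i, j in bonds) - h * sum(s)
        w = math.exp(-e / T)
        num += w * sum(s) / 4.0
        den += w
    return num / den


def test_enumeration_matches_hand_coded_2x2():
    p = GEParams(J=50.0, H0=100.0, ln_deg=1.0, z=4)
    for T in (150.0, 200.0, 250.0):
        ms, _ = enumerate_exact(p, "square", 2, T)
        assert ms == pytest.approx(hand_enumerate_2x2_square(p, T), rel=1e-12, abs=1e-12)


@pytest.mark.parametrize("lattice, side", [("square", 2), ("square", 3), ("square", 4),
                                           ("triangular", 2), ("triangular", 3),
                                           ("triangular", 4)])
def test_enumeration_symmetric_at_tstar(lattice, side):
    """H(T*) = 0 leaves the energy flip-invariant: <sigma> = 0 exactly."""
    z = {"square": 4, "triangular": 6}[lattice]
    for p in (
        GEParams(J=50.0, H0=100.0, ln_deg=1.0, z=z),
        GEParams(J=10.0, H0=500.0, ln_deg=4.0, z=z),
    ):
        ms, _ = enumerate_exact(p, lattice, side, tstar(p))
        assert ms == pytest.approx(0.0, abs=1e-12)


def test_independent_spins_have_closed_form_mean():
    """J = 0 decouples the sites: <sigma> = tanh(H(T)/T) per site exactly."""
    p = GEParams(J=0.0, H0=100.0, ln_deg=1.0, z=4)
    for T in (100.0, 300.0):
        ms, _ = enumerate_exact(p, "square", 3, T)
        assert ms == pytest.approx(math.tanh(field_at(p, T) / T), rel=1e-12)


def test_enumeration_site_limit():
    p = GEParams(J=50.0, H0=100.0, ln_deg=1.0, z=4)
    with pytest.raises(ModelDomainError, match="20 sites"):
        enumerate_exact(p, "square", 5, 200.0)


def test_lattice_coordination_must_match_model():
    p = GEParams(J=50.0, H0=100.0, ln_deg=1.0, z=6)
    with pytest.raises(ModelDomainError, match="z"):
        enumerate_exact(p, "square", 3, 200.0)
    with pytest.raises(ModelDomainError, match="z"):
        metropolis(p, MCConfig(lattice="square", side=3, sweeps=10, seed=0, T=200.0))


@pytest.mark.parametrize("side, sweeps", [(2, 12000), (3, 20000)])
def test_metropolis_matches_enumeration(side, sweeps):
    """Block-averaged magnetization within 3 s.e. of the exact average."""
    p = GEParams(J=50.0, H0=100.0, ln_deg=1.0, z=4)
    for T in (230.0, 250.0, 280.0):
        exact, _ = enumerate_exact(p, "square", side, T)
        cfg = MCConfig(lattice="square", side=side, sweeps=sweeps, seed=99, T=T,
                       block_sweeps=500)
        res = metropolis(p, cfg)
        m = res.magnetization[4:]  # drop equilibration blocks
        se = m.std(ddof=1) / np.sqrt(len(m))
        assert abs(m.mean() - exact) <= 3 * se + 1e-12


def test_metropolis_deterministic_under_seed():
    p = GEParams(J=50.0, H0=100.0, ln_deg=1.0, z=4)
    cfg = MCConfig(lattice="square", side=4, sweeps=500, seed=7, T=220.0)
    a = metropolis(p, cfg)
    b = metropolis(p, cfg)
    assert a.blocks.equals(b.blocks)


def test_deep_ordered_phase_stays_magnetized():
    p = GEParams(J=50.0, H0=100.0, ln_deg=1.0, z=4)
    cfg = MCConfig(lattice="square", side=8, sweeps=500, seed=1, T=20.0)
    res = metropolis(p, cfg)
    assert res.magnetization[-1] > 0.99


def test_hysteresis_loop_opens_for_discontinuous(toy_discontinuous):
    """Fast ramps across T* = 150 K superheat/supercool: positive loop area."""
    areas, superheated = [], 0
    for seed in range(3):
        ramp = RampSchedule(T_start=120.0, T_end=185.0, dT_per_block=2.5,
                            sweeps_per_block=15)
        cfg = MCConfig(lattice="square", side=10, sweeps=1, seed=seed, ramp=ramp)
        heat, cool = hysteresis_ramp(toy_discontinuous, cfg)
        areas.append(loop_area(heat, cool))
        # superheating: the solid branch can survive just above T*
        hb = heat.blocks
        superheated += hb[hb["T_K"] > 150.0].iloc[0]["m"] > 0.0
    assert np.mean(areas) > 1.0
    assert superheated >= 2  # most fast heating runs overshoot the transition


def test_crossover_loop_area_near_zero(toy_crossover):
    areas = []
    for seed in range(3):
        ramp = RampSchedule(T_start=250.0, T_end=350.0, dT_per_block=2.5,
                            sweeps_per_block=300)
        cfg = MCConfig(lattice="square", side=10, sweeps=1, seed=seed, ramp=ramp)
        heat, cool = hysteresis_ramp(toy_crossover, cfg)
        areas.append(loop_area(heat, cool))
    assert abs(np.mean(areas)) < 1.0


def test_slower_ramp_shrinks_the_loop(toy_discontinuous):
    """Paired seeds: more sweeps per block -> smaller loop area on average."""
    fast, slow = [], []
    for seed in range(4):
        for spb, acc in ((15, fast), (150, slow)):
            ramp = RampSchedule(T_start=120.0, T_end=185.0, dT_per_block=2.5,
                                sweeps_per_block=spb)
            cfg = MCConfig(lattice="square", side=10, sweeps=1, seed=seed, ramp=ramp)
            acc.append(loop_area(*hysteresis_ramp(toy_discontinuous, cfg)))
    assert np.mean(slow) <= np.mean(fast)


def test_mc_lifetime_nonincreasing_in_temperature(toy_discontinuous):
    """Deeper superheating decays faster, mirroring the VFT shape."""
    _, s_hi = spinodals(toy_discontinuous)
    temps = [s_hi - 8.0, s_hi - 5.0, s_hi - 2.0]
    means = []
    for T in temps:
        est = estimate_lifetime_mc(toy_discontinuous, T, replicas=12, max_sweeps=4000,
                                   seed=3, lattice="square", side=8)
        # censored replicas enter at the censoring bound (conservative)
        means.append(float(est.times.mean()))
    assert means[0] >= means[1] >= means[2]
    assert means[0] > means[2]


def test_mc_lifetime_domain_checks(toy_discontinuous, toy_crossover):
    _, s_hi = spinodals(toy_discontinuous)
    with pytest.raises(ModelDomainError, match="replicas"):
        estimate_lifetime_mc(toy_discontinuous, s_hi - 5.0, replicas=0, max_sweeps=10,
                             seed=0, lattice="square", side=4)
    for T in (140.0, s_hi + 5.0):
        with pytest.raises(ModelDomainError, match="superheated window"):
            estimate_lifetime_mc(toy_discontinuous, T, replicas=2, max_sweeps=10,
                                 seed=0, lattice="square", side=4)
    with pytest.raises(ModelDomainError, match="superheated window"):
        estimate_lifetime_mc(toy_crossover, 250.0, replicas=2, max_sweeps=10,
                             seed=0, lattice="square", side=4)
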