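"""Metropolis Monte Carlo realization of the pseudo-spin Hamiltonian.

The effective energy on a periodic lattice is (per distinct nearest-
neighbour bond, energies in kelvin)

    E = -J * sum_bonds sigma_i sigma_j - H(T) * sum_i sigma_i,

the pair sum written so that the mean-field limit gives Tc = z J.  The
module provides single-site Metropolis dynamics (one sweep = N attempted
flips at uniformly random sites), an exact-enumeration oracle for lattices
of at most 20 sites, heating/cooling temperature ramps exhibiting
hysteresis when the transition is discontinuous, and first-passage
estimation of the superheated-state lifetime in sweeps.

Lattices: "square" (z = 4) and "triangular" (z = 6, the natural choice for
hexagonally packed hydrocarbon chains), both with periodic boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .meanfield import spinodals
from .model import GEParams, ModelDomainError, field_at, tstar

__all__ = [
    "LATTICE_Z",
    "MCConfig",
    "RampSchedule",
    "MCResult",
    "LifetimeEstimate",
    "enumerate_exact",
    "metropolis",
    "hysteresis_ramp",
    "loop_area",
    "estimate_lifetime_mc",
]

LATTICE_Z = {"square": 4, "triangular": 6}

try:  # the sweep kernel is hot; compile it when numba is importable
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@dataclass(frozen=True)
class RampSchedule:
    """Linear temperature protocol: blocks of ``sweeps_per_block`` sweeps at
    temperatures stepping by ``dT_per_block`` from ``T_start`` to ``T_end``."""

    T_start: float
    T_end: float
    dT_per_block: float
    sweeps_per_block: int

    def temperatures(self) -> np.ndarray:
        if self.dT_per_block <= 0:
            raise ModelDomainError("dT_per_block must be > 0")
        lo, hi = sorted((self.T_start, self.T_end))
        n = int(round((hi - lo) / self.dT_per_block)) + 1
        grid = lo + self.dT_per_block * np.arange(n)
        return grid if self.T_end >= self.T_start else grid[::-1]


@dataclass(frozen=True)
class MCConfig:
    lattice: str
    side: int
    sweeps: int
    seed: int
    T: float | None = None
    ramp: RampSchedule | None = None
    block_sweeps: int = 100

    def __post_init__(self) -> None:
        if self.lattice not in LATTICE_Z:
            raise ModelDomainError(f"lattice must be one of {sorted(LATTICE_Z)}")
        if self.side < 2:
            raise ModelDomainError("side must be >= 2")
        if self.sweeps < 1 or self.block_sweeps < 1:
            raise ModelDomainError("sweeps and block_sweeps must be >= 1")
        if (self.T is None) == (self.ramp is None):
            raise ModelDomainError("exactly one of T or ramp must be given")


@dataclass
class MCResult:
    """Per-block trajectory (block index, temperature, mean magnetization,
    mean energy per site in kelvin, acceptance rate) plus protocol metadata."""

    blocks: pd.DataFrame
    protocol: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def magnetization(self) -> np.ndarray:
        return self.blocks["m"].to_numpy()


@dataclass(frozen=True)
class LifetimeEstimate:
    """First-passage sweeps of the superheated state over replicas."""

    times: np.ndarray  # first-passage sweeps (max_sweeps where censored)
    censored: np.ndarray  # True where the run never decayed
    mean: float  # mean over uncensored replicas (nan if none)
    se: float  # standard error of that mean
    n_censored: int


def _bonds(lattice: str, side: int) -> np.ndarray:
    """Distinct-bond list (n_bonds, 2) built from directed offsets.

    Offsets right/down (+ one diagonal for the triangular lattice) emitted
    from every site cover each periodic bond once for side >= 3; for
    side = 2 the wrap makes each bond appear twice, which is the standard
    doubled-bond convention for tiny periodic lattices and is used
    consistently by the enumerator and the Metropolis kernel.
    """
    offsets = [(0, 1), (1, 0)]
    if lattice == "triangular":
        offsets.append((1, 1))
    pairs = []
    for r in range(side):
        for c in range(side):
            i = r * side + c
            for dr, dc in offsets:
                j = ((r + dr) % side) * side + (c + dc) % side
                pairs.append((i, j))
    return np.asarray(pairs, dtype=np.int64)


def _neighbors(bonds: np.ndarray, n_sites: int, z: int) -> np.ndarray:
    """(N, z) incident-neighbour table; bond multiplicity is preserved."""
    lists: list[list[int]] = [[] for _ in range(n_sites)]
    for i, j in bonds:
        lists[i].append(j)
        lists[j].append(i)
    out = np.asarray(lists, dtype=np.int64)
    if out.shape != (n_sites, z):
        raise RuntimeError("neighbour table does not match coordination number")
    return out


def _check_lattice(p: GEParams, lattice: str) -> None:
    if LATTICE_Z[lattice] != p.z:
        raise ModelDomainError(
            f"lattice {lattice!r} has z = {LATTICE_Z[lattice]} but the model has z = {p.z}"
        )


def _energy(spins: np.ndarray, bonds: np.ndarray, J: float, h: float) -> float:
    pair = int(np.sum(spins[bonds[:, 0]] * spins[bonds[:, 1]]))
    return -J * pair - h * int(spins.sum())


def enumerate_exact(
    p: GEParams, lattice: str, side: int, T: float
) -> tuple[float, float]:
    """Exact Boltzmann averages (<sigma>, <E>/N) by summing all 2^N states.

    Limited to side^2 <= 20 sites.  At T = T* the field vanishes and the
    energy is invariant under a global spin flip, so <sigma> = 0 exactly.
    """
    _check_lattice(p, lattice)
    n = side * side
    if n > 20:
        raise ModelDomainError(f"exact enumeration limited to 20 sites, got {n}")
    if T <= 0:
        raise ModelDomainError("temperature must be > 0 K")
    h = field_at(p, T)
    bonds = _bonds(lattice, side)
    states = np.arange(1 << n, dtype=np.uint32)
    spins = (((states[:, None] >> np.arange(n, dtype=np.uint32)) & 1).astype(np.int8) * 2 - 1)
    pair = np.zeros(1 << n, dtype=np.int32)
    for i, j in bonds:
        pair += spins[:, i].astype(np.int32) * spins[:, j]
    mag = spins.sum(axis=1, dtype=np.int32)
    energy = -p.J * pair - h * mag
    w = np.exp(-(energy - energy.min()) / T)
    zsum = w.sum()
    mean_sigma = float((w @ (mag / n)) / zsum)
    mean_e = float((w @ energy) / zsum) / n
    return mean_sigma, mean_e


@njit(cache=False)
def _sweep_kernel(spins, neigh, J, h, T, sweeps, sites, us, e0):  # pragma: no cover
    n = spins.shape[0]
    z = neigh.shape[1]
    m_sweep = np.empty(sweeps)
    e_sweep = np.empty(sweeps)
    mag = 0
    for i in range(n):
        mag += spins[i]
    e = e0
    acc = 0
    k = 0
    for s in range(sweeps):
        for _ in range(n):
            i = sites[k]
            u = us[k]
            k += 1
            nn = 0
            for q in range(z):
                nn += spins[neigh[i, q]]
            dE = 2.0 * spins[i] * (J * nn + h)
            if dE <= 0.0 or u < math.exp(-dE / T):
                spins[i] = -spins[i]
                mag += 2 * spins[i]
                e += dE
                acc += 1
        m_sweep[s] = mag / n
        e_sweep[s] = e / n
    return m_sweep, e_sweep, acc


def _run_block(
    spins: np.ndarray,
    neigh: np.ndarray,
    bonds: np.ndarray,
    J: float,
    h: float,
    T: float,
    sweeps: int,
    rng: np.random.Generator,
) -> tuple[float, float, float]:
    n = spins.shape[0]
    sites = rng.integers(0, n, size=sweeps * n)
    us = rng.random(sweeps * n)
    e0 = _energy(spins, bonds, J, h)
    m_sweep, e_sweep, acc = _sweep_kernel(
        spins, neigh, J, h, T, sweeps, sites, us, e0
    )
    return float(m_sweep.mean()), float(e_sweep.mean()), acc / (sweeps * n)


def metropolis(p: GEParams, cfg: MCConfig) -> MCResult:
    """Fixed-temperature Metropolis run; reproducible from the seed.

    Starts from the all-ordered (sigma = +1) configuration and records
    block averages (``cfg.block_sweeps`` sweeps per block).
    """
    if cfg.T is None:
        raise ModelDomainError("metropolis requires a fixed temperature (cfg.T)")
    if cfg.T <= 0:
        raise ModelDomainError("temperature must be > 0 K")
    _check_lattice(p, cfg.lattice)
    n = cfg.side * cfg.side
    bonds = _bonds(cfg.lattice, cfg.side)
    neigh = _neighbors(bonds, n, p.z)
    spins = np.ones(n, dtype=np.int8)
    rng = np.random.default_rng(cfg.seed)
    h = field_at(p, cfg.T)
    rows = []
    n_blocks = max(cfg.sweeps // cfg.block_sweeps, 1)
    for b in range(n_blocks):
        m, e, acc = _run_block(spins, neigh, bonds, p.J, h, cfg.T, cfg.block_sweeps, rng)
        rows.append((b, cfg.T, m, e, acc))
    blocks = pd.DataFrame(rows, columns=["block", "T_K", "m", "E_per_site_K", "acc_rate"])
    return MCResult(
        blocks=blocks,
        protocol={"kind": "fixed_T", "lattice": cfg.lattice, "side": cfg.side,
                  "sweeps": cfg.sweeps, "block_sweeps": cfg.block_sweeps},
        seed=cfg.seed,
    )


def _ramp_branch(
    p: GEParams, cfg: MCConfig, temps: np.ndarray, start_spin: int, rng: np.random.Generator
) -> pd.DataFrame:
    n = cfg.side * cfg.side
    bonds = _bonds(cfg.lattice, cfg.side)
    neigh = _neighbors(bonds, n, p.z)
    spins = np.full(n, start_spin, dtype=np.int8)
    rows = []
    for b, T in enumerate(temps):
        h = field_at(p, float(T))
        m, e, acc = _run_block(
            spins, neigh, bonds, p.J, h, float(T), cfg.ramp.sweeps_per_block, rng
        )
        rows.append((b, float(T), m, e, acc))
    return pd.DataFrame(rows, columns=["block", "T_K", "m", "E_per_site_K", "acc_rate"])


def hysteresis_ramp(p: GEParams, cfg: MCConfig) -> tuple[MCResult, MCResult]:
    """Heating and cooling branches of a temperature ramp.

    Heating starts from the all-solid state (sigma = +1) at the cold end,
    cooling from the all-melt state (sigma = -1) at the hot end.  Across a
    discontinuous transition the branches open into a hysteresis loop
    (superheating/supercooling); for a crossover they coincide on average.
    """
    if cfg.ramp is None:
        raise ModelDomainError("hysteresis_ramp requires a ramp schedule")
    _check_lattice(p, cfg.lattice)
    grid = cfg.ramp.temperatures()
    ascending = np.sort(grid)
    rng_heat = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    rng_cool = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    heat = _ramp_branch(p, cfg, ascending, +1, rng_heat)
    cool = _ramp_branch(p, cfg, ascending[::-1], -1, rng_cool)
    meta = {"kind": "ramp", "lattice": cfg.lattice, "side": cfg.side,
            "sweeps_per_block": cfg.ramp.sweeps_per_block,
            "dT_per_block": cfg.ramp.dT_per_block}
    return (
        MCResult(blocks=heat, protocol={**meta, "branch": "heating"}, seed=cfg.seed),
        MCResult(blocks=cool, protocol={**meta, "branch": "cooling"}, seed=cfg.seed),
    )


def loop_area(heating: MCResult, cooling: MCResult) -> float:
    """Hysteresis loop area integral of (m_heat - m_cool) dT, kelvin."""
    h = heating.blocks.sort_values("T_K")
    c = cooling.blocks.sort_values("T_K")
    if not np.allclose(h["T_K"].to_numpy(), c["T_K"].to_numpy()):
        raise ValueError("heating and cooling branches use different temperature grids")
    t = h["T_K"].to_numpy()
    return float(np.trapezoid(h["m"].to_numpy() - c["m"].to_numpy(), t))


def estimate_lifetime_mc(
    p: GEParams,
    T: float,
    replicas: int,
    max_sweeps: int,
    seed: int,
    lattice: str = "triangular",
    side: int = 8,
    block_sweeps: int = 10,
) -> LifetimeEstimate:
    """First-passage lifetime (sweeps) of the superheated metastable state.

    Each replica starts all-solid (sigma = +1) at temperature T inside the
    superheated window (T*, spinodal_high) and runs until a block-mean
    magnetization drops to <= 0; runs that survive ``max_sweeps`` are
    reported censored.  Per-replica streams are spawned from the master seed
    so replica sets are reproducible.
    """
    if lattice is not None:
        _check_lattice(p, lattice)
    if replicas < 1:
        raise ModelDomainError("replicas must be >= 1")
    ts = tstar(p)
    s_lo, s_hi = spinodals(p)
    if s_hi is None or not ts < T < s_hi:
        raise ModelDomainError(
            f"T = {T} K is outside the superheated window (T* = {ts:.6g} K, "
            f"spinodal_high = {s_hi if s_hi is not None else 'absent'})"
        )
    n = side * side
    bonds = _bonds(lattice, side)
    neigh = _neighbors(bonds, n, p.z)
    h = field_at(p, T)
    streams = np.random.SeedSequence(seed).spawn(replicas)
    times = np.empty(replicas)
    censored = np.zeros(replicas, dtype=bool)
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        spins = np.ones(n, dtype=np.int8)
        swept = 0
        decayed = False
        while swept < max_sweeps:
            nb = min(block_sweeps, max_sweeps - swept)
            m, _, _ = _run_block(spins, neigh, bonds, p.J, h, T, nb, rng)
            swept += nb
            if m <= 0.0:
                decayed = True
                break
        times[r] = swept
        censored[r] = not decayed
    obs = times[~censored]
    if obs.size:
        mean = float(obs.mean())
        se = float(obs.std(ddof=1) / math.sqrt(obs.size)) if obs.size > 1 else math.nan
    else:
        mean, se = math.nan, math.nan
    return LifetimeEstimate(
        times=times, censored=censored, mean=mean, se=se,
        n_censored=int(censored.sum()),
    )
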