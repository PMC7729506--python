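"""Synthetic holding time-temperature "memory" datasets.

Laboratory memory studies hold a melt at a temperature above T* for some
time and then cool it, recording whether the original crystal form
reappears ("memory persists") or not ("memory is lost").  The published
datasets of this kind exist only as figures, so this module generates
labelled datasets with the same statistical structure: a convex,
decreasing persists/lost boundary in the T > T* half-plane, holding times
log-spaced over decades, and multiplicative lognormal scatter of the true
lifetime (times span decades, so noise is symmetric on the log scale).

Everything is deterministic under the generator seed, which makes the
generator usable both as a fixture factory and for parameter-recovery
simulation studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .meanfield import enthalpy, solve_sigma
from .model import GEParams, ModelDomainError
from .vft import MemoryPoint, VFTParams, lifetime

__all__ = ["GeneratorSpec", "gen_memory_dataset", "gen_meanfield_fixture"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Design of a synthetic memory experiment.

    vft : generating lifetime curve
    T_grid : holding temperatures, kelvin, all above vft.T_star
    times_per_T : candidate holding times per temperature
    time_range : (min, max) minutes; candidates are log-spaced across it
    noise_sigma : lognormal sigma applied to the true lifetime per temperature
    seed : RNG seed
    """

    vft: VFTParams
    T_grid: tuple[float, ...]
    times_per_T: int
    time_range: tuple[float, float]
    noise_sigma: float
    seed: int

    def __post_init__(self) -> None:
        lo, hi = self.time_range
        if lo <= 0 or hi <= lo:
            raise ModelDomainError("time_range must satisfy 0 < min < max")
        if any(T <= self.vft.T_star for T in self.T_grid):
            raise ModelDomainError("all holding temperatures must exceed T_star")
        if self.times_per_T < 1:
            raise ModelDomainError("times_per_T must be >= 1")
        if self.noise_sigma < 0:
            raise ModelDomainError("noise_sigma must be >= 0")


def gen_memory_dataset(gs: GeneratorSpec) -> list[MemoryPoint]:
    """Labelled holding observations from a known lifetime curve.

    For each temperature one effective lifetime is drawn,
    tau_eff = tau(T) * exp(noise_sigma * N(0,1)), and every candidate time t
    is labelled "persists" if t < tau_eff, else "lost".  With zero noise the
    labels are exactly separated by the generating curve, and per
    temperature all "persists" times precede all "lost" times.
    """
    rng = np.random.default_rng(gs.seed)
    times = np.geomspace(gs.time_range[0], gs.time_range[1], gs.times_per_T)
    points: list[MemoryPoint] = []
    for T in gs.T_grid:
        tau_eff = lifetime(gs.vft, T) * float(np.exp(gs.noise_sigma * rng.standard_normal()))
        for t in times:
            label = "persists" if t < tau_eff else "lost"
            points.append(MemoryPoint(T=float(T), holding_time=float(t), label=label))
    return points


def gen_meanfield_fixture(p: GEParams, T_grid) -> pd.DataFrame:
    """Branchwise (T, sigma, stability, U) table for regression fixtures.

    One row per mean-field root per temperature; deterministic, so
    regenerating with the same parameters is bit-identical.
    """
    rows = []
    for T in T_grid:
        sol = solve_sigma(p, float(T))
        for root in sol.roots:
            rows.append(
                (float(T), root.sigma, root.stability, enthalpy(p, float(T), root.sigma))
            )
    return pd.DataFrame(rows, columns=["T_K", "sigma", "stability", "U_kJ_mol"])
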