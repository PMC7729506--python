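"""Chain-length scaling of the two-state model parameters.

For saturated hydrocarbon chains of length L (carbons), to leading order
the dispersion coupling grows linearly, J = JC + J0 L (JC is the
electrostatic glycerol-core contribution), the excited-chain energy is
Ee = E0 L and the excited-state degeneracy is De = De0(L) * 3^L, with the
step convention De0(0) = 1, De0(L > 0) = D0.  A glycerol-core degeneracy
DC multiplies De.  This gives

    Tc(L) = z (JC + J0 L)
    T*(L) = [ (z/2)(JC + J0 L) + E0 L ] / [ L ln 3 + ln(DC De0(L)) ]

so the ratio Tc/T* vanishes as L -> 0 (with DC = 1) and grows linearly
without bound as L -> infinity: short chains cross over smoothly while long
chains melt discontinuously, with a critical chain length in between.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy.optimize import brentq

from .model import GEParams, ModelDomainError

__all__ = [
    "ChainLengthParams",
    "params_of_length",
    "ratio_tc_tstar",
    "critical_length",
]

_LN3 = math.log(3.0)


@dataclass(frozen=True)
class ChainLengthParams:
    """Chain-length parameterization of the model.

    L : chain length in carbons (real-valued so limits can be probed)
    JC : glycerol-core (Keesom/Debye electrostatic) coupling, kelvin
    J0 : dispersion coupling per unit chain length, kelvin
    E0 : excited-chain energy per unit length, kelvin
    D0 : per-chain degeneracy prefactor for L > 0 (>= 1)
    DC : glycerol-core degeneracy (>= 1)
    z  : coordination number
    """

    L: float
    JC: float
    J0: float
    E0: float
    D0: float = 1.0
    DC: float = 1.0
    z: int = 6

    def __post_init__(self) -> None:
        if self.L < 0:
            raise ModelDomainError(f"chain length must be >= 0, got {self.L}")
        for name in ("JC", "J0", "E0"):
            if getattr(self, name) < 0:
                raise ModelDomainError(f"{name} must be >= 0")
        if self.D0 < 1 or self.DC < 1:
            raise ModelDomainError("degeneracies D0, DC must be >= 1")
        if int(self.z) != self.z or self.z < 1:
            raise ModelDomainError(f"coordination z must be a positive integer, got {self.z}")

    def to_dict(self) -> dict:
        return {
            "L": self.L, "JC": self.JC, "J0": self.J0, "E0": self.E0,
            "D0": self.D0, "DC": self.DC, "z": int(self.z),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChainLengthParams":
        known = {"L", "JC", "J0", "E0", "D0", "DC", "z"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown ChainLengthParams keys: {sorted(unknown)}")
        return cls(**d)


def _de0(cp: ChainLengthParams) -> float:
    # exact step: a zero-length chain has a single state
    return 1.0 if cp.L == 0 else cp.D0


def _ln_deg(cp: ChainLengthParams) -> float:
    return cp.L * _LN3 + math.log(cp.DC * _de0(cp))


def params_of_length(cp: ChainLengthParams, chains_per_molecule: int = 3) -> GEParams:
    """Model parameters for a chain of length L.

    J = JC + J0 L; ln(De/Dg) = L ln 3 + ln(DC De0(L)); H0 = (z/4) J + E0 L / 2,
    chosen so that T* = 2 H0 / ln(De/Dg) reproduces the chain-length formula
    for T* exactly.
    """
    ln_deg = _ln_deg(cp)
    if ln_deg <= 0:
        raise ModelDomainError(
            "no spin-reorientation temperature: excited-state degeneracy equals "
            "the ground state (L = 0 with DC = 1)"
        )
    J = cp.JC + cp.J0 * cp.L
    H0 = 0.25 * cp.z * J + 0.5 * cp.E0 * cp.L
    return GEParams(J=J, H0=H0, ln_deg=ln_deg, z=cp.z,
                    chains_per_molecule=chains_per_molecule)


def ratio_tc_tstar(cp: ChainLengthParams) -> float:
    """The dimensionless ratio Tc / T* as a function of chain length.

        Tc/T* = z (JC + J0 L) [ L ln 3 + ln(DC De0(L)) ]
                / [ (z/2)(JC + J0 L) + E0 L ]

    -> 0 as L -> 0 (DC = 1) and ~ L at large L.
    """
    if cp.L <= 0 and cp.DC <= 1:
        raise ModelDomainError("Tc/T* undefined at L = 0 with DC = 1 (no T*)")
    J = cp.JC + cp.J0 * cp.L
    denom = 0.5 * cp.z * J + cp.E0 * cp.L
    if denom <= 0:
        raise ModelDomainError("degenerate parameters: (z/2)J + E0 L must be > 0")
    return cp.z * J * _ln_deg(cp) / denom


def critical_length(cp: ChainLengthParams, L_lo: float, L_hi: float) -> float:
    """Chain length at which Tc = T* (the transition becomes critical).

    Bisects ``ratio_tc_tstar - 1`` on [L_lo, L_hi]; raises if the ratio does
    not cross 1 on the bracket.  Below the returned length the transition is
    a crossover, above it discontinuous.
    """

    def f(L: float) -> float:
        return ratio_tc_tstar(replace(cp, L=L)) - 1.0

    f_lo, f_hi = f(L_lo), f(L_hi)
    if f_lo == 0.0:
        return L_lo
    if f_hi == 0.0:
        return L_hi
    if f_lo * f_hi > 0:
        raise ModelDomainError(
            f"no critical length in range [{L_lo}, {L_hi}]: "
            f"Tc/T* - 1 is {f_lo:.3g} and {f_hi:.3g} at the endpoints"
        )
    return brentq(f, L_lo, L_hi, xtol=1e-13, rtol=8.9e-16)
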