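"""Reduced two-state (g-e) model of a saturated hydrocarbon-chain system.

Each chain of a triacylglycerol (TAG) molecule is reduced to an effective
ground state ``g`` (ordered, extended conformers) and an effective excited
state ``e`` (melted, highly degenerate conformers).  Mapping the two states
onto a pseudo-spin sigma = +1 (g) / -1 (e) turns the system into an Ising
model in a temperature-dependent field

    H(T) = H0 - (T / 2) * ln(De / Dg),

where ``De/Dg`` is the degeneracy ratio of the two effective states.  The
field changes sign at the spin-reorientation (melting) temperature
T* = 2 H0 / ln(De/Dg); the mean-field critical temperature is Tc = z J.

Units: every energy is stored divided by the Boltzmann constant, i.e. in
kelvin.  Molar quantities are recovered by multiplying by the gas constant
R and the number of chains per molecule (three for a TAG).  The ground
state conventions Eg = 0, Dg = 1 fix the zero of energy, so only the ratio
``ln_deg = ln(De/Dg)`` is stored.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "GAS_CONSTANT",
    "GEParams",
    "ModelDomainError",
    "field_at",
    "tstar",
    "tc",
]

#: Gas constant in J mol^-1 K^-1; converts kelvin-energies to molar energies.
GAS_CONSTANT = 8.314


class ModelDomainError(ValueError):
    """A physically meaningless input (e.g. negative temperature)."""


@dataclass(frozen=True)
class GEParams:
    """Parameters of the reduced two-state model.

    Parameters
    ----------
    J :
        Nearest-neighbour chain-chain coupling, kelvin.  Attractive
        (dispersion) interactions give ``J >= 0``.
    H0 :
        Zero-temperature field energy scale, kelvin.
    ln_deg :
        ``ln(De/Dg) > 0`` — the excited state is the more degenerate one.
    z :
        Coordination number: average number of nearest-neighbour chains.
    chains_per_molecule :
        Chains per molecule; 3 for a triacylglycerol.
    """

    J: float
    H0: float
    ln_deg: float
    z: int
    chains_per_molecule: int = 3

    def __post_init__(self) -> None:
        if self.J < 0:
            raise ModelDomainError(f"coupling J must be >= 0, got {self.J}")
        if self.ln_deg <= 0:
            raise ModelDomainError(
                f"ln_deg must be > 0 (excited state more degenerate), got {self.ln_deg}"
            )
        if int(self.z) != self.z or self.z < 1:
            raise ModelDomainError(f"coordination z must be a positive integer, got {self.z}")
        if int(self.chains_per_molecule) != self.chains_per_molecule or self.chains_per_molecule < 1:
            raise ModelDomainError(
                f"chains_per_molecule must be a positive integer, got {self.chains_per_molecule}"
            )

    def to_dict(self) -> dict:
        return {
            "J": self.J,
            "H0": self.H0,
            "ln_deg": self.ln_deg,
            "z": int(self.z),
            "chains_per_molecule": int(self.chains_per_molecule),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GEParams":
        known = {"J", "H0", "ln_deg", "z", "chains_per_molecule"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown GEParams keys: {sorted(unknown)}")
        return cls(**d)


def field_at(p: GEParams, T: float) -> float:
    """Temperature-dependent field H(T) = H0 - (T/2) ln(De/Dg), in kelvin.

    Linear and strictly decreasing in T; its unique zero is ``tstar(p)``.
    """
    if T < 0:
        raise ModelDomainError(f"temperature must be >= 0 K, got {T}")
    return p.H0 - 0.5 * T * p.ln_deg


def tstar(p: GEParams) -> float:
    """Spin-reorientation (solid-liquid transition) temperature T* = 2 H0 / ln(De/Dg).

    This is the temperature at which the effective field changes sign; it
    requires ``H0 > 0`` (otherwise the field never changes sign on T >= 0).
    """
    if p.H0 <= 0:
        raise ModelDomainError("H0 must be > 0 for the field to change sign")
    return 2.0 * p.H0 / p.ln_deg


def tc(p: GEParams) -> float:
    """Mean-field critical temperature Tc = z J (kelvin units absorb kB)."""
    return p.z * p.J
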