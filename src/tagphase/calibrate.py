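"""Trilaurin calibration: from latent heat and melting point to parameters.

Given a transition temperature T* and a molar transition enthalpy ΔU, the
model parameters follow in closed form.  The degeneracy ratio of a chain
of L carbons is ln(De/Dg) = L ln 3 + ln(DC D0); the field scale inverts
the T* relation, H0 = T* ln(De/Dg) / 2; the order parameter at the
transition inverts the enthalpy jump, sigma0 = ΔU / (chains * R * 2 H0);
and the coupling inverts the field-free fixed-point condition at T*,
J = T* atanh(sigma0) / (z sigma0).

The defaults target trilaurin (LLL, L = 12): ΔU = 86.7 kJ/mol and the
beta-polymorph melting point T* = 319.4 K (an external physical constant,
configurable).  Because atanh(s) > s on (0, 1), any valid calibration lands
in the discontinuous regime z J > T* automatically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .meanfield import transition_enthalpy
from .model import GAS_CONSTANT, GEParams, ModelDomainError

__all__ = ["CalibrationInput", "calibrate", "implied_E0"]

_LN3 = math.log(3.0)


@dataclass(frozen=True)
class CalibrationInput:
    T_star: float = 319.4  # kelvin; trilaurin beta melting point
    delta_U: float = 86.7  # kJ per mole of molecule
    L: float = 12.0
    z: int = 6
    chains_per_molecule: int = 3
    D0: float = 1.0
    DC: float = 1.0

    def __post_init__(self) -> None:
        if min(self.T_star, self.delta_U, self.L) <= 0:
            raise ModelDomainError("T_star, delta_U and L must be > 0")
        if self.D0 < 1 or self.DC < 1:
            raise ModelDomainError("degeneracies D0, DC must be >= 1")

    def to_dict(self) -> dict:
        return {
            "T_star": self.T_star, "delta_U": self.delta_U, "L": self.L,
            "z": int(self.z), "chains_per_molecule": int(self.chains_per_molecule),
            "D0": self.D0, "DC": self.DC,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationInput":
        known = {"T_star", "delta_U", "L", "z", "chains_per_molecule", "D0", "DC"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown CalibrationInput keys: {sorted(unknown)}")
        return cls(**d)


def calibrate(ci: CalibrationInput) -> GEParams:
    """Invert (T*, ΔU) into model parameters; see the module docstring.

    Raises when the requested enthalpy would need sigma0 outside (0, 1)
    (too large for the chain-length degeneracy) or the result falls outside
    the discontinuous regime.
    """
    ln_deg = ci.L * _LN3 + math.log(ci.DC * ci.D0)
    H0 = 0.5 * ci.T_star * ln_deg
    sigma0 = 1000.0 * ci.delta_U / (ci.chains_per_molecule * GAS_CONSTANT * 2.0 * H0)
    if sigma0 >= 1.0:
        raise ModelDomainError(
            f"transition enthalpy {ci.delta_U} kJ/mol is too large for this "
            f"degeneracy (requires sigma0 = {sigma0:.4g} >= 1)"
        )
    if sigma0 <= 0.0:
        raise ModelDomainError("transition enthalpy must give sigma0 > 0")
    J = ci.T_star * math.atanh(sigma0) / (ci.z * sigma0)
    p = GEParams(
        J=J, H0=H0, ln_deg=ln_deg, z=ci.z,
        chains_per_molecule=ci.chains_per_molecule,
    )
    if p.z * p.J <= ci.T_star:
        raise ModelDomainError("calibration lands outside the discontinuous regime")
    du = transition_enthalpy(p)
    if abs(du - ci.delta_U) > 1e-6 * ci.delta_U:
        raise RuntimeError(
            f"calibration failed to close: round-trip enthalpy {du} != {ci.delta_U}"
        )
    return p


def implied_E0(ci: CalibrationInput, p: GEParams) -> float:
    """Excited-chain energy per carbon implied by a calibration, kelvin.

    From H0 = (z/4) J + E0 L / 2: E0 = (2 H0 - (z/2) J) / L.  For plausible
    calibrations this lands near the gauche-excitation scale (a few hundred
    kelvin per bond) and must be non-negative.
    """
    e0 = (2.0 * p.H0 - 0.5 * p.z * p.J) / ci.L
    if e0 < 0:
        raise ModelDomainError(
            f"calibration implies negative excited-chain energy E0 = {e0:.4g} K"
        )
    return e0
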