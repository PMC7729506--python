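"""Lifetime of the superheated metastable state and crystal-memory regions.

A melt held just above the transition temperature T* can retain solid
domains — "crystal memory" — for a long time.  The lifetime of this
superheated metastable state is modelled by a modified
Vogel-Fulcher-Tammann (VFT) law

    tau(T) + tau0 = tau0 * exp(D* T* / (T - T*)),        T > T*,

which diverges as T -> T*+ (the state becomes effectively stable) and
vanishes as T -> infinity.  Holding a sample at temperature T for a time
shorter than tau(T) leaves memory intact (region I); holding longer erases
it (region II).  The module also fits the law to labelled holding
time-temperature observations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .model import ModelDomainError

__all__ = [
    "VFTParams",
    "MemoryPoint",
    "VFTFit",
    "lifetime",
    "temperature_for_lifetime",
    "fit_vft",
    "classify_memory",
    "boundary_from_labeled",
]


@dataclass(frozen=True)
class VFTParams:
    """Lifetime-curve parameters: divergence temperature T* (kelvin),
    strength parameter D* (dimensionless, related to the barrier between
    the metastable and equilibrium melt), and prefactor tau0 (minutes)."""

    T_star: float
    D_star: float
    tau0: float

    def __post_init__(self) -> None:
        if self.T_star <= 0 or self.D_star <= 0 or self.tau0 <= 0:
            raise ModelDomainError("VFT parameters T_star, D_star, tau0 must all be > 0")

    def to_dict(self) -> dict:
        return {"T_star": self.T_star, "D_star": self.D_star, "tau0": self.tau0}

    @classmethod
    def from_dict(cls, d: dict) -> "VFTParams":
        known = {"T_star", "D_star", "tau0"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown VFTParams keys: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class MemoryPoint:
    """A labelled holding observation: temperature (kelvin), holding time
    (minutes), and whether crystal memory survived the hold."""

    T: float
    holding_time: float
    label: str  # "persists" | "lost"

    def __post_init__(self) -> None:
        if self.holding_time <= 0:
            raise ModelDomainError("holding_time must be > 0")
        if self.label not in ("persists", "lost"):
            raise ValueError(f"label must be 'persists' or 'lost', got {self.label!r}")


@dataclass(frozen=True)
class VFTFit:
    params: VFTParams
    rss: float
    n_points: int
    ci: dict  # parameter name -> (lo, hi) bootstrap percentile interval
    n_boot: int
    seed: int


def lifetime(v: VFTParams, T: float) -> float:
    """Mean lifetime (minutes) of the superheated state at temperature T > T*.

    tau = tau0 * (exp(D* T*/(T - T*)) - 1); strictly decreasing and convex,
    diverging at T* and vanishing at high temperature.  Below or at T* the
    solid is (meta)stable and no lifetime is defined.
    """
    if T <= v.T_star:
        raise ModelDomainError(
            f"T = {T} K is at or below T* = {v.T_star} K: the modified VFT "
            "lifetime applies only in the superheated metastable regime"
        )
    try:
        return v.tau0 * math.expm1(v.D_star * v.T_star / (T - v.T_star))
    except OverflowError:
        return math.inf  # closer to T* than double precision can resolve


def temperature_for_lifetime(v: VFTParams, tau: float) -> float:
    """Exact inverse of :func:`lifetime`: the temperature with lifetime tau.

    T = T* + D* T* / ln(1 + tau/tau0).
    """
    if tau <= 0:
        raise ModelDomainError(f"lifetime must be > 0 minutes, got {tau}")
    return v.T_star + v.D_star * v.T_star / math.log1p(tau / v.tau0)


def classify_memory(v: VFTParams, T: float, t: float) -> str:
    """Region label for a holding (T, t) pair.

    ``"persists"`` below/at T* (the solid never melted), ``"region_I"``
    (memory persists) when the hold is shorter than the metastable lifetime,
    ``"region_II"`` (memory lost) otherwise.  A hold exactly equal to the
    lifetime counts as lost — the conservative choice for memory-erasure
    protocols.
    """
    if t <= 0:
        raise ModelDomainError(f"holding time must be > 0, got {t}")
    if T <= v.T_star:
        return "persists"
    return "region_I" if t < lifetime(v, T) else "region_II"


def boundary_from_labeled(points: list[MemoryPoint]) -> list[tuple[float, float]]:
    """Per-temperature boundary lifetime estimates from labelled holds.

    At each temperature the boundary is estimated as the geometric mean of
    the longest persisting time and the shortest lost time (holding times
    are log-distributed, so the geometric mean is the symmetric choice).
    Temperatures lacking one of the two labels are dropped with a warning.
    """
    by_T: dict[float, dict[str, list[float]]] = {}
    for pt in points:
        by_T.setdefault(pt.T, {"persists": [], "lost": []})[pt.label].append(pt.holding_time)
    out: list[tuple[float, float]] = []
    for T in sorted(by_T):
        kept, lost = by_T[T]["persists"], by_T[T]["lost"]
        if not kept or not lost:
            warnings.warn(
                f"temperature {T} K lacks both labels; dropped from the boundary",
                stacklevel=2,
            )
            continue
        out.append((T, math.sqrt(max(kept) * min(lost))))
    if not out:
        raise ModelDomainError(
            "no temperature has both 'persists' and 'lost' observations; "
            "cannot locate the memory boundary"
        )
    return out


def _dstar_profile(
    T: np.ndarray, tau: np.ndarray, T_star: float, tau0: float
) -> tuple[float, float]:
    """Best D* and residual sum for fixed (T*, tau0) via the linearized law.

    ln(1 + tau/tau0) = D* * [T*/(T - T*)] is linear through the origin in
    x = T*/(T - T*), so D* has a closed form.
    """
    x = T_star / (T - T_star)
    y = np.log1p(tau / tau0)
    sxx = float(x @ x)
    d = float(x @ y) / sxx if sxx > 0 else 0.0
    r = y - d * x
    return d, float(r @ r)


def _fit_once(
    T: np.ndarray,
    tau: np.ndarray,
    fix_tau0: float | None,
    warm_start: tuple[float, float] | None = None,
) -> tuple[float, float, float, float]:
    """Profile least squares: search (T*, ln tau0), solve D* in closed form.

    ``warm_start`` = (T*, tau0) seeds a single local search (used for
    bootstrap resamples); otherwise several starting points are tried.
    """
    t_min = float(T.min())
    span = max(float(T.max()) - t_min, 1e-6)

    def unpack(theta: np.ndarray) -> tuple[float, float]:
        if fix_tau0 is None:
            # clamp ln tau0 so wandering simplex vertices cannot overflow exp
            return float(theta[0]), math.exp(min(float(theta[1]), 700.0))
        return float(theta[0]), fix_tau0

    def cost(theta: np.ndarray) -> float:
        T_star, tau0 = unpack(theta)
        if not 0.0 < T_star < t_min or not np.isfinite(tau0) or tau0 <= 0:
            return 1e30
        d, rss = _dstar_profile(T, tau, T_star, tau0)
        if d <= 0:
            return 1e30
        return rss

    if warm_start is not None:
        ts0 = min(warm_start[0], t_min - 1e-6 * span)
        starts = [(ts0, warm_start[1])]
    else:
        tau0_0 = max(float(tau.min()) / 10.0, 1e-12)
        starts = [(t_min - f * span, tau0_0) for f in (0.25, 1.0, 3.0)]
    best = None
    for ts0, t00 in starts:
        if ts0 <= 0:
            continue
        x0 = [ts0] if fix_tau0 is not None else [ts0, math.log(t00)]
        res = minimize(cost, np.asarray(x0, dtype=float), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    T_star, tau0 = unpack(best.x)
    if not 0.0 < T_star < t_min:
        raise ModelDomainError(
            "fit failed: optimal T* is not below the coldest observation"
        )
    d, rss = _dstar_profile(T, tau, T_star, tau0)
    return T_star, d, tau0, rss


def fit_vft(
    points: list[tuple[float, float]],
    fix_tau0: float | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> VFTFit:
    """Fit the modified VFT law to (temperature, boundary lifetime) points.

    Nested least squares on the linearized form ln(1 + tau/tau0) =
    D* T*/(T - T*): for each candidate (T*, tau0), D* is solved in closed
    form; (T*, ln tau0) are found by a derivative-free search (tau0 in
    log-space for positivity, or fixed via ``fix_tau0`` when the temperature
    range is too narrow to identify it).  Confidence intervals come from a
    seeded case-resampling bootstrap.

    Requires at least three points with distinct temperatures.
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be a sequence of (temperature, lifetime) pairs")
    T, tau = arr[:, 0], arr[:, 1]
    if len(np.unique(T)) < 3:
        raise ModelDomainError("need at least 3 points with distinct temperatures")
    if np.any(tau <= 0):
        raise ModelDomainError("boundary lifetimes must be > 0")

    T_star, D_star, tau0, rss = _fit_once(T, tau, fix_tau0)
    params = VFTParams(T_star=T_star, D_star=D_star, tau0=tau0)

    rng = np.random.default_rng(seed)
    n = len(T)
    samples: dict[str, list[float]] = {"T_star": [], "D_star": [], "tau0": []}
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(T[idx])) < 3:
            continue
        try:
            ts_b, d_b, t0_b, _ = _fit_once(
                T[idx], tau[idx], fix_tau0, warm_start=(T_star, tau0)
            )
        except (ModelDomainError, ValueError):
            continue
        samples["T_star"].append(ts_b)
        samples["D_star"].append(d_b)
        samples["tau0"].append(t0_b)
    alpha = 0.5 * (1.0 - ci_level)
    ci = {}
    for name, vals in samples.items():
        if vals:
            ci[name] = (
                float(np.quantile(vals, alpha)),
                float(np.quantile(vals, 1.0 - alpha)),
            )
        else:
            ci[name] = (math.nan, math.nan)
    return VFTFit(params=params, rss=rss, n_points=n, ci=ci, n_boot=n_boot, seed=seed)
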