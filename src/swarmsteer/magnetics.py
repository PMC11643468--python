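"""Chain magnetization model, magnetic force, and the gradient-limit input map.

Under a uniform field B the superparamagnetic nanoparticles assemble into
rod-like chains of n particles. For the force model each chain is replaced by
a volume-equivalent sphere of diameter D_eq = d (3n)^(1/3) and volume
V_eq = (pi/6) D_eq^3 = (pi/2) n d^3. The low-field magnetization per unit mass
follows the empirical power law M_m(B) = 1 + 19 (10 B)^0.16 with B in mT
(M_m in emu/g == A m^2/kg), and the steering force from a commanded flux-
density gradient grad-B is

    F = V_eq * M_m * rho * grad-B        (grad-B in T/m)

where the emu/g magnetization is converted to volumetric SI units by the
particle mass density rho. The user-side input is a dimensionless 2-vector of
magnitude <= 1; the gradient limit turns it into a command by pure scaling, so
the commanded magnitude never exceeds the limit.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MagneticParams",
    "GradientCommand",
    "magnetization",
    "chain_equivalent_diameter",
    "equivalent_volume",
    "magnetic_force",
    "chain_length_for_field",
    "limit_gradient",
]

MU_0 = 4e-7 * math.pi  # vacuum permeability, N/A^2

#: default chain-length rule slope, particles per mT (anchored at 3 mT -> 12000)
_CHAIN_SLOPE = 4000.0
_CHAIN_N_MAX = 50_000


def magnetization(B_mT: float) -> float:
    """Low-field magnetization per unit mass, emu/g, for field B in mT.

    M_m = 1 + 19 (10 B)^0.16; at 3 mT this gives 33.74 emu/g.
    """
    if B_mT <= 0:
        raise ValueError("magnetic field must be > 0")
    return 1.0 + 19.0 * (10.0 * B_mT) ** 0.16


def chain_equivalent_diameter(d: float, n: float) -> float:
    """Diameter of the sphere with the volume of an n-particle chain cylinder."""
    if d <= 0 or n < 1:
        raise ValueError("require d > 0 and n >= 1")
    return d * (3.0 * n) ** (1.0 / 3.0)


def equivalent_volume(D_eq: float) -> float:
    """Volume of the equivalent sphere, (4/3) pi (D_eq/2)^3."""
    if D_eq <= 0:
        raise ValueError("require D_eq > 0")
    return (4.0 / 3.0) * math.pi * (D_eq / 2.0) ** 3


def chain_length_for_field(B_mT: float, rule=None, n_max: int = _CHAIN_N_MAX) -> int:
    """Average chain length for field B (mT).

    The single well-characterized anchor is 12000 particles at 3 mT; the
    default rule interpolates linearly through it, n(B) = round(4000 B),
    clamped to [1, n_max]. Pass ``rule`` (a callable B -> n) to substitute a
    measured chain-length curve.
    """
    n = rule(B_mT) if rule is not None else _CHAIN_SLOPE * max(B_mT, 0.0)
    return int(min(max(round(n), 1), n_max))


@dataclass(frozen=True)
class MagneticParams:
    """Field, particle and chain parameters of the force model.

    Defaults are the platform's stock values: B = 3 mT, d = 75 nm magnetite
    particles of density 4800 kg/m^3 in chains of n = 12000. ``M_m`` defaults
    to magnetization(B) but can be pinned explicitly.
    """

    B_mT: float = 3.0
    d: float = 75e-9
    n: int = 12_000
    rho: float = 4800.0
    mu0: float = MU_0
    M_m: float | None = None

    def __post_init__(self) -> None:
        if min(self.B_mT, self.d, self.n, self.rho) <= 0:
            raise ValueError("all magnetic parameters must be positive")

    @property
    def magnetization_emu_g(self) -> float:
        return self.M_m if self.M_m is not None else magnetization(self.B_mT)

    @property
    def D_eq(self) -> float:
        return chain_equivalent_diameter(self.d, self.n)

    @property
    def V_eq(self) -> float:
        return equivalent_volume(self.D_eq)

    @classmethod
    def for_field(cls, B_mT: float, rule=None, **kwargs) -> "MagneticParams":
        """Params with chain length and magnetization adjusted to the field."""
        return cls(B_mT=B_mT, n=chain_length_for_field(B_mT, rule=rule), **kwargs)


@dataclass(frozen=True)
class GradientCommand:
    """A capped 2D flux-density gradient command, mT/m."""

    gradient: tuple[float, float]
    limit: float

    def __post_init__(self) -> None:
        if self.limit <= 0:
            raise ValueError("gradient limit must be > 0")
        if np.linalg.norm(self.gradient) > self.limit * (1 + 1e-12):
            raise ValueError("command magnitude exceeds the limit")

    @property
    def vector(self) -> np.ndarray:
        return np.asarray(self.gradient, float)


def limit_gradient(raw, limit: float) -> GradientCommand:
    """Scale a dimensionless input (magnitude <= 1) by the gradient limit.

    Inputs of magnitude above 1 are renormalized to 1 first, so the commanded
    gradient magnitude never exceeds ``limit``.
    """
    raw = np.asarray(raw, float)
    mag = float(np.linalg.norm(raw))
    if mag > 1.0:
        raw = raw / mag
    g = raw * limit
    return GradientCommand((float(g[0]), float(g[1])), limit)


def magnetic_force(params: MagneticParams, cmd: GradientCommand) -> np.ndarray:
    """Steering force (N) on the equivalent sphere from a gradient command.

    The commanded mT/m gradient is a flux-density gradient, converted to T/m;
    emu/g magnetization times mass density gives the volumetric magnetization,
    so mu0 cancels and never appears numerically.
    """
    grad_T_per_m = cmd.vector * 1e-3
    return params.V_eq * params.magnetization_emu_g * params.rho * grad_T_per_m
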