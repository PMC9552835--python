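"""Constitutive wall mechanics for 1D elastic vessel segments.

The tube law relates transmural pressure to cross-sectional area,

    P - Pext = f (1 - sqrt(A0 / A)) + P0,

with the stiffness coefficient

    f = (4/3) E h / R0 = (4/3) (k1 exp(k2 R0) + k3)

following the empirical three-constant fit for arterial walls.  Two
constant sets are carried: a stiff "coronary-like" law used for
coronary, internal-mammary and radial arteries, and a compliant
"large-systemic" law for the aorta and its major branches.  The
Moens-Korteweg wave speed at the unstressed state is c0 = sqrt(f / 2 rho).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .units import dyn

__all__ = [
    "FluidProperties",
    "WallLaw",
    "CORONARY",
    "LARGE_SYSTEMIC",
    "WALL_LAWS",
    "VelocityProfile",
    "stiffness_f",
    "pressure_from_area",
    "area_from_pressure",
    "wave_speed",
]

#: default reference (diastolic) pressure, dyn/cm^2
DEFAULT_P0 = dyn(76.41)


@dataclass(frozen=True)
class FluidProperties:
    """Blood rheology. Density in g/cm^3, dynamic viscosity in dyn s/cm^2."""

    rho: float = 1.06
    mu: float = 0.046

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu < 0:
            raise ValueError("density must be positive and viscosity non-negative")

    @property
    def nu(self) -> float:
        """Kinematic viscosity, cm^2/s."""
        return self.mu / self.rho


@dataclass(frozen=True)
class WallLaw:
    """Three-constant elastic wall law, stored in CGS.

    k1, k3 in g/s^2/cm (scale prefixes 1e6 / 1e4 applied once at
    construction), k2 in 1/cm.
    """

    name: str
    k1: float
    k2: float
    k3: float
    alpha: float = 1.1  # momentum-correction (Coriolis) coefficient

    def __post_init__(self) -> None:
        if not (1.0 < self.alpha <= 4.0 / 3.0):
            raise ValueError(f"alpha must lie in (1, 4/3], got {self.alpha}")

    def stiffness(self, r0: float) -> float:
        return stiffness_f(r0, self)

    def wave_speed(self, r0: float, rho: float) -> float:
        return wave_speed(r0, self, rho)


#: coronary / small-systemic wall constants (k1=20.0e6, k2=-22.5, k3=86.5e4)
CORONARY = WallLaw("coronary", 20.0e6, -22.5, 86.5e4, alpha=1.1)
#: aorta / major-branch wall constants (k1=3.0e6, k2=-9.0, k3=33.7e4)
LARGE_SYSTEMIC = WallLaw("large_systemic", 3.0e6, -9.0, 33.7e4, alpha=1.05)

WALL_LAWS = {law.name: law for law in (CORONARY, LARGE_SYSTEMIC)}


def stiffness_f(r0: float, law: WallLaw) -> float:
    """Wall stiffness f = (4/3)(k1 e^{k2 R0} + k3) in dyn/cm^2."""
    if r0 <= 0:
        raise ValueError(f"unstressed radius must be positive, got {r0}")
    return (4.0 / 3.0) * (law.k1 * math.exp(law.k2 * r0) + law.k3)


def pressure_from_area(a, a0: float, f: float, p0: float = DEFAULT_P0, pext: float = 0.0):
    """Tube law P = Pext + f (1 - sqrt(A0/A)) + P0. Accepts scalars or arrays."""
    a_arr = np.asarray(a, dtype=float)
    if np.any(a_arr <= 0):
        raise ValueError("cross-sectional area must be positive")
    p = pext + f * (1.0 - np.sqrt(a0 / a_arr)) + p0
    return float(p) if np.isscalar(a) else p


def area_from_pressure(p, a0: float, f: float, p0: float = DEFAULT_P0, pext: float = 0.0):
    """Inverse tube law A = A0 / (1 - (P - Pext - P0)/f)^2.

    Raises for the vessel-collapse condition (P - Pext - P0) >= f.
    """
    p_arr = np.asarray(p, dtype=float)
    x = (p_arr - pext - p0) / f
    if np.any(x >= 1.0):
        raise ValueError("nonphysical pressure: (P - Pext - P0)/f >= 1 (tube-law collapse)")
    a = a0 / (1.0 - x) ** 2
    return float(a) if np.isscalar(p) else a


def wave_speed(r0: float, law: WallLaw, rho: float) -> float:
    """Moens-Korteweg speed c0 = sqrt(f / (2 rho)) in cm/s."""
    return math.sqrt(stiffness_f(r0, law) / (2.0 * rho))


@dataclass(frozen=True)
class VelocityProfile:
    """Axial velocity-profile shape implied by the Coriolis coefficient.

    phi(r) = alpha/(2 - alpha) * (1 - (r/R)^gamma), gamma = (2 - alpha)/(alpha - 1),
    normalised so the cross-sectional mean velocity is 1 and the momentum
    integral is alpha.  alpha = 4/3 recovers the Poiseuille parabola,
    alpha -> 1 plug flow (which violates no-slip and is excluded).
    """

    alpha: float
    gamma: float = field(init=False)

    def __post_init__(self) -> None:
        if not (1.0 < self.alpha <= 4.0 / 3.0):
            raise ValueError(f"alpha must lie in (1, 4/3], got {self.alpha}")
        object.__setattr__(self, "gamma", (2.0 - self.alpha) / (self.alpha - 1.0))

    def phi(self, r, radius: float = 1.0):
        """Normalised profile phi(r); phi(R) = 0 (no-slip), mean over the
        cross-section is 1."""
        rr = np.asarray(r, dtype=float) / radius
        val = self.alpha / (2.0 - self.alpha) * (1.0 - rr**self.gamma)
        return float(val) if np.isscalar(r) else val

    def friction_coefficient(self) -> float:
        """Coefficient alpha/(alpha-1) entering the viscous source term."""
        return self.alpha / (self.alpha - 1.0)
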