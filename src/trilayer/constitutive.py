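"""Holzapfel-Gasser-Ogden (HGO) constitutive model for incompressible
arterial membranes.

Each arterial layer is modelled as an isotropic ground matrix (elastin,
neo-Hookean-like term ``mu * (I1 - 3)``) reinforced by two symmetric
families of collagen fibres at +/- alpha from the circumferential
direction with a scalar dispersion coefficient ``rho``:

    Psi = mu * (I1 - 3)
        + (c1 / c2) * (exp(c2 * [rho * I1 + (1 - 3 rho) * I4 - 1]**2) - 1)

with ``I1 = lam_c^2 + lam_r^2 + lam_a^2`` and
``I4 = lam_c^2 cos^2(alpha) + lam_a^2 sin^2(alpha)``.

Conventions (documented prominently because both exist in the literature):

* the isotropic term is ``mu * (I1 - 3)``, *not* ``mu/2 * (I1 - 3)``;
* the fibre exponent argument is ``rho*I1 + (1-3 rho)*I4 - 1``, which
  vanishes identically at the identity deformation, so ``Psi(I) = 0``
  for every admissible parameter set;
* fibres contribute in compression as well as tension (no tension-only
  switch); a switch can be enabled with ``fiber_tension_only=True``.

Deformations are volume-preserving and diagonal (negligible shear), so
the Cauchy stress is diagonal too; the Lagrange multiplier enforcing
incompressibility is eliminated through the membrane (plane-stress)
condition ``t_rad = 0``.

Angles are degrees at every public interface and radians internally.
Stresses are kPa throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "HGOParams",
    "DiagonalDeformation",
    "StressTriple",
    "DomainError",
    "EnergyOverflowError",
    "SolverError",
    "strain_invariants",
    "hgo_energy",
    "lagrange_multiplier",
    "membrane_stress",
    "uniaxial_state",
    "uniaxial_stress_curve",
]

_DET_TOL = 1e-10
_EXP_MAX = 700.0  # exp() overflows just above exp(709)
_TRANSVERSE_BRACKET = (0.3, 1.5)


class DomainError(ValueError):
    """Invalid parameter or deformation input."""


class SolverError(RuntimeError):
    """A scalar root solve failed (no bracket / no convergence)."""


class EnergyOverflowError(FloatingPointError):
    """The fibre exponential overflowed; carries the offending exponent."""

    def __init__(self, exponent: float):
        self.exponent = float(exponent)
        super().__init__(
            f"fibre exponential overflow: exponent c2*E^2 = {exponent:.6g} "
            f"exceeds {_EXP_MAX:g}"
        )


@dataclass(frozen=True)
class HGOParams:
    """Constitutive parameters of one arterial layer.

    Parameters
    ----------
    mu : float
        Isotropic (matrix) stiffness-like parameter, kPa.
    c1 : float
        Collagen stiffness-like parameter, kPa.
    c2 : float
        Dimensionless collagen nonlinearity parameter.
    alpha_deg : float
        Principal fibre angle from the circumferential direction, degrees.
    rho : float
        Fibre dispersion coefficient in [0, 1/3]; 0 = fully aligned,
        1/3 = fully dispersed (isotropic).
    """

    mu: float
    c1: float
    c2: float
    alpha_deg: float
    rho: float

    def __post_init__(self) -> None:
        if not (self.mu > 0):
            raise DomainError(f"mu must be > 0, got {self.mu}")
        if not (self.c1 > 0):
            raise DomainError(f"c1 must be > 0, got {self.c1}")
        if not (self.c2 > 0):
            raise DomainError(f"c2 must be > 0, got {self.c2}")
        if not (0.0 <= self.alpha_deg <= 90.0):
            raise DomainError(f"alpha_deg must be in [0, 90], got {self.alpha_deg}")
        if not (0.0 <= self.rho <= 1.0 / 3.0 + 1e-12):
            raise DomainError(f"rho must be in [0, 1/3], got {self.rho}")

    @property
    def alpha_rad(self) -> float:
        return math.radians(self.alpha_deg)

    def as_array(self) -> np.ndarray:
        return np.array([self.mu, self.c1, self.c2, self.alpha_deg, self.rho])


@dataclass(frozen=True)
class DiagonalDeformation:
    """Volume-preserving diagonal deformation gradient.

    Components are the principal stretches in the circumferential,
    radial and axial directions; ``det F = 1`` is enforced to 1e-10.
    """

    lam_circ: float
    lam_rad: float
    lam_ax: float

    def __post_init__(self) -> None:
        for name in ("lam_circ", "lam_rad", "lam_ax"):
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise DomainError(f"{name} must be positive and finite, got {v}")
        det = self.lam_circ * self.lam_rad * self.lam_ax
        if abs(det - 1.0) > _DET_TOL:
            raise DomainError(f"det F = {det!r} violates incompressibility")

    @classmethod
    def from_in_plane(cls, lam_circ: float, lam_ax: float) -> "DiagonalDeformation":
        """Build from in-plane stretches, radial from incompressibility."""
        if not (lam_circ > 0 and lam_ax > 0):
            raise DomainError("in-plane stretches must be positive")
        return cls(lam_circ, 1.0 / (lam_circ * lam_ax), lam_ax)

    def compose(self, other: "DiagonalDeformation") -> "DiagonalDeformation":
        """Componentwise product self @ other (both diagonal)."""
        return DiagonalDeformation.from_in_plane(
            self.lam_circ * other.lam_circ, self.lam_ax * other.lam_ax
        )

    @property
    def identity(self) -> bool:
        return self.lam_circ == self.lam_rad == self.lam_ax == 1.0


IDENTITY = DiagonalDeformation(1.0, 1.0, 1.0)


@dataclass(frozen=True)
class StressTriple:
    """Diagonal Cauchy stress, kPa; membrane states have t_rad = 0."""

    t_circ: float
    t_rad: float
    t_ax: float

    def as_array(self) -> np.ndarray:
        return np.array([self.t_circ, self.t_rad, self.t_ax])


def strain_invariants(F: DiagonalDeformation, alpha_deg: float) -> tuple[float, float]:
    """First and fourth invariants of C = F^T F for fibre angle alpha.

    ``I4`` is shared by both fibre families by symmetry.
    """
    a = math.radians(alpha_deg)
    i1 = F.lam_circ**2 + F.lam_rad**2 + F.lam_ax**2
    i4 = F.lam_circ**2 * math.cos(a) ** 2 + F.lam_ax**2 * math.sin(a) ** 2
    return i1, i4


def _fiber_exponent_arg(p: HGOParams, i1: float, i4: float) -> float:
    """E = rho*I1 + (1 - 3 rho)*I4 - 1 (zero at the identity)."""
    return p.rho * i1 + (1.0 - 3.0 * p.rho) * i4 - 1.0


def hgo_energy(
    p: HGOParams, F: DiagonalDeformation, *, fiber_tension_only: bool = False
) -> float:
    """Strain-energy density, kPa (per unit reference volume)."""
    i1, i4 = strain_invariants(F, p.alpha_deg)
    e = _fiber_exponent_arg(p, i1, i4)
    if fiber_tension_only and i4 < 1.0:
        fib = 0.0
    else:
        expo = p.c2 * e * e
        if expo > _EXP_MAX:
            raise EnergyOverflowError(expo)
        fib = (p.c1 / p.c2) * (math.exp(expo) - 1.0)
    return p.mu * (i1 - 3.0) + fib


def _psi_derivatives(
    p: HGOParams, i1: float, i4: float, *, fiber_tension_only: bool = False
) -> tuple[float, float]:
    """(dPsi/dI1, dPsi/dI4)."""
    e = _fiber_exponent_arg(p, i1, i4)
    if fiber_tension_only and i4 < 1.0:
        a = 0.0
    else:
        expo = p.c2 * e * e
        if expo > _EXP_MAX:
            raise EnergyOverflowError(expo)
        a = 2.0 * p.c1 * e * math.exp(expo)
    return p.mu + p.rho * a, (1.0 - 3.0 * p.rho) * a


def lagrange_multiplier(
    p: HGOParams, F: DiagonalDeformation, *, fiber_tension_only: bool = False
) -> float:
    """Pressure-like multiplier enforcing the membrane condition t_rad = 0.

    From ``t = -p I + 2 F (dPsi/dC) F^T`` with diagonal F and fibres in
    the circumferential-axial plane, ``t_rr = -p + 2 lam_r^2 Psi_1``.
    """
    i1, i4 = strain_invariants(F, p.alpha_deg)
    psi1, _ = _psi_derivatives(p, i1, i4, fiber_tension_only=fiber_tension_only)
    return 2.0 * F.lam_rad**2 * psi1


def membrane_stress(
    p: HGOParams, F: DiagonalDeformation, *, fiber_tension_only: bool = False
) -> StressTriple:
    """Diagonal Cauchy stress with t_rad = 0 enforced exactly.

    t_cc = 2 (lam_c^2 - lam_r^2) Psi_1 + 2 lam_c^2 cos^2(a) Psi_4
    t_aa = 2 (lam_a^2 - lam_r^2) Psi_1 + 2 lam_a^2 sin^2(a) Psi_4
    """
    i1, i4 = strain_invariants(F, p.alpha_deg)
    psi1, psi4 = _psi_derivatives(p, i1, i4, fiber_tension_only=fiber_tension_only)
    ca2 = math.cos(p.alpha_rad) ** 2
    sa2 = math.sin(p.alpha_rad) ** 2
    lc2, lr2, la2 = F.lam_circ**2, F.lam_rad**2, F.lam_ax**2
    t_circ = 2.0 * (lc2 - lr2) * psi1 + 2.0 * lc2 * ca2 * psi4
    t_ax = 2.0 * (la2 - lr2) * psi1 + 2.0 * la2 * sa2 * psi4
    return StressTriple(t_circ, 0.0, t_ax)


def _transverse_stress(
    p: HGOParams, direction: str, lam_load: float, lam_trans: float
) -> float:
    if direction == "circ":
        F = DiagonalDeformation.from_in_plane(lam_load, lam_trans)
        return membrane_stress(p, F).t_ax
    F = DiagonalDeformation.from_in_plane(lam_trans, lam_load)
    return membrane_stress(p, F).t_circ


def uniaxial_state(
    p: HGOParams,
    direction: str,
    lam_load: float,
    *,
    bracket: tuple[float, float] = _TRANSVERSE_BRACKET,
    xtol: float = 1e-10,
) -> tuple[float, float]:
    """Uniaxial membrane stress state at a given loading stretch.

    Solves for the in-plane transverse stretch that annihilates the
    transverse stress (with ``t_rad = 0`` and incompressibility built
    in) and returns ``(t_load [kPa], lam_transverse)``.

    Parameters
    ----------
    direction : {"circ", "ax"}
        Loading direction of the strip.
    lam_load : float
        Applied tensile stretch (>= 1 in tests; any positive value is
        accepted for model evaluation).
    """
    if direction not in ("circ", "ax"):
        raise DomainError(f"direction must be 'circ' or 'ax', got {direction!r}")
    if not (lam_load > 0):
        raise DomainError(f"lam_load must be positive, got {lam_load}")
    if lam_load == 1.0:
        return 0.0, 1.0

    def f(x: float) -> float:
        return _transverse_stress(p, direction, lam_load, x)

    lo, hi = bracket
    flo, fhi = f(lo), f(hi)
    if (flo > 0) == (fhi > 0):
        raise SolverError(
            f"no transverse-stress sign change in [{lo}, {hi}] for "
            f"direction={direction}, lam_load={lam_load}: "
            f"f({lo})={flo:.3g}, f({hi})={fhi:.3g}"
        )
    lam_t = brentq(f, lo, hi, xtol=xtol)
    if direction == "circ":
        F = DiagonalDeformation.from_in_plane(lam_load, lam_t)
        t_load = membrane_stress(p, F).t_circ
    else:
        F = DiagonalDeformation.from_in_plane(lam_t, lam_load)
        t_load = membrane_stress(p, F).t_ax
    return t_load, lam_t


def uniaxial_stress_curve(
    p: HGOParams, direction: str, stretches: np.ndarray
) -> np.ndarray:
    """Loading-direction Cauchy stress (kPa) at each applied stretch."""
    stretches = np.asarray(stretches, dtype=float)
    out = np.empty_like(stretches)
    for i, lam in enumerate(stretches.ravel()):
        out.ravel()[i] = uniaxial_state(p, direction, float(lam))[0]
    return out
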