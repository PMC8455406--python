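"""Closure of the flat composite wall into a cylinder and tension-inflation.

The flat tri-layered wall (circumferential length ``l_x``) is bent into a
closed, traction-free cylinder by a deformation F1 = diag(Lam_Theta,
1/(Lam_Theta Lam_Z), Lam_Z).  The through-thickness coordinate ``y``
(measured from the luminal face of the composite wall) maps to radius

    R(y) = sqrt(R_internal^2 + l_x * y / (pi * Lam_Z)),

so the circumferential closure stretch Lam_Theta(y) = 2 pi R(y) / l_x varies
through the wall.  Closure has two unknowns, solved so the
thickness-averaged circumferential and axial wall stresses vanish; the
radial stress is identically zero under the membrane assumption.  Two
anchors relate the geometry to the measured unloaded radius:

* ``anchor="closed_radius"`` (default): the measurement is taken as the
  internal radius of the unloaded *closed* vessel (a radius is a property
  of the intact vessel, not of a flattened strip); the flat-wall length
  ``l_x`` and ``Lam_Z`` are the unknowns.
* ``anchor="flat_length"``: ``l_x = 2 pi R_ref`` is fixed by the
  measurement and (R_internal, Lam_Z) are the unknowns.

Tension-inflation F2 = diag(lam_theta, 1/(lam_theta lam_z), lam_z) maps the
unloaded cylinder to a pressurised, axially stretched state; lam_theta(R) =
r/R follows from conservation of volume and the luminal radius is solved so
the thin-wall (Laplace) equilibrium

    P = t_thetatheta^wall * (r_external - r_internal) / r_internal

matches the target pressure.  Each layer is treated as a membrane: its
stresses and stretches are evaluated at its mid-thickness coordinate, and
wall quantities are deformed-thickness-weighted layer averages.

The in-vivo axial stretch is the mean of the pairwise cross-over stretches
of reduced axial force vs axial stretch curves at 60, 100 and 140 mmHg.

Units: lengths mm, stresses kPa, pressures mmHg at interfaces
(1 mmHg = 0.133322 kPa), forces N.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, least_squares

from .constitutive import (
    DiagonalDeformation,
    SolverError,
    StressTriple,
    membrane_stress,
)
from .layer_composition import WallModel

__all__ = [
    "TubeState",
    "MMHG_TO_KPA",
    "close_vessel",
    "inflate",
    "reduced_axial_force",
    "estimate_in_vivo_stretch",
]

MMHG_TO_KPA = 0.133322
KPA_MM2_TO_N = 1e-3  # kPa * mm^2 = 1e-3 N


@dataclass(frozen=True)
class TubeState:
    """A (possibly loaded) cylindrical configuration of the tri-layered wall.

    Closure fields describe the unloaded cylinder; the loaded fields equal
    the closure ones at pressure 0 and lam_z 1.  Layer arrays are ordered
    intima, media, adventitia (inner to outer).
    """

    wall: WallModel
    # closure (kappa_composite -> kappa_unloaded)
    l_x: float                           # mm, flat-wall circumferential length
    R_internal: float                    # mm, unloaded internal radius
    Lam_Z: float                         # axial closure stretch
    Lam_Theta: np.ndarray                # (3,) mid-layer circumferential closure stretches
    R_interfaces: np.ndarray             # (4,) unloaded interface radii, mm
    R_mid: np.ndarray                    # (3,) unloaded mid-layer radii, mm
    # loading (kappa_unloaded -> kappa_tension_inflation)
    pressure: float                      # mmHg
    lam_z: float                         # axial inflation stretch
    r_internal: float                    # mm, loaded internal radius
    r_interfaces: np.ndarray             # (4,) loaded interface radii, mm
    lam_theta: np.ndarray                # (3,) mid-layer inflation stretches
    layer_deformations: tuple[DiagonalDeformation, ...]  # total F2 F1 G^k
    layer_stresses: tuple[StressTriple, ...]
    wall_stress: StressTriple

    @property
    def r_external(self) -> float:
        return float(self.r_interfaces[-1])

    @property
    def R_external(self) -> float:
        return float(self.R_interfaces[-1])

    @property
    def deformed_thicknesses(self) -> np.ndarray:
        """Loaded layer thicknesses (mm); sum exactly to the wall thickness."""
        return np.diff(self.r_interfaces)

    @property
    def luminal_circ_stretch(self) -> float:
        """r_internal / R_internal, the circumferential stretch at the lumen."""
        return self.r_internal / self.R_internal


def _composite_layers_y(wall: WallModel) -> tuple[np.ndarray, np.ndarray]:
    """(interface, mid-layer) through-thickness coordinates of the composite
    flat wall; y measured from the luminal face."""
    h = np.array([l.composite_thickness for l in wall.layers])
    y_if = np.concatenate([[0.0], np.cumsum(h)])
    y_mid = 0.5 * (y_if[:-1] + y_if[1:])
    return y_if, y_mid


def _unloaded_radii(
    wall: WallModel, l_x: float, R_int: float, Lam_Z: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interface radii, mid-layer radii and mid-layer Lam_Theta."""
    y_if, y_mid = _composite_layers_y(wall)
    R_if = np.sqrt(R_int**2 + l_x * y_if / (math.pi * Lam_Z))
    R_mid = np.sqrt(R_int**2 + l_x * y_mid / (math.pi * Lam_Z))
    Lam_Theta = 2.0 * math.pi * R_mid / l_x
    return R_if, R_mid, Lam_Theta


def _closed_state(wall: WallModel, l_x: float, R_int: float, Lam_Z: float) -> TubeState:
    R_if, R_mid, Lam_Theta = _unloaded_radii(wall, l_x, R_int, Lam_Z)
    defs, stresses = [], []
    for j, layer in enumerate(wall.layers):
        F = DiagonalDeformation.from_in_plane(
            Lam_Theta[j] * layer.prestretch_circ, Lam_Z * layer.prestretch_ax
        )
        defs.append(F)
        stresses.append(membrane_stress(layer.params, F))
    h = np.diff(R_if)
    t_c = float(np.dot(h, [s.t_circ for s in stresses]) / h.sum())
    t_a = float(np.dot(h, [s.t_ax for s in stresses]) / h.sum())
    return TubeState(
        wall=wall,
        l_x=l_x,
        R_internal=R_int,
        Lam_Z=Lam_Z,
        Lam_Theta=Lam_Theta,
        R_interfaces=R_if,
        R_mid=R_mid,
        pressure=0.0,
        lam_z=1.0,
        r_internal=R_int,
        r_interfaces=R_if.copy(),
        lam_theta=np.ones(3),
        layer_deformations=tuple(defs),
        layer_stresses=tuple(stresses),
        wall_stress=StressTriple(t_c, 0.0, t_a),
    )


def close_vessel(
    wall: WallModel,
    *,
    prestretch: bool = True,
    anchor: str = "closed_radius",
    tol: float = 1e-6,
) -> TubeState:
    """Close the flat composite wall into a traction-free cylinder.

    Solves the two closure unknowns so that the thickness-averaged
    circumferential and axial stresses of the closed, unloaded vessel both
    vanish (|mean stress| < ``tol`` kPa).  ``anchor`` selects whether the
    measured unloaded radius pins the closed internal radius (default) or
    the flat-wall circumferential length; see the module docstring.  With
    ``prestretch=False`` the comparison case G^k = F1 = I is returned: the
    unloaded cylinder with the measured internal radius, stress-free by
    construction.
    """
    R_ref = wall.unloaded_internal_radius
    if not prestretch:
        wall0 = wall.without_prestretches()
        state = _closed_state(wall0, 2.0 * math.pi * R_ref, R_ref, 1.0)
        # the comparison case pins the closure map to the identity
        return TubeState(
            wall=wall0,
            l_x=state.l_x,
            R_internal=state.R_internal,
            Lam_Z=1.0,
            Lam_Theta=np.ones(3),
            R_interfaces=state.R_interfaces,
            R_mid=state.R_mid,
            pressure=0.0,
            lam_z=1.0,
            r_internal=state.R_internal,
            r_interfaces=state.R_interfaces.copy(),
            lam_theta=np.ones(3),
            layer_deformations=tuple(
                DiagonalDeformation(1.0, 1.0, 1.0) for _ in range(3)
            ),
            layer_stresses=tuple(StressTriple(0.0, 0.0, 0.0) for _ in range(3)),
            wall_stress=StressTriple(0.0, 0.0, 0.0),
        )

    if anchor == "closed_radius":
        def build(x: np.ndarray) -> TubeState:
            return _closed_state(wall, 2.0 * math.pi * x[0], R_ref, x[1])
    elif anchor == "flat_length":
        def build(x: np.ndarray) -> TubeState:
            return _closed_state(wall, 2.0 * math.pi * R_ref, x[0], x[1])
    else:
        raise ValueError(f"anchor must be 'closed_radius' or 'flat_length', got {anchor!r}")

    def residual(x: np.ndarray) -> np.ndarray:
        state = build(x)
        return np.array([state.wall_stress.t_circ, state.wall_stress.t_ax])

    sol = least_squares(
        residual,
        x0=np.array([(1.1 if anchor == "closed_radius" else 0.9) * R_ref, 1.0]),
        bounds=([0.2 * R_ref, 0.7], [2.0 * R_ref, 1.4]),
        xtol=3e-16, ftol=3e-16, gtol=1e-14,
    )
    res = residual(sol.x)
    if np.max(np.abs(res)) > tol:
        raise SolverError(
            "closure equilibrium not reached: residual mean stresses "
            f"(circ, ax) = ({res[0]:.3e}, {res[1]:.3e}) kPa"
        )
    return build(sol.x)


def _loaded_state(tube: TubeState, r_int: float, lam_z: float) -> TubeState:
    """Deformed state at given luminal radius and axial stretch."""
    R_if, R_mid = tube.R_interfaces, tube.R_mid
    R_int = tube.R_internal
    r_if = np.sqrt(r_int**2 + (R_if**2 - R_int**2) / lam_z)
    r_mid = np.sqrt(r_int**2 + (R_mid**2 - R_int**2) / lam_z)
    lam_theta = r_mid / R_mid
    defs, stresses = [], []
    for j, layer in enumerate(tube.wall.layers):
        F = DiagonalDeformation.from_in_plane(
            lam_theta[j] * tube.Lam_Theta[j] * layer.prestretch_circ,
            lam_z * tube.Lam_Z * layer.prestretch_ax,
        )
        defs.append(F)
        stresses.append(membrane_stress(layer.params, F))
    h = np.diff(r_if)
    t_c = float(np.dot(h, [s.t_circ for s in stresses]) / h.sum())
    t_a = float(np.dot(h, [s.t_ax for s in stresses]) / h.sum())
    wall_stress = StressTriple(t_c, 0.0, t_a)
    P_kpa = t_c * (r_if[-1] - r_int) / r_int
    return TubeState(
        wall=tube.wall,
        l_x=tube.l_x,
        R_internal=tube.R_internal,
        Lam_Z=tube.Lam_Z,
        Lam_Theta=tube.Lam_Theta,
        R_interfaces=tube.R_interfaces,
        R_mid=tube.R_mid,
        pressure=P_kpa / MMHG_TO_KPA,
        lam_z=lam_z,
        r_internal=r_int,
        r_interfaces=r_if,
        lam_theta=lam_theta,
        layer_deformations=tuple(defs),
        layer_stresses=tuple(stresses),
        wall_stress=wall_stress,
    )


def inflate(
    tube: TubeState,
    pressure: float,
    lam_z: float,
    *,
    tol_mmhg: float = 1e-3,
    bracket: tuple[float, float] = (0.5, 2.5),
) -> TubeState:
    """Tension-inflation of the closed vessel to a target pressure.

    Solves the luminal radius by bracketed root-finding so the thin-wall
    equilibrium pressure matches ``pressure`` (mmHg) at axial stretch
    ``lam_z``; the bracket is in multiples of the unloaded internal
    radius.
    """
    if pressure < 0:
        raise SolverError(f"pressure must be >= 0, got {pressure}")
    if not (lam_z > 0):
        raise SolverError(f"lam_z must be > 0, got {lam_z}")

    def p_err(r_int: float) -> float:
        return _loaded_state(tube, r_int, lam_z).pressure - pressure

    lo = bracket[0] * tube.R_internal
    hi = bracket[1] * tube.R_internal
    flo, fhi = p_err(lo), p_err(hi)
    if flo * fhi > 0:
        raise SolverError(
            f"target pressure {pressure} mmHg not bracketed by luminal radii "
            f"[{lo:.3g}, {hi:.3g}] mm (errors {flo:.3g}, {fhi:.3g} mmHg)"
        )
    r_int = brentq(p_err, lo, hi, xtol=1e-12, rtol=8.9e-16)
    state = _loaded_state(tube, r_int, lam_z)
    if abs(state.pressure - pressure) > tol_mmhg:
        raise SolverError(
            f"inflation solve imprecise: |P - target| = "
            f"{abs(state.pressure - pressure):.3g} mmHg"
        )
    return state


def reduced_axial_force(tube: TubeState) -> float:
    """Reduced axial force F_z (N) of a loaded state.

    F_z = pi * t_zz^wall * (r_ext^2 - r_int^2) - pi * r_int^2 * P, with the
    thickness-averaged axial wall stress and the pressure converted to kPa
    for unit consistency.  In the closed unloaded state (zero mean axial
    stress, zero pressure) the reduced force vanishes identically; the
    formula agrees with the exact annular integral of the layerwise
    stresses up to the membrane (thin-layer) approximation.
    """
    P_kpa = tube.pressure * MMHG_TO_KPA
    area = tube.r_external**2 - tube.r_internal**2
    return KPA_MM2_TO_N * math.pi * (
        tube.wall_stress.t_ax * area - tube.r_internal**2 * P_kpa
    )


def estimate_in_vivo_stretch(
    tube: TubeState,
    *,
    pressures: tuple[float, float, float] = (60.0, 100.0, 140.0),
    bracket: tuple[float, float] = (1.0, 1.3),
    return_crossings: bool = False,
) -> float | tuple[float, list[float]]:
    """In-vivo axial stretch from reduced axial force cross-overs.

    The reduced axial force vs axial stretch relationship is computed at
    each pressure; the in-vivo stretch is the mean of the three pairwise
    cross-over stretches (where two pressure curves predict the same
    reduced force).
    """

    def fz(lam: float, P: float) -> float:
        return reduced_axial_force(inflate(tube, P, lam))

    crossings = []
    for P1, P2 in itertools.combinations(pressures, 2):
        def diff(lam: float) -> float:
            return fz(lam, P1) - fz(lam, P2)

        lo, hi = bracket
        flo, fhi = diff(lo), diff(hi)
        if flo * fhi > 0:
            raise SolverError(
                f"no reduced-axial-force cross-over between {P1} and {P2} mmHg "
                f"for axial stretch in [{lo}, {hi}]"
            )
        crossings.append(brentq(diff, lo, hi, xtol=1e-10))
    mean = float(np.mean(crossings))
    if return_crossings:
        return mean, crossings
    return mean
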