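"""Stiffness, load partitioning and stored-energy metrics of loaded states.

Two circumferential stiffness measures are computed at a reference
pressure:

* the tangent elastic modulus K along the inflation path,
  K = d t_thetatheta / d eps_thetatheta with eps = lam_theta - 1,
  by central finite difference (+/- 2 mmHg by default);
* the small-on-large linearised stiffness
  C = 2 (t_thetatheta + p) + 4 lam_theta^4 * d^2 Psi / d(lam_theta^2)^2,
  where p is the membrane Lagrange multiplier, lam_theta the layer's total
  circumferential stretch from its stress-free isolated configuration, and
  the second derivative is taken at fixed total axial stretch with the
  radial stretch following incompressibility.

Load bearing is each layer's share of the circumferential force per unit
length, (t^k h^k) / (t^wall h^wall) * 100%, with deformed thicknesses.

The stored elastic energy change over a cardiac cycle is the difference of
strain-energy density (per unit isolated-configuration volume, kPa)
between the systolic and diastolic states; per-unit-length values multiply
by each layer's isolated-configuration cross-sectional area (result in
mJ/mm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .constitutive import (
    DiagonalDeformation,
    HGOParams,
    _psi_derivatives,
    hgo_energy,
    lagrange_multiplier,
    strain_invariants,
)
from .tube_mechanics import TubeState, inflate

__all__ = [
    "MechanicsReport",
    "tangent_stiffness",
    "small_on_large_stiffness",
    "load_bearing",
    "stored_energy",
    "mechanics_report",
]

_KEYS = ("intima", "media", "adventitia", "wall")


def tangent_stiffness(
    tube: TubeState,
    P_ref: float,
    lam_z: float,
    *,
    dP: float = 2.0,
) -> dict[str, float]:
    """Tangent circumferential elastic modulus (MPa) per layer and wall.

    Central finite difference of the circumferential Cauchy stress with
    respect to the engineering circumferential strain (lam_theta - 1)
    along the inflation path, evaluated +/- ``dP`` mmHg around ``P_ref``.
    Per-layer moduli use each layer's mid-layer inflation stretch; the
    wall modulus uses the luminal stretch r_internal / R_internal, the
    strain measure of the wall pressure-stretch relationship.
    """
    if P_ref - dP < 0:
        raise ValueError(f"P_ref = {P_ref} mmHg too close to zero for dP = {dP}")
    lo = inflate(tube, P_ref - dP, lam_z)
    hi = inflate(tube, P_ref + dP, lam_z)
    out: dict[str, float] = {}
    for j, name in enumerate(_KEYS[:3]):
        dt = hi.layer_stresses[j].t_circ - lo.layer_stresses[j].t_circ
        dl = hi.lam_theta[j] - lo.lam_theta[j]
        out[name] = 1e-3 * dt / dl
    dt = hi.wall_stress.t_circ - lo.wall_stress.t_circ
    dl = hi.luminal_circ_stretch - lo.luminal_circ_stretch
    out["wall"] = 1e-3 * dt / dl
    return out


def _d2psi_du2(p: HGOParams, lam_theta: float, lam_ax: float) -> float:
    """Analytic d^2 Psi / d(lam_theta^2)^2 at fixed total axial stretch,
    radial stretch from incompressibility."""
    u = lam_theta**2
    lz2 = lam_ax**2
    ca2 = math.cos(p.alpha_rad) ** 2
    i1 = u + 1.0 / (u * lz2) + lz2
    i4 = u * ca2 + lz2 * (1.0 - ca2)
    i1p = 1.0 - 1.0 / (u**2 * lz2)
    i1pp = 2.0 / (u**3 * lz2)
    e = p.rho * i1 + (1.0 - 3.0 * p.rho) * i4 - 1.0
    ep = p.rho * i1p + (1.0 - 3.0 * p.rho) * ca2
    epp = p.rho * i1pp
    # fibre chain A(E) = 2 c1 E exp(c2 E^2); Psi_1 = mu + rho A, Psi_4 = (1-3rho) A
    expo = math.exp(p.c2 * e * e)
    A = 2.0 * p.c1 * e * expo
    dA_dE = 2.0 * p.c1 * expo * (1.0 + 2.0 * p.c2 * e * e)
    # dPsi/du = (mu + rho A) i1p + (1-3rho) A ca2 = mu i1p + A ep
    # d2Psi/du2 = mu i1pp + dA/dE ep^2 + A epp
    return p.mu * i1pp + dA_dE * ep * ep + A * epp


def small_on_large_stiffness(
    tube: TubeState,
    P_ref: float,
    lam_z: float,
) -> dict[str, float]:
    """Small-on-large circumferential stiffness (MPa) per layer and wall.

    Per layer, C = 2 (t_thetatheta + p) + 4 lam_theta^4 d^2Psi/d(lam^2)^2
    with the layer's total circumferential stretch; the wall value is the
    deformed-thickness-weighted average.
    """
    state = inflate(tube, P_ref, lam_z)
    out: dict[str, float] = {}
    vals = np.empty(3)
    for j, name in enumerate(_KEYS[:3]):
        layer = state.wall.layers[j]
        F = state.layer_deformations[j]
        t = state.layer_stresses[j].t_circ
        p_mult = lagrange_multiplier(layer.params, F)
        d2 = _d2psi_du2(layer.params, F.lam_circ, F.lam_ax)
        c = 2.0 * (t + p_mult) + 4.0 * F.lam_circ**4 * d2
        vals[j] = c
        out[name] = 1e-3 * c
    h = state.deformed_thicknesses
    out["wall"] = 1e-3 * float(np.dot(h, vals) / h.sum())
    return out


def load_bearing(state: TubeState) -> dict[str, float]:
    """Percentage of circumferential load borne by each layer.

    (t_thetatheta^k h^k) / (t_thetatheta^wall h^wall) * 100; the three
    shares sum to 100 by construction.
    """
    h = state.deformed_thicknesses
    t_wall = state.wall_stress.t_circ
    if t_wall == 0.0:
        raise ZeroDivisionError("wall circumferential stress is zero; load shares undefined")
    denom = t_wall * h.sum()
    return {
        name: 100.0 * state.layer_stresses[j].t_circ * h[j] / denom
        for j, name in enumerate(_KEYS[:3])
    }


def stored_energy(
    tube: TubeState,
    P_dia: float,
    P_sys: float,
    lam_z: float,
) -> dict[str, dict[str, float]]:
    """Stored elastic energy change over a simulated cardiac cycle.

    Returns, per layer: ``delta_psi`` (kPa, per unit isolated-configuration
    volume), ``per_length`` (mJ/mm, delta_psi times the isolated
    cross-sectional area) and ``fraction`` (% of the three-layer
    per-length total).
    """
    if P_sys < P_dia:
        raise ValueError(f"P_sys ({P_sys}) must not be below P_dia ({P_dia})")
    dia = inflate(tube, P_dia, lam_z)
    sys_ = inflate(tube, P_sys, lam_z)
    l_x = tube.l_x
    dpsi = np.empty(3)
    area = np.empty(3)
    for j, layer in enumerate(tube.wall.layers):
        dpsi[j] = hgo_energy(layer.params, sys_.layer_deformations[j]) - hgo_energy(
            layer.params, dia.layer_deformations[j]
        )
        # isolated cross-section: thickness x circumferential length L_X = l_x / gx
        area[j] = layer.thickness * l_x / layer.prestretch_circ
    per_len = 1e-3 * dpsi * area  # kPa*mm^2 -> mJ/mm
    total = per_len.sum()
    out: dict[str, dict[str, float]] = {}
    for j, name in enumerate(_KEYS[:3]):
        out[name] = {
            "delta_psi": float(dpsi[j]),
            "per_length": float(per_len[j]),
            "fraction": float(100.0 * per_len[j] / total) if total != 0 else float("nan"),
        }
    return out


@dataclass(frozen=True)
class MechanicsReport:
    """Layer-resolved mechanics at a reference pressure plus cycle energy."""

    pressure: float                    # mmHg
    lam_z: float
    luminal_circ_stretch: float
    stresses_circ: Mapping[str, float]     # kPa, keys intima/media/adventitia/wall
    stresses_ax: Mapping[str, float]       # kPa
    tangent_stiffness: Mapping[str, float]     # MPa
    small_on_large: Mapping[str, float]        # MPa
    structural_tangent: Mapping[str, float]    # MPa*mm (K * deformed thickness)
    structural_small_on_large: Mapping[str, float]  # MPa*mm
    load_bearing: Mapping[str, float]          # %
    energy: Mapping[str, Mapping[str, float]]  # per-layer cycle energy
    cycle: tuple[float, float]                 # (P_dia, P_sys) mmHg

    def to_rows(self) -> list[dict[str, float | str]]:
        rows = []
        for name in _KEYS:
            row: dict[str, float | str] = {
                "component": name,
                "t_circ_kpa": self.stresses_circ[name],
                "t_ax_kpa": self.stresses_ax[name],
                "K_mpa": self.tangent_stiffness[name],
                "C_mpa": self.small_on_large[name],
                "Kh_mpa_mm": self.structural_tangent[name],
                "Ch_mpa_mm": self.structural_small_on_large[name],
            }
            if name != "wall":
                row["load_bearing_pct"] = self.load_bearing[name]
                row["delta_psi_kpa"] = self.energy[name]["delta_psi"]
                row["energy_per_length_mj_mm"] = self.energy[name]["per_length"]
                row["energy_fraction_pct"] = self.energy[name]["fraction"]
            rows.append(row)
        return rows

    def to_text(self) -> str:
        lines = [
            f"reference pressure {self.pressure:g} mmHg, axial stretch "
            f"{self.lam_z:.4f}, luminal circ stretch {self.luminal_circ_stretch:.4f}",
            f"cardiac cycle {self.cycle[1]:g}/{self.cycle[0]:g} mmHg",
            f"{'':12s}{'t_circ':>9s}{'t_ax':>9s}{'K':>8s}{'C':>8s}"
            f"{'load':>8s}{'dPsi':>8s}{'E frac':>8s}",
            f"{'':12s}{'kPa':>9s}{'kPa':>9s}{'MPa':>8s}{'MPa':>8s}"
            f"{'%':>8s}{'kPa':>8s}{'%':>8s}",
        ]
        for name in _KEYS:
            cells = (
                f"{name:12s}"
                f"{self.stresses_circ[name]:9.1f}"
                f"{self.stresses_ax[name]:9.1f}"
                f"{self.tangent_stiffness[name]:8.3f}"
                f"{self.small_on_large[name]:8.3f}"
            )
            if name != "wall":
                cells += (
                    f"{self.load_bearing[name]:8.1f}"
                    f"{self.energy[name]['delta_psi']:8.2f}"
                    f"{self.energy[name]['fraction']:8.1f}"
                )
            lines.append(cells)
        return "\n".join(lines)


def mechanics_report(
    tube: TubeState,
    P_ref: float,
    lam_z: float,
    *,
    cycle: tuple[float, float] = (80.0, 120.0),
) -> MechanicsReport:
    """Assemble the full layer-resolved mechanics report at ``P_ref``."""
    state = inflate(tube, P_ref, lam_z)
    k = tangent_stiffness(tube, P_ref, lam_z)
    c = small_on_large_stiffness(tube, P_ref, lam_z)
    h = state.deformed_thicknesses
    h_map = dict(zip(_KEYS[:3], h)) | {"wall": float(h.sum())}
    stresses_c = {
        name: state.layer_stresses[j].t_circ for j, name in enumerate(_KEYS[:3])
    } | {"wall": state.wall_stress.t_circ}
    stresses_a = {
        name: state.layer_stresses[j].t_ax for j, name in enumerate(_KEYS[:3])
    } | {"wall": state.wall_stress.t_ax}
    return MechanicsReport(
        pressure=P_ref,
        lam_z=lam_z,
        luminal_circ_stretch=state.luminal_circ_stretch,
        stresses_circ=stresses_c,
        stresses_ax=stresses_a,
        tangent_stiffness=k,
        small_on_large=c,
        structural_tangent={n: k[n] * h_map[n] for n in _KEYS},
        structural_small_on_large={n: c[n] * h_map[n] for n in _KEYS},
        load_bearing=load_bearing(state),
        energy=stored_energy(tube, cycle[0], cycle[1], lam_z),
        cycle=cycle,
    )
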