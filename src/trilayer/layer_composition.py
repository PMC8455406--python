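"""Composition of three fitted arterial layers into a flat composite wall.

Each layer carries a diagonal prestretch tensor ``G^k = diag(gx, 1/(gx gz),
gz)`` describing the deformation the isolated layer undergoes when
constrained within the intact flat wall.  A shared wall deformation applies
in-plane stretches multiplicatively on top of each layer's prestretch; each
layer's radial stretch follows from its own incompressibility.  The wall
Cauchy stress is the deformed-thickness-weighted average of the layer
stresses.

The prestretch estimator recovers the six in-plane prestretch components
from whole-wall uniaxial stress-stretch curves in both directions, inside a
constraint box (by default experimentally measured means +/- 3 SD).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq, least_squares
from scipy.stats import qmc

from .constitutive import (
    DiagonalDeformation,
    DomainError,
    HGOParams,
    SolverError,
    StressTriple,
    membrane_stress,
)
from .uniaxial_fit import UniaxialCurve, resample_curve

__all__ = [
    "LayerSpec",
    "WallModel",
    "PrestretchFitResult",
    "LAYER_NAMES",
    "DEFAULT_PRESTRETCH_BOX",
    "composite_wall_stress",
    "wall_uniaxial_state",
    "wall_uniaxial_stress_curve",
    "fit_prestretches",
]

LAYER_NAMES = ("intima", "media", "adventitia")

# Experimentally measured prestretch components (mean, SD) on a separate
# cohort of porcine thoracic aortas; the fit is constrained to mean +/- 3 SD.
EXPERIMENTAL_PRESTRETCHES: Mapping[str, tuple[tuple[float, float], tuple[float, float]]] = {
    # layer: ((circ mean, circ SD), (ax mean, ax SD))
    "intima": ((1.00, 0.01), (1.00, 0.01)),
    "media": ((1.00, 0.01), (0.98, 0.02)),
    "adventitia": ((0.93, 0.02), (1.01, 0.01)),
}


def _box_from_experiments(n_sd: float = 3.0) -> dict[str, tuple[tuple[float, float], tuple[float, float]]]:
    box = {}
    for name, ((mx, sx), (mz, sz)) in EXPERIMENTAL_PRESTRETCHES.items():
        box[name] = (
            (mx - n_sd * sx, mx + n_sd * sx),
            (mz - n_sd * sz, mz + n_sd * sz),
        )
    return box


#: Default constraint box for the prestretch fit: per layer,
#: ((circ lo, circ hi), (ax lo, ax hi)) from experimental means +/- 3 SD.
DEFAULT_PRESTRETCH_BOX = _box_from_experiments()


@dataclass(frozen=True)
class LayerSpec:
    """One arterial layer: constitutive parameters, isolated thickness (mm)
    and in-plane prestretch components of G^k."""

    name: str
    thickness: float
    params: HGOParams
    prestretch_circ: float = 1.0
    prestretch_ax: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in LAYER_NAMES:
            raise DomainError(f"layer name must be one of {LAYER_NAMES}, got {self.name!r}")
        if not (self.thickness >= 0):
            raise DomainError(f"thickness must be >= 0, got {self.thickness}")
        for f in ("prestretch_circ", "prestretch_ax"):
            v = getattr(self, f)
            if not (0.5 < v < 1.5):
                raise DomainError(f"{f} = {v} outside plausible range (0.5, 1.5)")

    @property
    def prestretch(self) -> DiagonalDeformation:
        """G^k as a volume-preserving diagonal deformation."""
        return DiagonalDeformation.from_in_plane(self.prestretch_circ, self.prestretch_ax)

    @property
    def composite_thickness(self) -> float:
        """Thickness in the composite-wall configuration (mm), from
        incompressibility: h = H / (gx * gz)."""
        return self.thickness / (self.prestretch_circ * self.prestretch_ax)


@dataclass(frozen=True)
class WallModel:
    """Tri-layered flat wall: intima, media, adventitia (inner to outer)
    plus the measured unloaded internal radius (mm)."""

    layers: tuple[LayerSpec, LayerSpec, LayerSpec]
    unloaded_internal_radius: float

    def __post_init__(self) -> None:
        names = tuple(l.name for l in self.layers)
        if names != LAYER_NAMES:
            raise DomainError(f"layers must be ordered {LAYER_NAMES}, got {names}")
        if not (self.unloaded_internal_radius > 0):
            raise DomainError("unloaded_internal_radius must be > 0")

    @property
    def wall_thickness(self) -> float:
        """Composite-wall thickness (mm): sum of composite layer thicknesses."""
        return sum(l.composite_thickness for l in self.layers)

    @property
    def isolated_thickness(self) -> float:
        return sum(l.thickness for l in self.layers)

    def with_prestretches(self, values: Sequence[float]) -> "WallModel":
        """New model with prestretches (gx_i, gz_i, gx_m, gz_m, gx_a, gz_a)."""
        gx_i, gz_i, gx_m, gz_m, gx_a, gz_a = values
        new = tuple(
            replace(l, prestretch_circ=gx, prestretch_ax=gz)
            for l, gx, gz in zip(self.layers, (gx_i, gx_m, gx_a), (gz_i, gz_m, gz_a))
        )
        return replace(self, layers=new)

    def without_prestretches(self) -> "WallModel":
        return self.with_prestretches([1.0] * 6)

    @property
    def prestretch_vector(self) -> np.ndarray:
        return np.array(
            [v for l in self.layers for v in (l.prestretch_circ, l.prestretch_ax)]
        )


def _layer_states(
    wall: WallModel, lam_x: float, lam_z: float
) -> tuple[list[StressTriple], np.ndarray]:
    """Per-layer membrane stresses and deformed thicknesses (mm) under
    shared in-plane wall stretches (lam_x, lam_z) applied on top of G^k."""
    stresses: list[StressTriple] = []
    h_def = np.empty(3)
    for j, layer in enumerate(wall.layers):
        lc = lam_x * layer.prestretch_circ
        la = lam_z * layer.prestretch_ax
        F = DiagonalDeformation.from_in_plane(lc, la)
        stresses.append(membrane_stress(layer.params, F))
        h_def[j] = layer.thickness * F.lam_rad
    return stresses, h_def


def composite_wall_stress(wall: WallModel, F3_wall: DiagonalDeformation) -> StressTriple:
    """Average Cauchy stress of the composite wall under a shared wall
    deformation.

    Only the in-plane components of ``F3_wall`` act on the layers; each
    layer's radial stretch follows from its own incompressibility.  The
    average is weighted by deformed layer thicknesses, which by
    construction sum to the deformed wall thickness.
    """
    stresses, h_def = _layer_states(wall, F3_wall.lam_circ, F3_wall.lam_ax)
    h_wall = h_def.sum()
    t_circ = sum(h * s.t_circ for h, s in zip(h_def, stresses)) / h_wall
    t_ax = sum(h * s.t_ax for h, s in zip(h_def, stresses)) / h_wall
    return StressTriple(t_circ, 0.0, t_ax)


def wall_uniaxial_state(
    wall: WallModel,
    direction: str,
    lam_load: float,
    *,
    bracket: tuple[float, float] = (0.3, 1.5),
    xtol: float = 1e-10,
) -> tuple[float, float]:
    """Uniaxial stress state of the composite wall.

    The transverse in-plane wall stretch is solved so the *average*
    transverse wall stress vanishes (individual layers generally carry
    non-zero, self-equilibrating transverse stresses).  Returns
    ``(t_load [kPa], lam_transverse)``.
    """
    if direction not in ("circ", "ax"):
        raise DomainError(f"direction must be 'circ' or 'ax', got {direction!r}")
    if lam_load == 1.0 and all(
        l.prestretch_circ == 1.0 and l.prestretch_ax == 1.0 for l in wall.layers
    ):
        return 0.0, 1.0

    def trans_stress(x: float) -> float:
        if direction == "circ":
            t = composite_wall_stress(wall, DiagonalDeformation.from_in_plane(lam_load, x))
            return t.t_ax
        t = composite_wall_stress(wall, DiagonalDeformation.from_in_plane(x, lam_load))
        return t.t_circ

    lo, hi = bracket
    flo, fhi = trans_stress(lo), trans_stress(hi)
    if (flo > 0) == (fhi > 0):
        raise SolverError(
            f"no wall transverse-stress sign change in [{lo}, {hi}] "
            f"for direction={direction}, lam_load={lam_load}"
        )
    lam_t = brentq(trans_stress, lo, hi, xtol=xtol)
    if direction == "circ":
        t = composite_wall_stress(wall, DiagonalDeformation.from_in_plane(lam_load, lam_t))
        return t.t_circ, lam_t
    t = composite_wall_stress(wall, DiagonalDeformation.from_in_plane(lam_t, lam_load))
    return t.t_ax, lam_t


def wall_uniaxial_stress_curve(
    wall: WallModel, direction: str, stretches: np.ndarray
) -> np.ndarray:
    """Wall uniaxial loading-direction stress (kPa) at each stretch."""
    stretches = np.asarray(stretches, dtype=float)
    return np.array(
        [wall_uniaxial_state(wall, direction, float(l))[0] for l in stretches]
    )


@dataclass(frozen=True)
class PrestretchFitResult:
    """Outcome of the prestretch estimation against whole-wall curves."""

    wall: WallModel
    r_squared: float
    cost: float
    n_restarts_used: int
    converged: bool


def _box_bounds(
    box: Mapping[str, tuple[tuple[float, float], tuple[float, float]]],
) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = [], []
    for name in LAYER_NAMES:
        (xlo, xhi), (zlo, zhi) = box[name]
        lo += [xlo, zlo]
        hi += [xhi, zhi]
    lo, hi = np.array(lo), np.array(hi)
    if np.any(lo >= hi):
        raise DomainError("infeasible prestretch constraint box (lo >= hi)")
    return lo, hi


def fit_prestretches(
    layers: Sequence[LayerSpec],
    wall_circ: UniaxialCurve,
    wall_ax: UniaxialCurve,
    *,
    unloaded_internal_radius: float,
    constraints: Mapping[str, tuple[tuple[float, float], tuple[float, float]]]
    | None = None,
    n_restarts: int = 5,
    n_resample: int = 50,
    seed: int | None = 0,
) -> PrestretchFitResult:
    """Estimate the six in-plane prestretch components of G^k.

    Minimises the summed squared error between measured and modelled wall
    stresses in both directions simultaneously (curves resampled at
    ``n_resample`` equal stretch increments), with bounded least squares
    and seeded Latin-hypercube restarts inside the constraint box.
    """
    box = DEFAULT_PRESTRETCH_BOX if constraints is None else constraints
    lo, hi = _box_bounds(box)
    base = WallModel(tuple(layers), unloaded_internal_radius)

    circ = resample_curve(wall_circ, n_resample)
    ax = resample_curve(wall_ax, n_resample)
    obs = np.concatenate([circ.stress, ax.stress])

    def residuals(g: np.ndarray) -> np.ndarray:
        wall = base.with_prestretches(g)
        try:
            mod_c = wall_uniaxial_stress_curve(wall, "circ", circ.stretch)
            mod_a = wall_uniaxial_stress_curve(wall, "ax", ax.stretch)
        except (SolverError, FloatingPointError):
            return np.full(obs.size, 1e6)
        res = np.concatenate([mod_c, mod_a]) - obs
        return np.where(np.isfinite(res), res, 1e6)

    rng = np.random.default_rng(seed)
    starts = [np.clip(np.ones(6), lo + 1e-9, hi - 1e-9)]
    if n_restarts > 1:
        sampler = qmc.LatinHypercube(d=6, seed=rng)
        starts += list(lo + sampler.random(n_restarts - 1) * (hi - lo))

    best = None
    n_used = 0
    for x0 in starts:
        n_used += 1
        sol = least_squares(residuals, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12)
        if best is None or sol.cost < best.cost:
            best = sol
    assert best is not None
    if not best.success and best.cost > 1e-6:
        raise SolverError(
            f"prestretch fit failed to converge; best cost {2 * best.cost:.4g} kPa^2"
        )

    wall = base.with_prestretches(best.x)
    res = residuals(best.x)
    ss_res = float(res @ res)
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return PrestretchFitResult(
        wall=wall, r_squared=r2, cost=ss_res, n_restarts_used=n_used,
        converged=bool(best.success),
    )
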