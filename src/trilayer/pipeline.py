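"""End-to-end workflows chaining fitting, composition, closure, inflation
and metrics.

Two entry points:

* :func:`evaluate_wall_mechanics` takes a fully specified wall model
  (parameters + prestretches + geometry), closes it, locates the in-vivo
  axial stretch and reports the physiological mechanics at the reference
  pressures (100 and 160 mmHg by default) plus cardiac-cycle energies and
  the no-prestretch comparison case.
* :func:`run_full_pipeline` starts from uniaxial curves (six layer curves
  plus two wall curves), fits layer parameters and prestretches, then
  calls :func:`evaluate_wall_mechanics`.

Group-level summaries of a cohort of wall models are means of the
per-model evaluations (:func:`evaluate_cohort`).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .layer_composition import (
    LayerSpec,
    PrestretchFitResult,
    WallModel,
    fit_prestretches,
)
from .metrics import (
    load_bearing,
    small_on_large_stiffness,
    stored_energy,
    tangent_stiffness,
)
from .tube_mechanics import (
    TubeState,
    close_vessel,
    estimate_in_vivo_stretch,
    inflate,
)
from .uniaxial_fit import FitResult, UniaxialCurve, fit_layer

__all__ = [
    "WallMechanicsSummary",
    "PipelineResult",
    "evaluate_wall_mechanics",
    "evaluate_cohort",
    "run_full_pipeline",
]

_LAYERS = ("intima", "media", "adventitia")


@dataclass(frozen=True)
class WallMechanicsSummary:
    """Scalar outcomes of the tension-inflation analysis of one wall model.

    Stresses kPa, stiffnesses MPa, shares %, energies kPa (density) and
    mJ/mm (per length); ``no_prestretch_*`` fields describe the comparison
    case with all prestretch tensors set to identity.
    """

    in_vivo_axial_stretch: float
    crossover_stretches: tuple[float, float, float]
    closure_Lam_Theta: tuple[float, float, float]
    closure_Lam_Z: float
    intima_residual_circ_stretch: float   # Lam_Theta_intima * prestretch_circ_intima
    luminal_stretch: dict[float, float]   # by pressure (mmHg)
    wall_stress_circ: dict[float, float]
    wall_stress_ax: dict[float, float]
    layer_stress_circ: dict[float, dict[str, float]]
    layer_stress_ax: dict[float, dict[str, float]]
    tangent_stiffness: dict[float, dict[str, float]]
    small_on_large: dict[float, dict[str, float]]
    load_bearing: dict[float, dict[str, float]]
    energy_normotensive: dict[str, dict[str, float]]   # 120/80 mmHg cycle
    energy_hypertensive: dict[str, dict[str, float]]   # 160/100 mmHg cycle
    no_prestretch_layer_stress_circ: dict[str, float]  # at the first reference pressure
    no_prestretch_load_bearing: dict[str, float]

    def flat(self) -> dict[str, float]:
        """Flatten to scalar key/value pairs (for CSV/JSON reporting)."""
        out: dict[str, float] = {
            "in_vivo_axial_stretch": self.in_vivo_axial_stretch,
            "closure_Lam_Z": self.closure_Lam_Z,
            "intima_residual_circ_stretch": self.intima_residual_circ_stretch,
        }
        for j, name in enumerate(_LAYERS):
            out[f"closure_Lam_Theta_{name}"] = self.closure_Lam_Theta[j]
        for P in self.wall_stress_circ:
            tag = f"{P:g}mmHg"
            out[f"luminal_stretch_{tag}"] = self.luminal_stretch[P]
            out[f"wall_stress_circ_kpa_{tag}"] = self.wall_stress_circ[P]
            out[f"wall_stress_ax_kpa_{tag}"] = self.wall_stress_ax[P]
            for name in _LAYERS:
                out[f"stress_circ_kpa_{name}_{tag}"] = self.layer_stress_circ[P][name]
                out[f"stress_ax_kpa_{name}_{tag}"] = self.layer_stress_ax[P][name]
                out[f"load_bearing_pct_{name}_{tag}"] = self.load_bearing[P][name]
            for name in (*_LAYERS, "wall"):
                out[f"K_mpa_{name}_{tag}"] = self.tangent_stiffness[P][name]
                out[f"C_mpa_{name}_{tag}"] = self.small_on_large[P][name]
        for cyc, tag in ((self.energy_normotensive, "120_80"),
                         (self.energy_hypertensive, "160_100")):
            for name in _LAYERS:
                out[f"delta_psi_kpa_{name}_{tag}"] = cyc[name]["delta_psi"]
                out[f"energy_fraction_pct_{name}_{tag}"] = cyc[name]["fraction"]
        for name in _LAYERS:
            out[f"no_prestretch_stress_circ_kpa_{name}"] = (
                self.no_prestretch_layer_stress_circ[name]
            )
            out[f"no_prestretch_load_bearing_pct_{name}"] = (
                self.no_prestretch_load_bearing[name]
            )
        return out


def evaluate_wall_mechanics(
    wall: WallModel,
    *,
    reference_pressures: Sequence[float] = (100.0, 160.0),
    crossover_pressures: tuple[float, float, float] = (60.0, 100.0, 140.0),
    cycles: tuple[tuple[float, float], tuple[float, float]] = ((80.0, 120.0), (100.0, 160.0)),
    anchor: str = "closed_radius",
) -> WallMechanicsSummary:
    """Close, find the in-vivo axial stretch, inflate and report mechanics."""
    tube = close_vessel(wall, anchor=anchor)
    lam_z, crossings = estimate_in_vivo_stretch(
        tube, pressures=crossover_pressures, return_crossings=True
    )

    lum, wc, wa = {}, {}, {}
    lsc: dict[float, dict[str, float]] = {}
    lsa: dict[float, dict[str, float]] = {}
    kk: dict[float, dict[str, float]] = {}
    cc: dict[float, dict[str, float]] = {}
    lb: dict[float, dict[str, float]] = {}
    for P in reference_pressures:
        state = inflate(tube, P, lam_z)
        lum[P] = state.luminal_circ_stretch
        wc[P] = state.wall_stress.t_circ
        wa[P] = state.wall_stress.t_ax
        lsc[P] = {n: state.layer_stresses[j].t_circ for j, n in enumerate(_LAYERS)}
        lsa[P] = {n: state.layer_stresses[j].t_ax for j, n in enumerate(_LAYERS)}
        kk[P] = tangent_stiffness(tube, P, lam_z)
        cc[P] = small_on_large_stiffness(tube, P, lam_z)
        lb[P] = load_bearing(state)

    P0 = reference_pressures[0]
    tube0 = close_vessel(wall, prestretch=False)
    state0 = inflate(tube0, P0, lam_z)

    return WallMechanicsSummary(
        in_vivo_axial_stretch=lam_z,
        crossover_stretches=tuple(crossings),
        closure_Lam_Theta=tuple(tube.Lam_Theta),
        closure_Lam_Z=tube.Lam_Z,
        intima_residual_circ_stretch=float(
            tube.Lam_Theta[0] * wall.layers[0].prestretch_circ
        ),
        luminal_stretch=lum,
        wall_stress_circ=wc,
        wall_stress_ax=wa,
        layer_stress_circ=lsc,
        layer_stress_ax=lsa,
        tangent_stiffness=kk,
        small_on_large=cc,
        load_bearing=lb,
        energy_normotensive=stored_energy(tube, cycles[0][0], cycles[0][1], lam_z),
        energy_hypertensive=stored_energy(tube, cycles[1][0], cycles[1][1], lam_z),
        no_prestretch_layer_stress_circ={
            n: state0.layer_stresses[j].t_circ for j, n in enumerate(_LAYERS)
        },
        no_prestretch_load_bearing=load_bearing(state0),
    )


def evaluate_cohort(
    walls: Mapping[str, WallModel], **kwargs
) -> tuple[dict[str, float], dict[str, WallMechanicsSummary]]:
    """Evaluate each wall model and average the flattened scalar outcomes.

    Returns (group means, per-model summaries); group-level results are
    means of per-model outputs.
    """
    summaries = {k: evaluate_wall_mechanics(w, **kwargs) for k, w in walls.items()}
    flats = [s.flat() for s in summaries.values()]
    means = {k: float(np.mean([f[k] for f in flats])) for k in flats[0]}
    return means, summaries


@dataclass(frozen=True)
class PipelineResult:
    """Everything produced by the curve-to-mechanics pipeline."""

    layer_fits: dict[str, FitResult]
    prestretch_fit: PrestretchFitResult
    wall: WallModel
    summary: WallMechanicsSummary
    seed: int | None = field(default=None)


def run_full_pipeline(
    layer_curves: Mapping[str, tuple[UniaxialCurve, UniaxialCurve]],
    wall_curves: tuple[UniaxialCurve, UniaxialCurve],
    *,
    thicknesses: Mapping[str, float],
    unloaded_internal_radius: float,
    seed: int | None = 0,
    n_restarts: int = 10,
    prestretch: bool = True,
    **evaluate_kwargs,
) -> PipelineResult:
    """Fit layers, estimate prestretches and evaluate in-vivo mechanics.

    ``layer_curves`` maps layer name to (circ, ax) curves; ``wall_curves``
    is the whole-wall (circ, ax) pair.  With ``prestretch=False`` the
    prestretch estimation is skipped and the comparison case (all
    prestretches = 1) is evaluated.
    """
    fits: dict[str, FitResult] = {}
    layers: list[LayerSpec] = []
    for name in _LAYERS:
        circ, ax = layer_curves[name]
        fits[name] = fit_layer(circ, ax, seed=seed, n_restarts=n_restarts)
        layers.append(
            LayerSpec(name=name, thickness=thicknesses[name], params=fits[name].params)
        )

    if prestretch:
        pfit = fit_prestretches(
            layers,
            wall_curves[0],
            wall_curves[1],
            unloaded_internal_radius=unloaded_internal_radius,
            seed=seed,
        )
        wall = pfit.wall
    else:
        wall = WallModel(tuple(layers), unloaded_internal_radius)
        # degenerate "fit": identity prestretches, no search performed
        pfit = PrestretchFitResult(
            wall=wall, r_squared=float("nan"), cost=float("nan"),
            n_restarts_used=0, converged=True,
        )
    summary = evaluate_wall_mechanics(wall, **evaluate_kwargs)
    return PipelineResult(
        layer_fits=fits, prestretch_fit=pfit, wall=wall, summary=summary, seed=seed
    )
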