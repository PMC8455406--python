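"""Synthetic uniaxial curves and wall datasets with known ground truth.

The generator runs the HGO forward model (uniaxial membrane state for
isolated layers, composite average stress for the intact wall) up to a
peak Cauchy stress cap and perturbs the stresses with seeded
multiplicative Gaussian noise, emulating the relative error of a uniaxial
load cell.  Defaults reproduce the study conditions of the packaged
porcine dataset: average-response layer parameters, modelled prestretches
and a 250 kPa stress cap.  Jaw-mounting artefacts, preconditioning
hysteresis and peeling damage are not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .constitutive import DomainError, SolverError, uniaxial_state
from .layer_composition import WallModel, wall_uniaxial_state
from .reference import reference_wall_model
from .uniaxial_fit import UniaxialCurve

__all__ = ["SyntheticSpec", "generate_layer_curves", "generate_wall_dataset"]

_MAX_CAP_STRETCH = 2.0
_NOISE_FLOOR_KPA = 0.1  # stresses below this get the floor's noise scale

# independent, order-insensitive noise streams per curve family
_STREAM_INDEX = {"intima": 0, "media": 1, "adventitia": 2, "wall": 3}


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAM_INDEX[name]])


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions of a synthetic uniaxial experiment.

    ``wall`` supplies per-layer parameters, thicknesses and the ground-truth
    prestretches; curves stop where the noise-free stress reaches
    ``stress_cap`` (kPa).  ``noise_cv`` is the relative (multiplicative)
    noise level.
    """

    wall: WallModel = field(default_factory=reference_wall_model)
    noise_cv: float = 0.02
    stress_cap: float = 250.0
    n_points: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise DomainError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if not (self.stress_cap > 0):
            raise DomainError(f"stress_cap must be > 0, got {self.stress_cap}")
        if self.n_points < 10:
            raise DomainError(f"n_points must be >= 10, got {self.n_points}")

    def layer(self, name: str):
        for l in self.wall.layers:
            if l.name == name:
                return l
        raise DomainError(f"unknown layer {name!r}")


def _cap_stretch(stress_at, cap: float) -> float:
    """Stretch at which the noise-free stress reaches ``cap`` kPa."""
    hi = 1.0 + 1e-3
    while stress_at(hi) < cap:
        hi += 0.05
        if hi > _MAX_CAP_STRETCH:
            raise SolverError(
                f"stress cap {cap} kPa unreachable below stretch {_MAX_CAP_STRETCH}"
            )
    return brentq(lambda l: stress_at(l) - cap, 1.0 + 1e-6, hi, xtol=1e-10)


def _noisy_curve(
    direction: str, stress_at, spec: SyntheticSpec, rng: np.random.Generator
) -> UniaxialCurve:
    lam_max = _cap_stretch(stress_at, spec.stress_cap)
    stretch = np.linspace(1.0, lam_max, spec.n_points)
    stress = np.array([stress_at(float(l)) for l in stretch])
    if spec.noise_cv > 0:
        eps = rng.normal(0.0, 1.0, size=stress.size)
        sigma = spec.noise_cv * np.maximum(stress, _NOISE_FLOOR_KPA)
        stress = np.clip(stress + sigma * eps, 0.0, None)
        stress[0] = 0.0  # the unloaded point is exact by definition
    return UniaxialCurve(direction, stretch, stress, source="synthetic")


def generate_layer_curves(
    spec: SyntheticSpec, layer_name: str
) -> tuple[UniaxialCurve, UniaxialCurve]:
    """Synthetic circumferential and axial uniaxial curves for one layer."""
    params = spec.layer(layer_name).params
    rng_layer = _stream(spec.seed, layer_name)
    circ = _noisy_curve(
        "circ", lambda l: uniaxial_state(params, "circ", l)[0], spec, rng_layer
    )
    ax = _noisy_curve(
        "ax", lambda l: uniaxial_state(params, "ax", l)[0], spec, rng_layer
    )
    return circ, ax


def generate_wall_dataset(
    spec: SyntheticSpec,
) -> tuple[
    tuple[UniaxialCurve, UniaxialCurve],
    dict[str, tuple[UniaxialCurve, UniaxialCurve]],
    WallModel,
]:
    """Full synthetic dataset: wall curves, per-layer curve pairs and the
    ground-truth wall model (for recovery experiments)."""
    layer_curves = {
        name: generate_layer_curves(spec, name)
        for name in ("intima", "media", "adventitia")
        if spec.layer(name).thickness > 0
    }
    wall_stream = _stream(spec.seed, "wall")
    wall = spec.wall
    wall_circ = _noisy_curve(
        "circ", lambda l: wall_uniaxial_state(wall, "circ", l)[0], spec, wall_stream
    )
    wall_ax = _noisy_curve(
        "ax", lambda l: wall_uniaxial_state(wall, "ax", l)[0], spec, wall_stream
    )
    return (wall_circ, wall_ax), layer_curves, wall
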