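"""Packaged reference dataset: porcine upper thoracic aorta (n = 10).

Two parameter views are shipped:

* the *average-response* model — one HGO parameter set per layer, fitted
  to the cohort-average uniaxial response (a convenient single fixture);
* the *per-animal cohort* — the ten layer-specific parameter sets, from
  which group-level results are obtained by averaging the per-animal
  model outputs (the cohort's reported statistics are means of per-animal
  models, not outputs of an averaged model).

Both share the modelled in-plane prestretches, mean layer thicknesses
(0.33 / 1.35 / 0.61 mm) and mean unloaded internal radius (8.66 mm).
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import yaml

from .constitutive import HGOParams
from .io import wall_model_from_dict
from .layer_composition import LAYER_NAMES, WallModel

__all__ = [
    "reference_wall_model",
    "cohort_parameter_sets",
    "cohort_wall_models",
    "REFERENCE_DATASET",
]

REFERENCE_DATASET = "porcine_thoracic_aorta"


def _read_packaged(name: str) -> dict:
    text = resources.files("trilayer.data").joinpath(f"{name}.yaml").read_text()
    return yaml.safe_load(text)


def reference_wall_model(*, prestretch: bool = True) -> WallModel:
    """The packaged average-response tri-layered wall model.

    With ``prestretch=False`` the same constitutive inputs are returned
    with all layer prestretches set to 1 (the no-residual-deformation
    comparison case).
    """
    wall = wall_model_from_dict(_read_packaged(REFERENCE_DATASET))
    return wall if prestretch else wall.without_prestretches()


def cohort_parameter_sets() -> dict[str, dict[str, HGOParams]]:
    """Per-animal HGO parameter sets, keyed by sample id then layer name."""
    raw = _read_packaged(f"{REFERENCE_DATASET}_cohort")["samples"]
    out: dict[str, dict[str, HGOParams]] = {}
    for sample, layers in raw.items():
        out[sample] = {
            name: HGOParams(
                mu=layers[name]["mu_kpa"],
                c1=layers[name]["c1_kpa"],
                c2=layers[name]["c2"],
                alpha_deg=layers[name]["alpha_deg"],
                rho=layers[name]["rho"],
            )
            for name in LAYER_NAMES
        }
    return out


def cohort_wall_models() -> dict[str, WallModel]:
    """Ten per-animal wall models: per-animal constitutive parameters with
    the cohort-mean prestretches and geometry (the per-animal prestretch
    fits are summarised only as means)."""
    base = reference_wall_model()
    out: dict[str, WallModel] = {}
    for sample, params in cohort_parameter_sets().items():
        layers = tuple(
            dataclasses.replace(l, params=params[l.name]) for l in base.layers
        )
        out[sample] = dataclasses.replace(base, layers=layers)
    return out
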