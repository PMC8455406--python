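"""File formats: uniaxial-curve CSV and wall-model YAML.

Curve CSV dialect: comma-separated, dot decimal, UTF-8, mandatory header
``stretch,stress_kpa,direction`` (direction in {circ, ax}); one file may
hold one or both directions.  Wall models round-trip losslessly through a
small hierarchical YAML schema (geometry, per-layer parameters and
prestretches).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .constitutive import HGOParams
from .layer_composition import LAYER_NAMES, LayerSpec, WallModel
from .uniaxial_fit import UniaxialCurve

__all__ = [
    "CurveFormatError",
    "ConfigError",
    "read_curves",
    "write_curves",
    "wall_model_to_dict",
    "wall_model_from_dict",
    "save_wall_model",
    "load_wall_model",
]

_CURVE_COLUMNS = ("stretch", "stress_kpa", "direction")


class CurveFormatError(ValueError):
    """Malformed curve CSV."""


class ConfigError(ValueError):
    """Malformed wall-model / run configuration."""


def read_curves(path: str | Path, *, source: str = "measured") -> dict[str, UniaxialCurve]:
    """Read a curve CSV; returns a dict keyed by direction ('circ', 'ax')."""
    df = pd.read_csv(path)
    missing = [c for c in _CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise CurveFormatError(f"{path}: missing column(s) {missing}")
    out: dict[str, UniaxialCurve] = {}
    for direction, grp in df.groupby("direction", sort=False):
        if direction not in ("circ", "ax"):
            row = int(grp.index[0]) + 2  # header + 1-based
            raise CurveFormatError(
                f"{path}: unknown direction {direction!r} at row {row}"
            )
        stretch = grp["stretch"].to_numpy(float)
        bad = np.flatnonzero(np.diff(stretch) <= 0)
        if bad.size:
            row = int(grp.index[bad[0] + 1]) + 2
            raise CurveFormatError(
                f"{path}: stretch not strictly increasing at row {row}"
            )
        out[str(direction)] = UniaxialCurve(
            str(direction), stretch, grp["stress_kpa"].to_numpy(float), source
        )
    if not out:
        raise CurveFormatError(f"{path}: no curve rows found")
    return out


def write_curves(path: str | Path, curves: Mapping[str, UniaxialCurve] | list[UniaxialCurve]) -> None:
    """Write one or more curves to a single CSV file."""
    items = list(curves.values()) if isinstance(curves, Mapping) else list(curves)
    frames = [
        pd.DataFrame(
            {"stretch": c.stretch, "stress_kpa": c.stress, "direction": c.direction}
        )
        for c in items
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def wall_model_to_dict(wall: WallModel) -> dict:
    layers = {}
    for l in wall.layers:
        layers[l.name] = {
            "thickness_mm": float(l.thickness),
            "params": {
                "mu_kpa": float(l.params.mu),
                "c1_kpa": float(l.params.c1),
                "c2": float(l.params.c2),
                "alpha_deg": float(l.params.alpha_deg),
                "rho": float(l.params.rho),
            },
            "prestretch": {
                "circ": float(l.prestretch_circ),
                "ax": float(l.prestretch_ax),
            },
        }
    return {
        "geometry": {"unloaded_internal_radius_mm": float(wall.unloaded_internal_radius)},
        "layers": layers,
    }


def _require(d: Mapping, key: str, path: str):
    if not isinstance(d, Mapping) or key not in d:
        raise ConfigError(f"missing key '{path}{key}'")
    return d[key]


def wall_model_from_dict(data: Mapping) -> WallModel:
    geometry = _require(data, "geometry", "")
    radius = _require(geometry, "unloaded_internal_radius_mm", "geometry.")
    layers_cfg = _require(data, "layers", "")
    layers = []
    for name in LAYER_NAMES:
        lc = _require(layers_cfg, name, "layers.")
        pc = _require(lc, "params", f"layers.{name}.")
        pre = lc.get("prestretch", {"circ": 1.0, "ax": 1.0})
        try:
            params = HGOParams(
                mu=float(_require(pc, "mu_kpa", f"layers.{name}.params.")),
                c1=float(_require(pc, "c1_kpa", f"layers.{name}.params.")),
                c2=float(_require(pc, "c2", f"layers.{name}.params.")),
                alpha_deg=float(_require(pc, "alpha_deg", f"layers.{name}.params.")),
                rho=float(_require(pc, "rho", f"layers.{name}.params.")),
            )
            layers.append(
                LayerSpec(
                    name=name,
                    thickness=float(_require(lc, "thickness_mm", f"layers.{name}.")),
                    params=params,
                    prestretch_circ=float(_require(pre, "circ", f"layers.{name}.prestretch.")),
                    prestretch_ax=float(_require(pre, "ax", f"layers.{name}.prestretch.")),
                )
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, ConfigError):
                raise
            raise ConfigError(f"invalid value in layers.{name}: {exc}") from exc
    return WallModel(tuple(layers), unloaded_internal_radius=float(radius))


def save_wall_model(path: str | Path, wall: WallModel) -> None:
    Path(path).write_text(yaml.safe_dump(wall_model_to_dict(wall), sort_keys=False))


def load_wall_model(path: str | Path) -> WallModel:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: expected a mapping at the top level")
    return wall_model_from_dict(data)
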