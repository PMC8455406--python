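import dataclasses

import numpy as np
import pytest

from trilayer import (
    HGOParams,
    LayerSpec,
    WallModel,
    close_vessel,
    estimate_in_vivo_stretch,
    reference_wall_model,
)
from trilayer.reference import cohort_parameter_sets


@pytest.fixture(scope="session")
def ref_wall() -> WallModel:
    """Packaged average-response porcine wall model."""
    return reference_wall_model()


@pytest.fixture(scope="session")
def ref_tube(ref_wall):
    return close_vessel(ref_wall)


@pytest.fixture(scope="session")
def ref_lamz(ref_tube):
    return estimate_in_vivo_stretch(ref_tube)


@pytest.fixture(scope="session")
def media_params() -> HGOParams:
    """Average-response media parameter set."""
    return HGOParams(mu=22.3, c1=134.8, c2=9.5, alpha_deg=33.4, rho=0.24)


@pytest.fixture(scope="session")
def intima_params() -> HGOParams:
    return HGOParams(mu=23.5, c1=124.7, c2=11.0, alpha_deg=39.5, rho=0.24)


@pytest.fixture(scope="session")
def adventitia_params() -> HGOParams:
    return HGOParams(mu=21.2, c1=25.7, c2=67.3, alpha_deg=42.9, rho=0.18)


@pytest.fixture(scope="session")
def cohort_mean_wall(ref_wall) -> WallModel:
    """Wall model whose layer parameters are the per-animal cohort means."""
    sets = cohort_parameter_sets()
    layers = []
    for layer in ref_wall.layers:
        arrs = np.array([sets[s][layer.name].as_array() for s in sets])
        layers.append(dataclasses.replace(layer, params=HGOParams(*arrs.mean(axis=0))))
    return dataclasses.replace(ref_wall, layers=tuple(layers))


def random_params(rng: np.random.Generator) -> HGOParams:
    """Random plausible parameter set spanning the fitted cohort ranges."""
    return HGOParams(
        mu=rng.uniform(5.0, 40.0),
        c1=rng.uniform(20.0, 200.0),
        c2=rng.uniform(1.0, 80.0),
        alpha_deg=rng.uniform(15.0, 60.0),
        rho=rng.uniform(0.0, 1.0 / 3.0),
    )
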