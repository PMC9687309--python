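"""Shared fixtures: small plate models, the desk-scale phantom, and the
paired desk-scale reconstructions reused by the acceptance tests."""

import numpy as np
import pytest

from trabtopo.fem import DensityImage, FEModel
from trabtopo.materials import MaterialParams
from trabtopo.phantom import (FemurPhantomParams, default_load_cases,
                              distribute_load, generate_femur)
from trabtopo.refine import build_continuum_model
from trabtopo.workbench import make_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return make_fixtures(seed=0)


@pytest.fixture(scope="session")
def material():
    return MaterialParams()


def plate_model(values, fixed="bottom", nu=0.3, pixel_um=600.0):
    """Plane-stress model of a rectangular plate with uniform-law moduli."""
    values = np.asarray(values, dtype=float)
    img = DensityImage(values, np.ones(values.shape, bool), pixel_um)
    moduli = np.clip(values, 0.01, 1.0) ** 3 * 15e9
    nr, nc = values.shape
    if fixed == "bottom":
        fixed_nodes = np.array([[0, j] for j in range(nc + 1)])
    elif fixed == "left":
        fixed_nodes = np.array([[i, 0] for i in range(nr + 1)])
    else:
        fixed_nodes = None
    return img, FEModel.from_active_grid(
        np.ones(values.shape, bool), moduli, nu, pixel_um, fixed_nodes)


@pytest.fixture(scope="session")
def desk_phantom():
    params = FemurPhantomParams(seed=1).half_scale()
    image, landmarks = generate_femur(params)
    return image, landmarks


@pytest.fixture(scope="session")
def desk_lr_setup(desk_phantom, material):
    """LR continuum model of the desk phantom with its distributed loads."""
    image, landmarks = desk_phantom
    model = build_continuum_model(image, material)
    cases = default_load_cases()
    loads = [distribute_load(c, landmarks, model) for c in cases]
    return model, cases, loads
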