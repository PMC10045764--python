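import numpy as np
import pytest

from dwiguide import PhantomSpec, make_dataset
from dwiguide.phantom import Tissue


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A 64 x 64 single-slice phantom for fast unit tests."""
    return PhantomSpec(matrix_size=64, n_slices=1, tissues=_small_tissues(), seed=7)


def _small_tissues():
    c = (32.0, 32.0)
    return [
        Tissue(1, 0.75, 1.4e-3, {"kind": "ellipse", "center": c, "radii": (27.0, 29.0)}, "pelvis"),
        Tissue(2, 0.15, 2.5e-3, {"kind": "disk", "center": c, "radius": 5.0}, "lumen"),
        Tissue(3, 1.00, 1.0e-3, {"kind": "annulus", "center": c, "r_in": 5.0, "r_out": 9.0}, "inner_wall"),
        Tissue(4, 0.80, 1.3e-3, {"kind": "annulus", "center": c, "r_in": 9.0, "r_out": 13.0}, "outer_wall"),
    ]


@pytest.fixture(scope="session")
def small_pairs(small_spec):
    """Three simulated subjects on the small phantom."""
    return make_dataset(small_spec, n_subjects=3, seed=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
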