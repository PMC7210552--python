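import numpy as np
import pytest

from eecp_hemoflow.flow import WallShearField
from eecp_hemoflow.synthdata import GeometrySpec, ImageStackSpec, WaveformSpec


@pytest.fixture(scope="session")
def geom_spec():
    return GeometrySpec()


@pytest.fixture(scope="session")
def geom_mesh(geom_spec):
    from eecp_hemoflow.synthdata import generate_bifurcation_geometry

    return generate_bifurcation_geometry(geom_spec)


@pytest.fixture(scope="session")
def clean_stack(geom_spec):
    from eecp_hemoflow.synthdata import generate_mr_stack

    spec = ImageStackSpec(noise_sigma=0.0, clutter_blob_count=0)
    return generate_mr_stack(geom_spec, spec)


@pytest.fixture
def wave_spec():
    return WaveformSpec()


def make_series(tau_fn, n_t=400, period=0.8, points=None):
    """WallShearField from tau(t) -> (n_pts, 3) or (3,) callable."""
    t = np.linspace(0.0, period, n_t, endpoint=False)
    sample = np.atleast_2d(np.asarray(tau_fn(t[0]), dtype=float))
    n_pts = sample.shape[0]
    tau = np.zeros((n_pts, n_t, 3))
    for k, tk in enumerate(t):
        tau[:, k, :] = np.atleast_2d(np.asarray(tau_fn(tk), dtype=float))
    if points is None:
        points = np.zeros((n_pts, 3))
    return WallShearField(points=points, tau=tau, t=t, period=period)
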