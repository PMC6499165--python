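import numpy as np
import pytest

import tmsmap as tm
from tmsmap.synthetic import PhantomSpec, make_head_phantom


@pytest.fixture(scope="session")
def sphere():
    """Exact sphere scalp model, radius 100 mm about the origin."""
    return tm.ScalpEllipsoid.exact_sphere(100.0)


@pytest.fixture(scope="session")
def phantom():
    """Default noiseless ellipsoid phantom: (volume, ground-truth mask, spec)."""
    spec = PhantomSpec()
    volume, mask = make_head_phantom(spec)
    return volume, mask, spec


@pytest.fixture(scope="session")
def phantom_scalp(phantom):
    """Scalp model fitted end-to-end from the phantom volume."""
    volume, _, spec = phantom
    seg = tm.segment_head(volume)
    cloud = tm.sample_point_cloud(seg, spec.voxel_spacing)
    return tm.fit_scalp_ellipsoid(cloud, tm.compute_centroid(cloud))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_sphere_points(rng, n, radius=100.0, center=(0.0, 0.0, 0.0)):
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    return radius * v + np.asarray(center)


@pytest.fixture()
def equator_patch_surface(sphere):
    """Smooth Gaussian bump fitted around the equator of the sphere model."""
    from tmsmap.synthetic import SyntheticMapSpec, field_value

    spec = SyntheticMapSpec(width_rad=0.25)
    ax = np.linspace(np.pi / 2 - 0.5, np.pi / 2 + 0.5, 21)
    th, ph = np.meshgrid(ax, np.linspace(-0.5, 0.5, 21), indexing="ij")
    values = field_value(spec, th, ph)
    surface = tm.fit_surface(th.ravel(), ph.ravel(), values.ravel(),
                             algorithm="piecewise_cubic")
    grid = tm.AngularGrid(
        spacing=0.01,
        theta_min=float(ax[0]),
        theta_max=float(ax[-1]) + 1e-9,
        phi_min=-0.5,
        phi_max=0.5,
    )
    return surface, grid
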