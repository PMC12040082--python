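import numpy as np
import pytest

import forestacd as fa


@pytest.fixture(scope="session")
def sparse_scene() -> fa.SceneSpec:
    """Five well-separated trees on a 100 m x 100 m flat floodplain."""
    return fa.generate_scene(
        extent=(0.0, 0.0, 100.0, 100.0),
        n_trees=5,
        height_range=(5.0, 15.0),
        min_spacing=20.0,
        ground_elevation=10.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def noise_free_cloud(sparse_scene) -> fa.PointCloud:
    return fa.render_point_cloud(
        sparse_scene, point_density=100.0, ground_fraction=1.0, vertical_noise_sd=0.0, seed=12
    )


@pytest.fixture(scope="session")
def noise_free_chm(noise_free_cloud) -> fa.ChmResult:
    return fa.build_chm(noise_free_cloud)


def paraboloid_chm(height=10.0, radius=3.0, cell=0.1, pad=2.0) -> fa.GridRaster:
    """Analytic paraboloid crown sampled directly onto a raster."""
    half = radius + pad
    n = int(round(2 * half / cell))
    raster = fa.GridRaster(origin=(-half, -half), cell_size=cell, values=np.zeros((n, n)))
    xs, ys = raster.cell_centers()
    r2 = (xs**2 + ys**2) / radius**2
    raster.values[:] = np.maximum(height * (1 - r2), 0.0)
    return raster
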