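import numpy as np
import pytest

import cedbt
from cedbt.filtering import RampFilterSpec


@pytest.fixture(scope="session")
def small_geom():
    """5 views over 40 degrees onto a small detector."""
    return cedbt.ScanGeometry(
        n_views=5, arc_span=40.0, detector_pitch=1.0, detector_shape=(30, 22)
    )


@pytest.fixture(scope="session")
def small_grid():
    return cedbt.VolumeGrid((8, 9, 7), 1.3, (-5.0, -6.0, 0.8))


@pytest.fixture(scope="session")
def geom2d():
    """Fan-beam-like 2D setup: 9 views over 50 degrees, single detector column."""
    return cedbt.ScanGeometry(
        n_views=9, arc_span=50.0, detector_pitch=1.0, detector_shape=(64, 1)
    )


@pytest.fixture(scope="session")
def grid2d():
    return cedbt.VolumeGrid((1, 32, 32), 1.0, (0.0, -15.5, 0.5))


@pytest.fixture(scope="session")
def phantom2d(grid2d):
    """Piecewise-constant 2D attenuation map (1/mm) in the y-z plane."""
    y, z = np.meshgrid(np.arange(32) - 15.5, np.arange(32) - 15.0, indexing="ij")
    f = np.zeros((32, 32))
    f[(y / 13) ** 2 + (z / 12) ** 2 <= 1] = 0.05
    f[(y + 5) ** 2 + (z - 3) ** 2 <= 9] = 0.08
    f[(y - 6) ** 2 + (z + 4) ** 2 <= 4] = 0.10
    return f[None]


@pytest.fixture(scope="session")
def projections2d(phantom2d, geom2d, grid2d):
    return cedbt.forward_project(phantom2d, geom2d, grid2d)


@pytest.fixture(scope="session")
def filter_spec():
    return RampFilterSpec()


@pytest.fixture(scope="session")
def desk_run():
    """One reduced-scale end-to-end dual-energy pipeline run (dTV + FBP).

    Session-scoped because it is by far the most expensive fixture; the
    depth-blur, weight-selection and pipeline-artifact tests all share it.
    """
    import tempfile

    cfg = cedbt.PipelineConfig(
        seed=7,
        output_dir=tempfile.mkdtemp(prefix="cedbt_desk_"),
    )
    results = cedbt.run_pipeline(cfg)
    return cfg, results
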