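import numpy as np
import pytest

import cedbt
from cedbt.phantom import (
    NoiseModel,
    PhantomSpec,
    SpectralModel,
    make_phantom,
    simulate_de_scan,
)


@pytest.fixture(scope="module")
def grid():
    return cedbt.default_volume_grid((64, 64, 48), 1.0)


@pytest.fixture(scope="module")
def truth(grid):
    spec = PhantomSpec(seed=4, insert_diameters=(3.0, 8.0),
                       iodine_concentrations=(2.0, 5.0))
    return make_phantom(spec, grid)


class TestMakePhantom:
    def test_deterministic_given_seed(self, grid):
        spec = PhantomSpec(seed=12)
        a = make_phantom(spec, grid)
        b = make_phantom(spec, grid)
        assert np.array_equal(a.mu_le, b.mu_le)
        assert a.inserts == b.inserts

    def test_glandular_fraction_near_target(self, truth):
        assert abs(truth.glandular_fraction - 0.5) <= 0.02 * 1.0 + 0.01

    def test_zero_concentration_leaves_only_tissue_contrast(self, grid):
        spec = PhantomSpec(seed=4, iodine_concentrations=(0.0, 0.0))
        t = make_phantom(spec, grid)
        diff = t.mu_he - t.mu_le
        # only two tissue contrast levels present off/on the support
        levels = np.unique(np.round(diff, 12))
        assert levels.size <= 3

    def test_sphere_voxel_count_matches_analytic_volume(self, truth, grid):
        r = 4.0  # 8 mm sphere
        count = 0
        for ins in truth.inserts:
            if ins["diameter_mm"] == 8.0 and ins["concentration_mgml"] == 5.0:
                cx, cy, cz = ins["center_mm"]
                x = grid.axis_coords(0)[:, None, None]
                y = grid.axis_coords(1)[None, :, None]
                z = grid.axis_coords(2)[None, None, :]
                region = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= r**2
                count = int(((truth.iodine_mgml == 5.0) & region).sum())
        analytic = 4.0 / 3.0 * np.pi * r**3 / grid.voxel_size**3
        assert abs(count - analytic) / analytic <= 0.05

    def test_truth_metadata_lists_all_inserts(self, truth):
        assert len(truth.inserts) == 4
        assert {i["concentration_mgml"] for i in truth.inserts} == {2.0, 5.0}
        assert {i["diameter_mm"] for i in truth.inserts} == {3.0, 8.0}

    def test_oversized_insert_rejected(self, grid):
        spec = PhantomSpec(slab_thickness=6.0, insert_diameters=(8.0,),
                           iodine_concentrations=(1.0,))
        with pytest.raises(ValueError, match="slab"):
            make_phantom(spec, grid)

    def test_spectral_validation(self):
        with pytest.raises(ValueError, match="K-edge"):
            SpectralModel(iodine_le=0.005, iodine_he=0.002)
        with pytest.raises(ValueError):
            SpectralModel(adipose_le=-0.1)

    def test_cylinder_inserts(self, grid):
        spec = PhantomSpec(seed=4, insert_shape="cylinder",
                           insert_diameters=(8.0,), iodine_concentrations=(5.0,))
        t = make_phantom(spec, grid)
        region = t.iodine_mgml > 0
        # cylinder cross-section is constant along z within its height
        zs = np.where(region.any(axis=(0, 1)))[0]
        areas = region[:, :, zs].sum(axis=(0, 1))
        assert areas.max() == areas.min()


class TestSimulateScan:
    def test_infinite_fluence_equals_line_integrals(self, truth, grid):
        geom = cedbt.desk_geometry(detector_shape=(96, 80))
        g_le, g_he = simulate_de_scan(truth.mu_le, truth.mu_he, geom, grid,
                                      NoiseModel(fluence=None))
        assert np.array_equal(g_le, cedbt.forward_project(truth.mu_le, geom, grid))
        assert np.array_equal(g_he, cedbt.forward_project(truth.mu_he, geom, grid))

    def test_doubling_attenuation_doubles_noiseless_data(self, truth, grid):
        geom = cedbt.desk_geometry(detector_shape=(96, 80))
        g1, _ = simulate_de_scan(truth.mu_le, truth.mu_he, geom, grid,
                                 NoiseModel(fluence=None))
        g2, _ = simulate_de_scan(2 * truth.mu_le, truth.mu_he, geom, grid,
                                 NoiseModel(fluence=None))
        assert np.allclose(g2, 2 * g1, atol=1e-10)

    def test_poisson_noise_matches_delta_method(self, truth, grid):
        """Var of -log(counts/fluence) is 1/lambda, so the std of g - g0 is
        exp(l/2)/sqrt(fluence) to first order."""
        geom = cedbt.desk_geometry(detector_shape=(96, 80))
        fluence = 1e5
        g0, _ = simulate_de_scan(truth.mu_le, truth.mu_he, geom, grid,
                                 NoiseModel(fluence=None))
        reps = [
            simulate_de_scan(truth.mu_le, truth.mu_he, geom, grid,
                             NoiseModel(fluence=fluence, seed=s))[0]
            for s in range(12)
        ]
        sd = np.std(np.stack(reps) - g0, axis=0, ddof=1)
        pred = np.exp(g0 / 2.0) / np.sqrt(fluence)
        sel = g0 > 0.5  # rays through the object
        ratio = np.median(sd[sel] / pred[sel])
        assert abs(ratio - 1.0) <= 0.10

    def test_deterministic_given_seed(self, truth, grid):
        geom = cedbt.desk_geometry(detector_shape=(96, 80))
        nm = NoiseModel(fluence=1e5, seed=77)
        a = simulate_de_scan(truth.mu_le, truth.mu_he, geom, grid, nm)
        b = simulate_de_scan(truth.mu_le, truth.mu_he, geom, grid, nm)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_negative_attenuation_rejected(self, grid, truth):
        geom = cedbt.desk_geometry(detector_shape=(96, 80))
        bad = truth.mu_le.copy()
        bad[0, 0, 0] = -1.0
        with pytest.raises(ValueError):
            simulate_de_scan(bad, truth.mu_he, geom, grid)
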