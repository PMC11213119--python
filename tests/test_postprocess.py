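import numpy as np
import pytest

from cedbt.postprocess import (
    IRLSControls,
    build_poly_basis,
    estimate_support_mask,
    n_poly_terms,
    normalize_volume,
    process_volume,
    robust_polyfit_slice,
)

from oracles import l1_polyfit_lp


def poly_surface(shape, coeffs_exp):
    """Evaluate sum c * x^i y^j on the same normalized coordinates as the basis."""
    x = np.linspace(-1, 1, shape[0])
    y = np.linspace(-1, 1, shape[1])
    xx, yy = np.meshgrid(x, y, indexing="ij")
    s = np.zeros(shape)
    for c, (i, j) in coeffs_exp:
        s += c * xx**i * yy**j
    return s


class TestPolyBasis:
    def test_eighth_degree_has_45_terms(self):
        assert build_poly_basis((32, 32), 8).n_terms == 45

    def test_degree_zero_is_constant(self):
        basis = build_poly_basis((5, 7), 0)
        assert basis.n_terms == 1
        assert np.allclose(basis.matrix, 1.0)

    def test_degree_two_enumeration(self):
        basis = build_poly_basis((8, 8), 2)
        assert basis.n_terms == 6
        assert set(basis.exponents) == {(0, 0), (1, 0), (0, 1), (2, 0), (1, 1), (0, 2)}

    @pytest.mark.parametrize("degree", range(11))
    def test_term_count_formula(self, degree):
        assert build_poly_basis((12, 12), degree).n_terms == (degree + 1) * (degree + 2) // 2
        assert n_poly_terms(degree) == (degree + 1) * (degree + 2) // 2

    def test_negative_degree(self):
        with pytest.raises(ValueError):
            build_poly_basis((4, 4), -1)


class TestSupportMask:
    def test_uniform_slice_gives_full_mask(self):
        assert estimate_support_mask(np.ones((10, 10))).all()

    def test_half_plane_fraction_of_mean(self):
        s = np.zeros((10, 10))
        s[:, 5:] = 1.0
        m = estimate_support_mask(s, "fraction_of_mean", 0.5)
        assert m[:, 5:].all() and not m[:, :5].any()

    def test_breast_shaped_slab_area(self):
        """Mask area of an elliptical object over air within 2% of truth."""
        x = np.linspace(-1, 1, 96)
        xx, yy = np.meshgrid(x, x, indexing="ij")
        truth = (xx / 0.8) ** 2 + (yy / 0.6) ** 2 <= 1.0
        rng = np.random.default_rng(0)
        s = np.where(truth, 1.0 + 0.05 * rng.standard_normal(truth.shape), 0.0)
        m = estimate_support_mask(s)
        assert abs(m.sum() - truth.sum()) / truth.sum() <= 0.02

    def test_all_zero_slice_warns_and_is_empty(self):
        with pytest.warns(UserWarning):
            m = estimate_support_mask(np.zeros((6, 6)))
        assert not m.any()

    def test_largest_component_kept(self):
        s = np.zeros((20, 20))
        s[2:12, 2:12] = 1.0
        s[15:17, 15:17] = 1.0
        m = estimate_support_mask(s, "fraction_of_mean", 0.5)
        assert m[5, 5] and not m[16, 16]

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            estimate_support_mask(np.ones((4, 4)), "median_of_fraction")


class TestRobustPolyfit:
    def test_exact_low_degree_surface_fits_exactly(self):
        shape = (24, 24)
        s = poly_surface(shape, [(1.0, (0, 0)), (0.5, (1, 0)), (-0.3, (2, 1)), (0.2, (0, 3))])
        basis = build_poly_basis(shape, 8)
        _, b = robust_polyfit_slice(s, np.ones(shape, bool), basis)
        assert np.abs(b - s).max() <= 1e-8

    def test_outlier_resistant_recovery(self):
        """5% gross outliers do not move a degree-2 fit (l1 breakdown)."""
        shape = (28, 28)
        true_coeffs = [(2.0, (0, 0)), (0.7, (1, 0)), (-0.4, (0, 1)),
                       (0.3, (2, 0)), (-0.2, (1, 1)), (0.1, (0, 2))]
        s = poly_surface(shape, true_coeffs)
        rng = np.random.default_rng(5)
        idx = rng.choice(s.size, size=int(0.05 * s.size), replace=False)
        s_corrupt = s.copy().ravel()
        s_corrupt[idx] += 10.0
        s_corrupt = s_corrupt.reshape(shape)
        basis = build_poly_basis(shape, 2)
        c, _ = robust_polyfit_slice(s_corrupt, np.ones(shape, bool), basis)
        truth = np.zeros(basis.n_terms)
        for val, exp in true_coeffs:
            truth[basis.exponents.index(exp)] = val
        assert np.abs(c - truth).max() <= 1e-4

    def test_matches_lp_oracle_objective(self):
        shape = (16, 16)
        rng = np.random.default_rng(9)
        s = rng.standard_normal(shape)
        basis = build_poly_basis(shape, 3)
        c, _ = robust_polyfit_slice(s, np.ones(shape, bool), basis,
                                    IRLSControls(max_iter=200, tol=1e-12))
        _, lp_obj = l1_polyfit_lp(basis.matrix, s.ravel())
        irls_obj = np.abs(s.ravel() - basis.matrix @ c).sum()
        assert irls_obj <= lp_obj * 1.001

    def test_irls_objective_non_increasing(self):
        shape = (20, 20)
        rng = np.random.default_rng(3)
        s = poly_surface(shape, [(1.0, (0, 0)), (0.5, (2, 0))]) \
            + 0.1 * rng.standard_normal(shape)
        basis = build_poly_basis(shape, 2)
        objs = []
        for k in range(1, 12):
            c, _ = robust_polyfit_slice(s, np.ones(shape, bool), basis,
                                        IRLSControls(max_iter=k, tol=0.0))
            objs.append(np.abs(s.ravel() - basis.matrix @ c).sum())
        assert all(b <= a + 1e-9 for a, b in zip(objs, objs[1:]))

    def test_single_huge_outlier_barely_moves_background(self):
        shape = (24, 24)
        s = poly_surface(shape, [(1.0, (0, 0)), (0.4, (1, 1))])
        basis = build_poly_basis(shape, 2)
        _, b0 = robust_polyfit_slice(s, np.ones(shape, bool), basis)
        s_out = s.copy()
        s_out[10, 10] += 1e6
        _, b1 = robust_polyfit_slice(s_out, np.ones(shape, bool), basis)
        assert np.sqrt(np.mean((b1 - b0) ** 2)) < 1e-3

    def test_too_small_mask_raises(self):
        basis = build_poly_basis((10, 10), 8)
        m = np.zeros((10, 10), bool)
        m[:5, :5] = True  # 25 < 45
        with pytest.raises(ValueError, match="mask"):
            robust_polyfit_slice(np.ones((10, 10)), m, basis)


class TestNormalizeAndProcess:
    def test_identity_background_gives_ones_on_mask(self):
        f = np.random.default_rng(0).random((6, 6, 3)) + 0.5
        fm = np.ones(f.shape, bool)
        fd = normalize_volume(f, f.copy(), fm)
        assert np.allclose(fd, 1.0)

    def test_empty_mask_gives_zero(self):
        f = np.ones((4, 4, 2))
        fd = normalize_volume(f, np.ones_like(f), np.zeros(f.shape, bool))
        assert np.all(fd == 0)

    def test_nonpositive_background_rejected(self):
        f = np.ones((4, 4, 2))
        fb = np.zeros_like(f)
        with pytest.raises(ValueError, match="background"):
            normalize_volume(f, fb, np.ones(f.shape, bool))

    def test_uniform_volume_normalizes_to_one(self):
        f = np.ones((20, 20, 4))
        fd, fb, fm = process_volume(f, degree=2)
        assert np.allclose(fd[fm], 1.0, atol=1e-8)

    def test_background_centres_on_one(self):
        """Smooth shading times a flat object normalizes to ~1 on the support."""
        n = 48
        x = np.linspace(-1, 1, n)
        xx, yy = np.meshgrid(x, x, indexing="ij")
        support = xx**2 + yy**2 <= 0.8**2
        shading = 1.0 + 0.4 * xx - 0.3 * yy**2
        f = np.where(support, shading, 0.0)[:, :, None] * np.ones(3)
        fd, fb, fm = process_volume(f, degree=4)
        inner = fm & np.broadcast_to((xx**2 + yy**2 <= 0.6**2)[:, :, None], fm.shape)
        assert 0.97 <= fd[inner].mean() <= 1.03

    def test_idempotent_within_tolerance(self):
        n = 40
        rng = np.random.default_rng(11)
        x = np.linspace(-1, 1, n)
        xx, yy = np.meshgrid(x, x, indexing="ij")
        support = xx**2 + yy**2 <= 0.85**2
        f = np.where(support, 1.0 + 0.3 * xx + 0.1 * rng.standard_normal((n, n)), 0.0)
        f = f[:, :, None] * np.ones(2)
        fd, _, _ = process_volume(f, degree=4)
        fd2, _, _ = process_volume(fd, degree=4)
        denom = np.sqrt(np.mean(fd[fd != 0] ** 2))
        assert np.sqrt(np.mean((fd2 - fd) ** 2)) / denom < 0.02

    def test_empty_volume_rejected(self):
        with pytest.raises(ValueError):
            process_volume(np.ones((4, 4)))
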