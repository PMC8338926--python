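"""Gaussian kernels, Hessian eigen-analysis and the multiscale filter."""

import numpy as np
import pytest

from retorient.hessian import (
    BRIGHT,
    DARK,
    EigenField,
    FilterParams,
    eigen_field,
    hessian_at_scale,
    make_gaussian_kernel,
    multiscale_vesselness,
    vesselness_at_scale,
)
from retorient.image import ScalarImage2D, axial_distance
from retorient.synthetic import render_scene

from conftest import centerline_mask, single_tube_scene


class TestGaussianKernel:
    def test_center_value_matches_closed_form(self):
        k = make_gaussian_kernel(1.0, normalize=False)
        r = k.shape[0] // 2
        assert k[r, r] == pytest.approx(1.0 / (2.0 * np.pi), rel=1e-12)

    def test_normalized_kernel_sums_to_one(self):
        for sigma in (0.7, 1.0, 2.5):
            assert make_gaussian_kernel(sigma).sum() == pytest.approx(1.0, abs=1e-12)

    def test_scaling_relation_between_sigmas(self):
        # G(t, 2) sampled at integers equals G(t/2, 1)/4 before renormalization
        k2 = make_gaussian_kernel(2.0, truncate_radius=8.0, normalize=False)
        r = k2.shape[0] // 2
        ax = np.arange(-r, r + 1) / 2.0
        xx, yy = np.meshgrid(ax, ax)
        k1_half = np.exp(-(xx**2 + yy**2) / 2.0) / (2.0 * np.pi) / 4.0
        np.testing.assert_allclose(k2, k1_half, rtol=1e-12)

    @pytest.mark.parametrize("sigma", [0.0, -1.0])
    def test_rejects_nonpositive_sigma(self, sigma):
        with pytest.raises(ValueError):
            make_gaussian_kernel(sigma)

    def test_rejects_small_truncation(self):
        with pytest.raises(ValueError):
            make_gaussian_kernel(2.0, truncate_radius=4.0)


class TestHessianAtScale:
    def test_constant_image_has_zero_hessian(self):
        img = ScalarImage2D(np.full((32, 32), 0.5))
        h = hessian_at_scale(img, 1.0)
        assert np.allclose(h.ixx, 0.0) and np.allclose(h.ixy, 0.0) \
            and np.allclose(h.iyy, 0.0)

    def test_vertical_tube_centerline_structure(self, vertical_tube):
        # intensity varies only across the tube (x): Ixx < 0, Iyy ~ 0, Ixy ~ 0
        img, _ = vertical_tube
        h = hessian_at_scale(img, 1.0)
        c = img.shape[0] // 2
        assert h.ixx[c, c] < 0
        assert abs(h.iyy[c, c]) < 0.02 * abs(h.ixx[c, c])
        assert abs(h.ixy[c, c]) < 0.02 * abs(h.ixx[c, c])

    def test_rotating_image_90deg_swaps_ixx_iyy(self, vertical_tube):
        img, _ = vertical_tube
        h0 = hessian_at_scale(img, 1.0)
        h90 = hessian_at_scale(np.rot90(img.pixels), 1.0)
        c = img.shape[0] // 2
        assert h90.ixx[c, c] == pytest.approx(h0.iyy[c, c], abs=1e-10)
        assert h90.iyy[c, c] == pytest.approx(h0.ixx[c, c], abs=1e-10)

    def test_rejects_aliasing_sigma(self):
        with pytest.raises(ValueError):
            hessian_at_scale(np.zeros((32, 32)), 0.25)


def _eigen_of(a, b, c):
    from retorient.hessian import HessianField
    h = HessianField(ixx=np.array([[a]]), ixy=np.array([[b]]),
                     iyy=np.array([[c]]), sigma=1.0)
    return eigen_field(h)


class TestEigenField:
    def test_ideal_ridge_pixel(self):
        # Hessian of the ideal s=1 tube at its ridge: λ1 = 0, tube along y
        e = _eigen_of(-1.0 / (2.0 * np.pi), 0.0, 0.0)
        assert e.lambda1[0, 0] == 0.0
        assert e.theta[0, 0] == pytest.approx(90.0)

    def test_isotropic_pixel_has_undefined_orientation(self):
        e = _eigen_of(0.7, 0.0, 0.7)
        assert abs(e.lambda1[0, 0]) == pytest.approx(0.7)
        assert abs(e.lambda2[0, 0]) == pytest.approx(0.7)
        assert np.isnan(e.theta[0, 0])

    def test_matches_lapack_on_random_symmetric_matrices(self, rng):
        # independent oracle: LAPACK eigh per matrix
        n = 1000
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        c = rng.normal(size=n)
        from retorient.hessian import HessianField
        h = HessianField(ixx=a.reshape(1, -1), ixy=b.reshape(1, -1),
                         iyy=c.reshape(1, -1), sigma=1.0)
        e = eigen_field(h)
        for i in range(n):
            m = np.array([[a[i], b[i]], [b[i], c[i]]])
            w, v = np.linalg.eigh(m)
            order = np.argsort(np.abs(w))
            assert e.lambda1[0, i] == pytest.approx(w[order[0]], abs=1e-10)
            assert e.lambda2[0, i] == pytest.approx(w[order[1]], abs=1e-10)
            vec = v[:, order[0]]
            ang = np.degrees(np.arctan2(vec[1], vec[0])) % 180.0
            assert axial_distance(e.theta[0, i], ang) < 1e-7

    def test_magnitude_ordering_holds_everywhere(self, rng):
        from retorient.hessian import HessianField
        shape = (50, 50)
        h = HessianField(ixx=rng.normal(size=shape), ixy=rng.normal(size=shape),
                         iyy=rng.normal(size=shape), sigma=1.0)
        e = eigen_field(h)
        assert np.all(np.abs(e.lambda1) <= np.abs(e.lambda2) + 1e-15)
        finite = np.isfinite(e.theta)
        assert np.all((e.theta[finite] >= 0.0) & (e.theta[finite] < 180.0))


def _field(lam1, lam2, theta=45.0):
    return EigenField(lambda1=np.array([[float(lam1)]]),
                      lambda2=np.array([[float(lam2)]]),
                      theta=np.array([[theta]]), sigma=1.0)


class TestVesselnessResponse:
    def test_pure_line_response(self):
        # R=0, S=10 with beta=0.5, gamma=5: rho = 1 - exp(-2)
        rho = vesselness_at_scale(_field(0.0, -10.0), beta=0.5, gamma=5.0)
        assert rho[0, 0] == pytest.approx(1.0 - np.exp(-2.0), rel=1e-12)

    def test_zero_eigenvalues_give_zero_response(self):
        assert vesselness_at_scale(_field(0.0, 0.0), 0.5, 5.0)[0, 0] == 0.0

    def test_three_four_five_ratio_and_structureness(self):
        from retorient.hessian import _line_ratio, _structureness
        e = _field(3.0, 4.0)
        assert _line_ratio(e)[0, 0] == pytest.approx(0.75)
        assert _structureness(e)[0, 0] == pytest.approx(5.0)

    def test_polarity_gate(self):
        bright = vesselness_at_scale(_field(0.0, -10.0), 0.5, 5.0, BRIGHT)
        dark = vesselness_at_scale(_field(0.0, -10.0), 0.5, 5.0, DARK)
        assert bright[0, 0] > 0 and dark[0, 0] == 0.0

    @pytest.mark.parametrize("beta,gamma", [(0.0, 5.0), (0.5, -1.0)])
    def test_rejects_nonpositive_suppression(self, beta, gamma):
        with pytest.raises(ValueError):
            vesselness_at_scale(_field(0.0, -1.0), beta, gamma)


class TestMultiscale:
    def test_singleton_grid_equals_single_scale(self):
        img, _ = render_scene(single_tube_scene(30.0, s=2.0))
        params = FilterParams(sigma_min=2.0, sigma_max=2.0, sigma_step=0.5)
        res = multiscale_vesselness(img, params)
        e = eigen_field(hessian_at_scale(img, 2.0, params.ridge_norm_gamma))
        rho = vesselness_at_scale(e, params.beta, res.gamma_used, params.polarity)
        np.testing.assert_allclose(res.rho, rho, atol=1e-12)
        assert np.all(res.sigma0 == 2.0)

    def test_scale_selection_matches_tube_width(self):
        img, _ = render_scene(single_tube_scene(90.0, s=2.0, size=96))
        res = multiscale_vesselness(img, FilterParams(sigma_min=0.5, sigma_max=6.0,
                                                      sigma_step=0.5))
        core = centerline_mask(90.0, 96, margin=20)
        assert 1.5 <= np.median(res.sigma0[core]) <= 2.5

    def test_orientation_recovery_30deg(self):
        img, truth = render_scene(single_tube_scene(30.0, s=1.5, size=96))
        res = multiscale_vesselness(img)
        core = centerline_mask(30.0, 96)
        err = axial_distance(res.theta0[core], 30.0)
        assert err.mean() <= 3.0

    def test_response_bounds_and_constant_image(self):
        img, _ = render_scene(single_tube_scene(60.0, s=1.0, noise=0.05, seed=3))
        res = multiscale_vesselness(img)
        assert np.all((res.rho >= 0.0) & (res.rho <= 1.0))
        flat = multiscale_vesselness(ScalarImage2D(np.full((32, 32), 0.3)))
        assert np.all(flat.rho == 0.0)

    def test_rotation_equivariance_90deg(self):
        img, _ = render_scene(single_tube_scene(30.0, s=2.0, size=96))
        res = multiscale_vesselness(img)
        res_rot = multiscale_vesselness(np.ascontiguousarray(np.rot90(img.pixels)))
        b = 13
        theta = res.theta0[b:-b, b:-b]
        # rot90 CCW: pixel (i,j) -> (N-1-j, i); orientation gains +90°
        theta_rot = np.rot90(res_rot.theta0, k=-1)[b:-b, b:-b]
        ok = np.isfinite(theta) & np.isfinite(theta_rot)
        strong = res.rho[b:-b, b:-b] > 0.5
        sel = ok & strong
        d = axial_distance(theta_rot[sel], theta[sel] + 90.0)
        assert d.mean() <= 2.0

    def test_empty_scale_grid_rejected(self):
        with pytest.raises(ValueError):
            FilterParams(sigma_min=4.0, sigma_max=1.0)
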