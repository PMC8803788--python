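"""Projector, z-filter, relative difference prior, OSEM and BSREM."""

import numpy as np
import pytest

from petdle.phantom import (Ellipsoid, PhantomSpec, Sinogram, build_phantom,
                            simulate_counts, thin_counts)
from petdle.recon import (EPS, ImageVolume, ProjectorConfig, ReconParams,
                          back_project, bsrem_reconstruct, forward_project,
                          osem_reconstruct, rdp_gradient, rdp_penalty,
                          z_filter)

CFG16 = ProjectorConfig(n_angles=16, radial_bins=24, psf_fwhm_mm=6.0)
CFG16_NOPSF = ProjectorConfig(n_angles=16, radial_bins=24, psf_fwhm_mm=0.0)


def explicit_matrix(config, n=16):
    """Dense system matrix built by pushing basis vectors through the
    forward projector — the adjointness oracle."""
    cols = []
    for j in range(n * n):
        e = np.zeros(n * n)
        e[j] = 1.0
        cols.append(forward_project(e.reshape(n, n), config).ravel())
    return np.array(cols).T  # (rows, n*n)


class TestProjector:
    def test_zero_volume_projects_to_zero(self):
        assert not forward_project(np.zeros((16, 16)), CFG16).any()
        assert not back_project(np.zeros((16, 24)), CFG16, 16, 16).any()

    def test_mass_preserved_at_every_angle(self):
        x = np.zeros((17, 17))
        x[8, 8] = 1.0
        cfg = ProjectorConfig(n_angles=16, radial_bins=25, psf_fwhm_mm=0.0)
        sums = forward_project(x, cfg).sum(axis=1)
        assert np.allclose(sums, 1.0, rtol=1e-6)

    def test_adjointness_against_explicit_matrix(self, rng):
        A = explicit_matrix(CFG16)
        for _ in range(10):
            x = rng.random((16, 16))
            y = rng.random((16, 24))
            lhs = float(forward_project(x, CFG16).ravel() @ y.ravel())
            rhs = float(x.ravel() @ back_project(y, CFG16, 16, 16).ravel())
            ref = float((A @ x.ravel()) @ y.ravel())
            assert lhs == pytest.approx(ref, rel=1e-5)
            assert rhs == pytest.approx(ref, rel=1e-5)

    def test_back_projection_positive_inside_fov(self):
        vol = back_project(np.ones((16, 24)), CFG16_NOPSF, 16, 16)
        assert (vol[4:12, 4:12] > 0).all()

    def test_radial_bins_must_cover_diagonal(self):
        with pytest.raises(ValueError, match="diagonal"):
            forward_project(np.zeros((32, 32)), CFG16)

    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError):
            forward_project(np.full((16, 16), -1.0), CFG16)


class TestZFilter:
    def test_axially_constant_volume_unchanged(self):
        v = np.random.default_rng(0).random((5, 5, 1)) * np.ones((5, 5, 8))
        assert np.allclose(z_filter(v), v, atol=1e-12)

    def test_impulse_response(self):
        v = np.zeros((3, 3, 9))
        v[1, 1, 4] = 1.0
        out = z_filter(v)
        assert np.allclose(out[1, 1, 3:6], [1 / 6, 4 / 6, 1 / 6])
        assert out.sum() == pytest.approx(1.0, abs=1e-10)

    def test_interior_support_preserves_total(self, rng):
        v = np.zeros((4, 4, 10))
        v[:, :, 3:7] = rng.random((4, 4, 4))
        assert z_filter(v).sum() == pytest.approx(v.sum(), abs=1e-10)

    def test_short_axis_is_identity(self):
        v = np.random.default_rng(1).random((4, 4, 2))
        assert np.array_equal(z_filter(v), v)


class TestRDP:
    def test_two_voxel_closed_form(self):
        # (a, b) = (2, 1), gamma = 2: both orderings give 1/(3+2) each
        x = np.array([2.0, 1.0]).reshape(2, 1, 1)
        assert rdp_penalty(x, gamma=2.0) == pytest.approx(0.4, abs=1e-6)

    def test_constant_image_has_zero_penalty_and_gradient(self):
        x = np.full((4, 4, 4), 3.0)
        assert rdp_penalty(x, 2.0) == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(rdp_gradient(x, 2.0), 0.0)

    def test_gradient_matches_finite_differences(self, rng):
        x = rng.random((5, 4, 3)) + 0.1
        g = rdp_gradient(x, 2.0)
        eps = 1e-6
        for idx in [(0, 0, 0), (2, 1, 1), (4, 3, 2), (1, 2, 0)]:
            xp = x.copy()
            xp[idx] += eps
            xm = x.copy()
            xm[idx] -= eps
            fd = (rdp_penalty(xp, 2.0) - rdp_penalty(xm, 2.0)) / (2 * eps)
            assert g[idx] == pytest.approx(fd, rel=1e-5, abs=1e-8)


def _disc_sinogram(nx=32, scale=50.0, noiseless=True, seed=0):
    cfg = ProjectorConfig(n_angles=32, radial_bins=48, psf_fwhm_mm=5.0)
    xx, yy = np.meshgrid(np.arange(nx) - (nx - 1) / 2,
                         np.arange(nx) - (nx - 1) / 2, indexing="ij")
    disc = ((xx ** 2 + yy ** 2) <= 10 ** 2).astype(float)[:, :, None]
    lam = scale * forward_project(disc, cfg)
    if noiseless:
        counts = np.round(lam).astype(np.int64)
    else:
        counts = np.random.default_rng(seed).poisson(lam)
    return disc, cfg, Sinogram(counts=counts, duration_fraction=1.0,
                               scale=scale, seed=seed)


class TestOSEM:
    def test_mlem_fits_noiseless_data(self):
        disc, cfg, sino = _disc_sinogram()
        params = ReconParams(algorithm="OSEM", iterations=200, subsets=1,
                             z_filter=False)
        vol = osem_reconstruct(sino, cfg, params, (32, 32, 1))
        fitted = forward_project(vol.values.astype(float), cfg)
        data = sino.counts / sino.scale
        nrmse = np.sqrt(np.mean((fitted - data) ** 2)) / data.mean()
        assert nrmse < 0.01

    def test_count_conservation_at_convergence(self):
        disc, cfg, sino = _disc_sinogram()
        params = ReconParams(algorithm="OSEM", iterations=200, subsets=1,
                             z_filter=False)
        vol = osem_reconstruct(sino, cfg, params, (32, 32, 1))
        fitted_total = forward_project(vol.values.astype(float), cfg).sum()
        assert fitted_total == pytest.approx(sino.counts.sum() / sino.scale,
                                             rel=0.005)

    def test_truth_is_a_fixed_point_on_noiseless_data(self):
        # one EM update started at the true image leaves the fitted
        # projections unchanged (the data term is already matched)
        disc, cfg, sino = _disc_sinogram(scale=1000.0)
        y = sino.counts / sino.scale
        proj = forward_project(disc, cfg)
        ratio = y / (proj + EPS)
        ones = np.ones_like(y)
        update = (back_project(ratio, cfg, 32, 32)
                  / (back_project(ones, cfg, 32, 32) + EPS))
        x1 = disc * update
        assert np.allclose(forward_project(x1, cfg), proj, rtol=2e-3)

    def test_suv_calibration_round_trip(self):
        # uniform SUV-1 phantom: interior of the reconstruction within 2%
        spec = PhantomSpec(grid_shape=(24, 24, 16), voxel_size=(4, 4, 4),
                           body=Ellipsoid((11.5, 11.5, 7.5), (9, 9, 7), 1.0))
        vol = build_phantom(spec)
        cfg = ProjectorConfig(n_angles=96, radial_bins=48, psf_fwhm_mm=0.0)
        lam = 200.0 * forward_project(vol.values.astype(float), cfg)
        sino = Sinogram(counts=np.round(lam).astype(np.int64),
                        duration_fraction=1.0, scale=200.0, seed=0)
        params = ReconParams(algorithm="OSEM", iterations=50, subsets=1,
                             z_filter=False)
        recon = osem_reconstruct(sino, cfg, params, spec.grid_shape)
        interior = recon.values[8:16, 8:16, 6:10]
        assert np.all(np.abs(interior - 1.0) < 0.02)

    def test_noise_increases_as_duration_decreases(self, tiny_spec):
        vol = build_phantom(tiny_spec)
        cfg = ProjectorConfig(n_angles=16, radial_bins=24, psf_fwhm_mm=6.0)
        sino = simulate_counts(vol, cfg, 5.0, seed=3)
        half = thin_counts(sino, 0.5, seed=4)
        params = ReconParams(algorithm="OSEM", iterations=2, subsets=8)
        full_rec = osem_reconstruct(sino, cfg, params, tiny_spec.grid_shape)
        half_rec = osem_reconstruct(half, cfg, params, tiny_spec.grid_shape)
        body = build_phantom(tiny_spec).values == 1.0
        assert half_rec.values[body].std() > full_rec.values[body].std()


class TestBSREM:
    def test_beta_zero_matches_osem(self, tiny_spec):
        vol = build_phantom(tiny_spec)
        cfg = ProjectorConfig(n_angles=16, radial_bins=24, psf_fwhm_mm=6.0)
        sino = simulate_counts(vol, cfg, 5.0, seed=9)
        osem = osem_reconstruct(
            sino, cfg, ReconParams(algorithm="OSEM", iterations=2, subsets=8),
            tiny_spec.grid_shape)
        bsrem = bsrem_reconstruct(
            sino, cfg, ReconParams(algorithm="BSREM", iterations=2, subsets=8,
                                   beta=0.0), tiny_spec.grid_shape)
        denom = np.abs(osem.values) + 1e-12
        assert np.max(np.abs(osem.values - bsrem.values) / denom) < 1e-6

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            ReconParams(algorithm="BSREM", beta=-1.0)

    def test_subsets_must_divide_angles(self, tiny_spec):
        vol = build_phantom(tiny_spec)
        cfg = ProjectorConfig(n_angles=16, radial_bins=24)
        sino = simulate_counts(vol, cfg, 5.0, seed=1)
        params = ReconParams(algorithm="OSEM", iterations=1, subsets=5)
        with pytest.raises(ValueError, match="divide"):
            osem_reconstruct(sino, cfg, params, tiny_spec.grid_shape)

    def test_regularisation_trades_noise_for_contrast(self, tiny_spec):
        # on the tiny grid a single comparison is robust: turning the
        # penalty on lowers both body noise and the lesion maximum (the
        # full monotone beta-grid behaviour is exercised at study scale
        # in the acceptance suite)
        vol = build_phantom(tiny_spec)
        cfg = ProjectorConfig(n_angles=16, radial_bins=24, psf_fwhm_mm=5.0)
        sino = simulate_counts(vol, cfg, 4.0, seed=12)
        body = vol.values == 1.0
        recs = {}
        for beta in (0.0, 4.0):
            recs[beta] = bsrem_reconstruct(
                sino, cfg, ReconParams(algorithm="BSREM", iterations=10,
                                       subsets=8, beta=beta),
                tiny_spec.grid_shape)
        assert recs[4.0].values[body].std() < recs[0.0].values[body].std()
        assert recs[4.0].values.max() < recs[0.0].values.max()


class TestImageVolume:
    def test_provenance_required(self):
        with pytest.raises(ValueError):
            ImageVolume(np.zeros((4, 4, 4)), (4, 4, 4), method="bogus",
                        duration_fraction=1.0)
        with pytest.raises(ValueError):
            ImageVolume(np.zeros((4, 4, 4)), (4, 4, 4), method="OSEM",
                        duration_fraction=0.0)

    def test_non_negative_enforced(self):
        with pytest.raises(ValueError):
            ImageVolume(np.full((4, 4, 4), -1.0), (4, 4, 4), method="OSEM",
                        duration_fraction=1.0)
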