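"""Surface extraction, profile sampling, model fitting, map filtering."""

import numpy as np
import pytest

from cortmap import (CTVolume, FitConfig, ThicknessMap, estimate_global_density,
                     estimate_thickness_map, extract_surface,
                     filter_thickness_map, fit_profile, sample_profile)
from cortmap.cbt import CBTModelParams, ProfileSamples
from cortmap.phantom import (PhantomSpec, blurred_profile, generate_line_profile,
                             generate_tibia_phantom)

DENS = (0.0, 1200.0, 300.0)


def make_slab_volume(spacing=0.2, thickness=5.0, sigma=0.9):
    """Planar cortex normal to x, with the continuous blurred closed form
    evaluated at the voxel centres (so the only sampling error is trilinear
    interpolation, not edge-position quantization)."""
    nx = int(40 / spacing)
    xw = np.arange(nx) * spacing - 20.0
    prof = blurred_profile(xw, 0.0, thickness, sigma, DENS)
    vol = np.broadcast_to(prof[:, None, None], (nx, 40, 40)).astype(np.float32)
    return CTVolume(vol.copy(), (spacing, spacing, spacing), (-20.0, 0.0, 0.0))


class TestExtractSurface:
    def test_cylinder_radius_recovered(self, noiseless_phantom):
        """Mean vertex radius matches the outer cortex radius to sub-voxel error."""
        spec = noiseless_phantom["spec"]
        mesh = noiseless_phantom["mesh"]
        zfrac = mesh.vertices[:, 2] / spec.tibial_length
        band = (zfrac > 0.45) & (zfrac < 0.55)
        r = np.hypot(mesh.vertices[band, 0], mesh.vertices[band, 1])
        r_true = spec.shaft_outer_radius_profile(zfrac[band])
        assert abs(np.mean(r - r_true)) < 0.35  # half the in-plane voxel

    def test_all_background_rejected(self):
        vol = CTVolume(np.zeros((10, 10, 10)), (1, 1, 1))
        with pytest.raises(ValueError, match="empty segmentation"):
            extract_surface(vol, threshold=600.0)

    def test_normals_point_outward(self, noiseless_phantom):
        mesh = noiseless_phantom["mesh"]
        radial = mesh.vertices[:, :2].copy()
        radial /= np.linalg.norm(radial, axis=1, keepdims=True)
        dots = np.einsum("ij,ij->i", mesh.vertex_normals[:, :2], radial)
        assert np.all(dots > 0)


class TestSampleProfile:
    def test_constant_volume_gives_constant_profile(self):
        vol = CTVolume(np.full((40, 40, 40), 77.0), (1, 1, 1))
        prof = sample_profile(vol, [20, 20, 20], [1, 0, 0], 5.0, 0.5)
        assert np.allclose(prof.value, 77.0)

    def test_slab_matches_closed_form_within_interpolation_error(self):
        """Fine-grid slab: trilinear sampling reproduces the model to ~2 HU RMS."""
        vol = make_slab_volume(spacing=0.2)
        prof = sample_profile(vol, [0.0, 4.0, 4.0], [-1.0, 0, 0], 9.0, 0.3)
        ref = blurred_profile(prof.x, 0.0, 5.0, 0.9, DENS)
        assert np.sqrt(np.mean((prof.value - ref) ** 2)) < 2.0

    def test_coarse_grid_interpolation_error_scale(self):
        """0.7 mm voxels: structured interpolation error ~h^2/8*max|y''| ~ 22 HU."""
        vol = make_slab_volume(spacing=0.7)
        prof = sample_profile(vol, [0.0, 14.0, 14.0], [-1.0, 0, 0], 9.0, 0.3)
        ref = blurred_profile(prof.x, 0.0, 5.0, 0.9, DENS)
        rms = np.sqrt(np.mean((prof.value - ref) ** 2))
        assert rms < 30.0  # bounded by the linear-interpolation curvature term

    def test_spacing_too_large_rejected(self):
        vol = CTVolume(np.zeros((10, 10, 10)), (1, 1, 1))
        with pytest.raises(ValueError, match="spacing"):
            sample_profile(vol, [5, 5, 5], [1, 0, 0], half_length=2.0, spacing=5.0)

    def test_fully_outside_rejected(self):
        vol = CTVolume(np.zeros((10, 10, 10)), (1, 1, 1))
        with pytest.raises(ValueError, match="outside"):
            sample_profile(vol, [500, 500, 500], [1, 0, 0], 2.0, 0.5)

    def test_truncated_profile_flagged(self):
        vol = CTVolume(np.zeros((40, 40, 40)), (1, 1, 1))
        prof = sample_profile(vol, [3, 20, 20], [-1, 0, 0], 9.0, 0.5)
        assert prof.truncated


class TestFitProfile:
    def test_sharp_edges_read_exactly(self):
        """Nearly unblurred profile: both edges recovered to 1e-3 mm, y1 free."""
        x, y = generate_line_profile(5.0, 0.0, DENS, sigma=0.05, spacing=0.25,
                                     half_length=9.0)
        cfg = FitConfig(sigma_bounds=(0.02, 3.0))
        fit = fit_profile(ProfileSamples(x, y), config=cfg)
        assert fit.converged
        assert fit.thickness == pytest.approx(5.0, abs=1e-3)

    def test_non_monotone_x_rejected(self):
        with pytest.raises(ValueError):
            ProfileSamples(np.array([0, 1, 1, 2, 3, 4, 5, 6.0]), np.zeros(8))

    def test_subvoxel_thickness_recovered(self):
        """t = 0.7 * spacing: error well below the sampling resolution."""
        spacing = 0.7
        t = 0.7 * spacing
        x, y = generate_line_profile(t, 0.0, DENS, sigma=0.9, spacing=spacing,
                                     half_length=9.0)
        fit = fit_profile(ProfileSamples(x, y), fixed_y1=1200.0)
        assert abs(fit.thickness - t) < spacing

    def test_fixed_y1_held_constant(self):
        x, y = generate_line_profile(3.0, 0.0, DENS, 0.9, 0.3, 9.0)
        fit = fit_profile(ProfileSamples(x, y), fixed_y1=1234.0)
        assert fit.y1 == 1234.0 and fit.y1_fixed


class TestGlobalDensity:
    def _fit(self, y1, t=5.0, sigma=1.0, conv=True):
        return CBTModelParams(0, y1, 300, 0, t, sigma, 1.0, conv)

    def test_constant_density_returned(self):
        assert estimate_global_density([self._fit(1200.0)] * 5) == 1200.0

    def test_phantom_noisy_estimate_within_2pct(self):
        rng = np.random.default_rng(3)
        fits = []
        for _ in range(200):
            t = rng.uniform(1, 8)
            x, y = generate_line_profile(t, 0.0, DENS, 0.9, 0.7, 12.0,
                                         noise_sd=20.0, rng=rng)
            fits.append(fit_profile(ProfileSamples(x, y)))
        est = estimate_global_density(fits)
        assert est == pytest.approx(1200.0, rel=0.02)

    def test_no_high_confidence_fits_rejected(self):
        with pytest.raises(ValueError, match="min_width_sigmas"):
            estimate_global_density([self._fit(1200.0, t=1.0, sigma=1.0)])
        with pytest.raises(ValueError):
            estimate_global_density([self._fit(1200.0, conv=False)])


class TestThicknessMap:
    def test_uniform_phantom_map_accuracy(self, pipeline_bundle):
        """Default 5 mm phantom: >=95% convergence, mean within 0.1 mm."""
        tmap = pipeline_bundle["thickness_map"]
        n_est = np.sum([f is not None for f in tmap.fits])
        assert tmap.n_converged / n_est >= 0.95
        assert np.nanmean(tmap.thickness) == pytest.approx(5.0, abs=0.1)

    def test_medial_lateral_contrast_recovered(self, ml_phantom_bundle):
        """6 mm medial / 4 mm lateral phantom: sector means within 0.3 mm."""
        mesh = ml_phantom_bundle["mesh"]
        tmap = ml_phantom_bundle["thickness_map"]
        az = np.arctan2(mesh.vertices[:, 1], mesh.vertices[:, 0])
        ok = tmap.converged
        # 60-degree wedges about the medial (-x, right side) and lateral poles
        medial = ok & (np.abs(np.abs(az) - np.pi) < np.pi / 6)
        lateral = ok & (np.abs(az) < np.pi / 6)
        assert np.nanmean(tmap.thickness[medial]) == pytest.approx(6.0, abs=0.3)
        assert np.nanmean(tmap.thickness[lateral]) == pytest.approx(4.0, abs=0.3)

    def test_map_determinism(self):
        spec = PhantomSpec(seed=21, noise_sd=15.0)
        volume, _ = generate_tibia_phantom(spec)
        mesh = extract_surface(volume, points_per_ring=24, ring_step=8)
        mask = np.zeros(len(mesh), bool)
        mid = np.argsort(np.abs(mesh.vertices[:, 2] - 165.0))[:48]
        mask[mid] = True
        m1 = estimate_thickness_map(volume, mesh, vertex_mask=mask)
        m2 = estimate_thickness_map(volume, mesh, vertex_mask=mask)
        assert np.array_equal(m1.thickness, m2.thickness, equal_nan=True)


class TestFilter:
    def _map(self, values):
        v = np.asarray(values, dtype=float)
        return ThicknessMap(v, np.isfinite(v), 1200.0)

    def _line_mesh(self, n):
        from cortmap.cbt import SurfaceMesh
        verts = np.column_stack([np.arange(n, dtype=float),
                                 np.zeros(n), np.zeros(n)])
        faces = [[i, i + 1, i] for i in range(n - 1)]  # degenerate, unused
        normals = np.tile([0.0, 0.0, 1.0], (n, 1))
        return SurfaceMesh(verts, np.asarray(faces), normals)

    def test_radius_zero_is_identity(self):
        mesh = self._line_mesh(10)
        tmap = self._map(np.arange(10.0))
        out = filter_thickness_map(tmap, mesh, 0.0)
        assert np.array_equal(out.thickness, tmap.thickness)

    def test_constant_map_unchanged(self):
        mesh = self._line_mesh(12)
        tmap = self._map(np.full(12, 5.0))
        out = filter_thickness_map(tmap, mesh, 3.0)
        assert np.allclose(out.thickness, 5.0)

    def test_step_map_stays_in_range(self):
        mesh = self._line_mesh(20)
        vals = np.where(np.arange(20) < 10, 6.0, 4.0)
        out = filter_thickness_map(self._map(vals), mesh, 2.5)
        assert np.all(out.thickness >= 4.0 - 1e-12)
        assert np.all(out.thickness <= 6.0 + 1e-12)

    def test_negative_radius_rejected(self):
        mesh = self._line_mesh(5)
        with pytest.raises(ValueError):
            filter_thickness_map(self._map(np.ones(5)), mesh, -1.0)
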