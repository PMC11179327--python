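"""Phantom generator: profiles, plateau points, volumes, cohorts."""

import numpy as np
import pytest
from scipy.special import erf

from cortmap.cohort import CohortSpec, default_groups, generate_cohort
from cortmap.morphometry import fit_mct_plane
from cortmap.phantom import (PhantomSpec, blurred_profile, generate_line_profile,
                             generate_mct_points, generate_tibia_phantom,
                             uniform_thickness)


class TestLineProfile:
    def test_degenerate_blur_gives_three_level_step(self):
        x, y = generate_line_profile(5.0, 0.0, (0, 1200, 300), sigma=1e-4,
                                     spacing=0.25, half_length=9.0)
        assert np.allclose(y[x < -0.01], 0.0, atol=1e-6)
        assert np.allclose(y[(x > 0.01) & (x < 4.99)], 1200.0, atol=1e-6)
        assert np.allclose(y[x > 5.01], 300.0, atol=1e-6)

    def test_matches_closed_form_via_erf(self):
        """Noiseless samples equal the two-edge erf formula computed independently."""
        x, y = generate_line_profile(2.0, 0.3, (0, 1200, 300), sigma=1.0,
                                     spacing=0.7, half_length=9.0)
        phi = lambda u: 0.5 * (1 + erf(u / np.sqrt(2)))
        ref = 0 + 1200 * phi((x - 0.3) / 1.0) + (300 - 1200) * phi((x - 2.3) / 1.0)
        assert np.allclose(y, ref, atol=1e-9)

    def test_monte_carlo_mean_converges_to_closed_form(self):
        reps, sd = 10_000, 20.0
        rng = np.random.default_rng(7)
        acc = None
        for _ in range(reps):
            x, y = generate_line_profile(2.0, 0.0, (0, 1200, 300), 1.0, 0.7,
                                         9.0, noise_sd=sd, rng=rng)
            acc = y if acc is None else acc + y
        mean = acc / reps
        ref = blurred_profile(x, 0.0, 2.0, 1.0, (0, 1200, 300))
        assert np.all(np.abs(mean - ref) < 3 * sd / np.sqrt(reps))

    def test_half_length_too_short_rejected(self):
        with pytest.raises(ValueError, match="half_length"):
            generate_line_profile(5.0, 0.0, (0, 1200, 300), 1.0, 0.3,
                                  half_length=6.0)


class TestMCTPoints:
    def test_flat_plateau_is_horizontal_coplanar(self):
        pts = generate_mct_points(0.0, 0.0, n=8, seed=0)
        assert np.allclose(pts[:, 2], pts[0, 2], atol=1e-12)

    def test_points_satisfy_plane_equation(self):
        b = np.tan(np.radians(12.2))
        pts = generate_mct_points(b, 0.05, n=8, seed=1, offset=3.0)
        assert np.allclose(pts[:, 2], 3.0 + b * pts[:, 0] + 0.05 * pts[:, 1],
                           atol=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            generate_mct_points(0.1, n=2, seed=0)

    def test_fitted_slope_unbiased_under_noise(self):
        """1e3 noisy digitizations: mean coronal-slope error below 0.005."""
        b = np.tan(np.radians(12.2))
        errs = []
        for rep in range(1000):
            pts = generate_mct_points(b, 0.0, n=8, noise_sd=0.5, seed=rep)
            plane = fit_mct_plane(pts)
            n = plane.normal
            slope = -n[0] / n[2]  # z = c + slope*x for normal (n0, n1, n2)
            errs.append(slope - b)
        assert abs(np.mean(errs)) < 0.005


class TestVolume:
    def test_same_seed_bit_identical(self):
        spec = PhantomSpec(seed=42)
        v1, _ = generate_tibia_phantom(spec)
        v2, _ = generate_tibia_phantom(PhantomSpec(seed=42))
        assert np.array_equal(v1.data, v2.data)

    def test_thickness_bound_violation_rejected(self):
        spec = PhantomSpec(thickness_field=uniform_thickness(0.1))
        with pytest.raises(ValueError, match="thickness_field"):
            generate_tibia_phantom(spec)

    def test_invalid_density_order_rejected(self):
        spec = PhantomSpec(densities=(0.0, 300.0, 1200.0))
        with pytest.raises(ValueError, match="densities"):
            spec.validate()

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError, match="tibial_length"):
            PhantomSpec(tibial_length=-5.0).validate()

    def test_landmarks_inside_volume(self):
        volume, gt = generate_tibia_phantom(PhantomSpec(seed=1))
        lm = gt.landmarks
        pts = np.vstack([getattr(lm, k) for k in lm._POINTS])
        assert np.all(volume.contains_world(pts))

    def test_ground_truth_mct_angle_matches_slope(self):
        spec = PhantomSpec(mct_coronal_slope=np.tan(np.radians(9.3)))
        _, gt = generate_tibia_phantom(spec)
        assert gt.true_mct_angle == pytest.approx(9.3, abs=1e-9)


class TestCohort:
    def test_empty_cohort_keeps_header(self):
        spec = CohortSpec(groups=default_groups(
            {g: 0 for g in ("oa_male", "oa_female", "healthy_male",
                            "healthy_female")}))
        df = generate_cohort(spec)
        assert len(df) == 0
        assert "fta" in df.columns and "cbt_most_proximal_medial" in df.columns

    def test_negative_sd_rejected(self):
        groups = default_groups()
        groups[0].demographics["age"] = (70.0, -1.0)
        with pytest.raises(ValueError, match="negative SD"):
            generate_cohort(CohortSpec(groups=groups))

    def test_determinism(self):
        a = generate_cohort(CohortSpec(seed=9))
        b = generate_cohort(CohortSpec(seed=9))
        assert a.equals(b)

    def test_oa_female_fta_mean_converges(self):
        """Sample FTA mean approaches the published OA-female 189.3 at large n."""
        spec = CohortSpec(groups=default_groups(
            {"oa_male": 0, "oa_female": 100_000, "healthy_male": 0,
             "healthy_female": 0}), seed=2)
        df = generate_cohort(spec)
        assert df["fta"].mean() == pytest.approx(189.3, abs=0.05)
        assert df["fta"].std() == pytest.approx(4.5, rel=0.01)

    def test_moments_converge_for_all_columns(self):
        """Per-column means and SDs match the group spec within 1% at n=1e5."""
        spec = CohortSpec(groups=default_groups(
            {"oa_male": 100_000, "oa_female": 0, "healthy_male": 0,
             "healthy_female": 0}), seed=3)
        df = generate_cohort(spec)
        g = spec.groups[0]
        for var, (m, sd) in g.demographics.items():
            assert df[var].mean() == pytest.approx(m, rel=0.01)
            assert df[var].std() == pytest.approx(sd, rel=0.015)
        for (band, sector), (m, sd) in list(g.regional.items())[:4]:
            col = f"cbt_{band}_{sector}"
            assert df[col].mean() == pytest.approx(m, rel=0.01)
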