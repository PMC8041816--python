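"""Radial profiling, Gaussian vs ring-convolved fitting, averaging, rendering."""

import numpy as np
import pytest
from scipy import stats as sps

from stormring import (LocalizationTable, average_profiles, fit_radial,
                       radial_profile, render_average_ring)
from stormring.errors import EmptyInputError, UsageError
from stormring.radial import RadialProfile


def table_at_distances(d, intensity=None):
    d = np.asarray(d, float)
    inten = np.ones_like(d) if intensity is None else np.asarray(intensity)
    return LocalizationTable(d, np.zeros_like(d), inten)


class TestRadialProfile:
    def test_single_distance_bin(self):
        prof = radial_profile(table_at_distances(np.full(50, 100.0)), (0, 0))
        assert prof.bin_mass[50] == 50  # bin [100, 102)
        assert prof.total_mass() == 50

    def test_half_open_bin_convention(self):
        prof = radial_profile(table_at_distances([102.0]), (0, 0))
        assert prof.bin_mass[51] == 1  # exactly 102 -> [102, 104)

    def test_mass_conservation(self, rng):
        t = LocalizationTable(rng.normal(0, 50, 300), rng.normal(0, 50, 300),
                              rng.lognormal(6, 1, 300))
        prof = radial_profile(t, (3.0, -7.0))
        assert prof.total_mass() == pytest.approx(t.intensity.sum(), rel=1e-12)

    def test_empty_table(self):
        t = table_at_distances([1.0]).with_events(np.array([], dtype=int))
        with pytest.raises(EmptyInputError):
            radial_profile(t, (0, 0))


class TestFitRadial:
    def _rice_profile(self, r=150.0, sigma=10.0, n=10_000, seed=0):
        d = sps.rice(b=r / sigma, scale=sigma).rvs(n, random_state=seed)
        return radial_profile(table_at_distances(d), (0, 0)), d

    def test_delta_ring_gaussian_peak(self):
        prof = radial_profile(table_at_distances(np.full(60, 150.0)
                                                 + np.linspace(-4, 4, 60)), (0, 0))
        fit = fit_radial(prof, model="gaussian")
        assert fit.radius_mean == pytest.approx(150.0, abs=1.1)

    def test_ring_convolved_recovers_rice_parameters(self):
        prof, d = self._rice_profile()
        fit = fit_radial(prof, model="ring_convolved_gaussian")
        assert fit.radius_mean == pytest.approx(150.0, abs=1.0)
        assert fit.width_sd == pytest.approx(10.0, abs=1.0)
        # maximum-likelihood oracle on the raw distances (moment-based start)
        b_ml, loc_ml, scale_ml = sps.rice.fit(d, d.mean() / d.std(), floc=0.0,
                                              scale=d.std())
        assert fit.radius_mean == pytest.approx(b_ml * scale_ml, abs=1.0)
        assert fit.width_sd == pytest.approx(scale_ml, abs=1.0)

    def test_gaussian_mean_exceeds_rice_radius(self):
        # the Rice mode sits outside the circle radius for sigma > 0
        prof, _ = self._rice_profile()
        g = fit_radial(prof, model="gaussian")
        rc = fit_radial(prof, model="ring_convolved_gaussian")
        assert g.radius_mean >= rc.radius_mean

    def test_best_model_selection_records_alternative(self):
        prof, _ = self._rice_profile()
        fit = fit_radial(prof, model="best")
        assert fit.model in ("gaussian", "ring_convolved_gaussian")
        assert len(fit.alternatives) == 1

    def test_qc_flag_threshold(self):
        prof, _ = self._rice_profile()
        fit = fit_radial(prof)
        assert fit.passed_qc == (fit.r_squared >= 0.8)


class TestAverageProfiles:
    def test_idempotence_on_identical_profiles(self):
        p = RadialProfile(bin_mass=np.array([0.0, 2.0, 5.0, 1.0]))
        avg = average_profiles([p, p])
        np.testing.assert_allclose(avg.bin_mass, p.bin_mass)
        assert avg.n_rings == 2

    def test_two_delta_profiles(self):
        a = radial_profile(table_at_distances(np.full(10, 140.0)), (0, 0))
        b = radial_profile(table_at_distances(np.full(10, 160.0)), (0, 0))
        avg = average_profiles([a, b])
        assert avg.bin_mass[70] == 5.0
        assert avg.bin_mass[80] == 5.0

    def test_total_mass_is_mean_of_inputs(self, rng):
        profs = [radial_profile(table_at_distances(rng.uniform(0, 200, 50)),
                                (0, 0)) for _ in range(4)]
        avg = average_profiles(profs)
        assert avg.total_mass() == pytest.approx(
            np.mean([p.total_mass() for p in profs]), rel=1e-12)

    def test_mixed_bin_widths_rejected(self):
        a = RadialProfile(bin_mass=np.ones(3))
        b = RadialProfile(bin_mass=np.ones(3), bin_width=4.0)
        with pytest.raises(UsageError):
            average_profiles([a, b])


class TestRenderAverageRing:
    def test_delta_profile_gives_annulus(self):
        prof = radial_profile(table_at_distances(np.full(30, 100.0)), (0, 0))
        img = render_average_ring(None, prof, image_half_width=150, pixel=2.0)
        n = img.shape[0]
        c = (np.arange(n) + 0.5) * 2.0 - 150
        xx, yy = np.meshgrid(c, c)
        rho = np.hypot(xx, yy)
        assert img[(rho < 80) | (rho > 120)].max() == 0.0
        # interpolation support is (99, 101]: the one-bin-wide annulus
        assert img[(rho > 99.5) & (rho < 101.0)].min() > 0.0

    def test_quarter_rotation_symmetry(self):
        prof = RadialProfile(bin_mass=np.arange(60.0))
        img = render_average_ring(None, prof, image_half_width=100, pixel=2.0)
        np.testing.assert_allclose(img, np.rot90(img), atol=1e-12)

    def test_integrated_mass_matches_polar_integral(self):
        prof = radial_profile(
            table_at_distances(sps.rice(b=15, scale=10).rvs(5000,
                                                            random_state=2)),
            (0, 0))
        img = render_average_ring(None, prof, image_half_width=300, pixel=1.0)
        # oracle: ∫ p(ρ) 2πρ dρ with p the interpolated profile
        rho = np.linspace(0, 300, 30_000)
        p = np.interp(rho, prof.bin_centers, prof.bin_mass, left=0, right=0)
        oracle = np.trapezoid(2 * np.pi * rho * p, rho)
        assert img.sum() * 1.0**2 == pytest.approx(oracle, rel=0.02)

    def test_bad_pixel_rejected(self):
        prof = RadialProfile(bin_mass=np.ones(5))
        with pytest.raises(UsageError):
            render_average_ring(None, prof, pixel=0)
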