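"""Side-view analysis: mixture split, canonical frame, two-Gaussian distance."""

import numpy as np
import pytest

from stormring import (LocalizationTable, SideViewConfig, analyze_side_view,
                       average_side_views, canonicalize_frame,
                       fit_axial_distance, generate_side_view,
                       split_two_clusters)
from stormring.axial import weighted_moment_ellipse

from conftest import best_two_cluster_partition


def two_blob_table(rng, sep=200.0, n=40, spread=5.0, ratio=2.0):
    x = np.concatenate([rng.normal(0, spread, n), rng.normal(0, spread, n)])
    y = np.concatenate([rng.normal(-sep / 2, spread, n),
                        rng.normal(sep / 2, spread, n)])
    inten = np.concatenate([np.full(n, 100.0 * ratio), np.full(n, 100.0)])
    return LocalizationTable(x, y, inten)


class TestSplitTwoClusters:
    def test_well_separated_blobs_match_nearest_center(self, rng):
        t = two_blob_table(rng)
        split = split_two_clusters(t, seed=0)
        nearest = (t.y > 0).astype(int)
        agree = (split.labels == nearest).mean()
        assert agree in (0.0, 1.0)  # identical up to label swap
        assert split.brighter == split.labels[0]

    def test_matches_exhaustive_likelihood_partition(self, rng):
        n = 8
        pts = np.vstack([rng.normal((0, -40), 6.0, (n, 2)),
                         rng.normal((0, 40), 6.0, (n, 2))])
        t = LocalizationTable(pts[:, 0], pts[:, 1], np.ones(2 * n))
        split = split_two_clusters(t, seed=1)
        oracle = best_two_cluster_partition(pts)
        agree = (split.labels == oracle.astype(int)).mean()
        assert agree in (0.0, 1.0)

    def test_equal_intensity_tie_broken_by_count(self, rng):
        x = np.concatenate([rng.normal(0, 4, 30), rng.normal(0, 4, 20)])
        y = np.concatenate([rng.normal(-80, 4, 30), rng.normal(80, 4, 20)])
        # equalize summed intensity across the two blobs
        inten = np.concatenate([np.full(30, 2.0), np.full(20, 3.0)])
        t = LocalizationTable(x, y, inten)
        split = split_two_clusters(t, seed=0)
        big = split.labels[0]  # first 30 events form the bigger cluster
        assert split.brighter == big
        assert split.provenance.get("brightness_tie_broken_by_count")

    def test_collinear_fallback_flagged(self):
        x = np.concatenate([np.linspace(0, 50, 20), np.linspace(150, 200, 20)])
        t = LocalizationTable(x, np.zeros_like(x), np.ones_like(x))
        split = split_two_clusters(t, seed=0)
        assert split.provenance.get("degenerate_1d_split")
        assert len(np.unique(split.labels)) == 2


class TestCanonicalizeFrame:
    def test_horizontal_bright_bar_dim_blob_above(self, rng):
        xb = rng.uniform(-100, 100, 60)
        t = LocalizationTable(
            np.concatenate([xb, rng.normal(0, 5, 30)]),
            np.concatenate([rng.normal(0, 4, 60), rng.normal(150, 5, 30)]),
            np.concatenate([np.full(60, 200.0), np.full(30, 50.0)]))
        split = split_two_clusters(t, seed=0)
        canon, rotation, prov = canonicalize_frame(t, split)
        assert abs(np.sin(rotation)) < 0.05  # rotation ~ 0 (mod pi)
        dim = split.labels == 1 - split.brighter
        assert canon.y[dim].mean() > 0

    def test_equivariance_under_pre_rotation(self, rng):
        t = two_blob_table(rng, spread=8.0)
        # elongate the brighter (lower) blob along x
        x = t.x.copy()
        x[:40] *= 6
        t = LocalizationTable(x, t.y, t.intensity)
        split = split_two_clusters(t, seed=0)
        canon0, rot0, _ = canonicalize_frame(t, split)
        phi = np.deg2rad(37)
        tr = t.rotated(phi)
        split_r = split_two_clusters(tr, seed=0)
        canon1, rot1, _ = canonicalize_frame(tr, split_r)
        assert ((rot1 - rot0 + phi) % np.pi) == pytest.approx(0, abs=0.02) or \
               ((rot1 - rot0 + phi) % np.pi) == pytest.approx(np.pi, abs=0.02)
        d0 = np.hypot(canon0.x[0] - canon0.x[1], canon0.y[0] - canon0.y[1])
        d1 = np.hypot(canon1.x[0] - canon1.x[1], canon1.y[0] - canon1.y[1])
        assert d0 == pytest.approx(d1, abs=1e-9)

    def test_weighted_ellipse_against_hand_linear_algebra(self):
        pts = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 1.0], [4.0, 1.0],
                        [1.0, 3.0], [3.0, 2.0]])
        w = np.array([1.0, 2.0, 1.0, 4.0, 2.0, 1.0])
        mu, vals, vecs = weighted_moment_ellipse(pts, w)
        wn = w / w.sum()
        mu_hand = (pts * wn[:, None]).sum(axis=0)
        cov_hand = np.zeros((2, 2))
        for p, wi in zip(pts, wn):
            c = (p - mu_hand)[:, None]
            cov_hand += wi * (c @ c.T)
        vals_hand, vecs_hand = np.linalg.eigh(cov_hand)
        np.testing.assert_allclose(mu, mu_hand, atol=1e-12)
        np.testing.assert_allclose(np.sort(vals), np.sort(vals_hand), atol=1e-12)


class TestFitAxialDistance:
    def test_two_bars_distance_recovered(self, rng):
        n = 2500
        t = LocalizationTable(
            rng.uniform(-150, 150, 2 * n),
            np.concatenate([rng.normal(-95, 10, n), rng.normal(95, 10, n)]),
            np.ones(2 * n))
        fit = fit_axial_distance(t)
        assert fit.distance == pytest.approx(190.0, abs=1.0)
        assert fit.passed_qc

    def test_coincident_bars_give_near_zero(self, rng):
        t = LocalizationTable(rng.uniform(-150, 150, 4000),
                              rng.normal(0, 12, 4000), np.ones(4000))
        fit = fit_axial_distance(t)
        assert fit.distance < 2.0

    def test_translation_invariance_of_distance(self, rng):
        n = 1500
        y = np.concatenate([rng.normal(-80, 8, n), rng.normal(80, 8, n)])
        x = rng.uniform(-100, 100, 2 * n)
        t = LocalizationTable(x, y, np.ones(2 * n))
        f0 = fit_axial_distance(t)
        f1 = fit_axial_distance(t.translated(0.0, 57.0))
        assert f1.distance == pytest.approx(f0.distance, abs=0.2)


class TestAverageSideViews:
    def test_identical_datasets_preserve_distance(self):
        t, _ = generate_side_view(SideViewConfig(seed=4))
        fit = analyze_side_view(t, seed=4)
        cohort = average_side_views([fit, fit, fit])
        assert cohort.summary.distance == pytest.approx(fit.distance, abs=0.1)
        assert cohort.n_datasets == 3

    def test_outer_product_image_rank_one(self):
        t, _ = generate_side_view(SideViewConfig(seed=5))
        fit = analyze_side_view(t, seed=5)
        cohort = average_side_views([fit])
        s = np.linalg.svd(cohort.image, compute_uv=False)
        assert s[1] <= 1e-12 * s[0]

    def test_cohort_recovery_true_separation(self):
        fits = []
        for i in range(50):
            t, _ = generate_side_view(SideViewConfig(
                seed=300 + i, bar_separation=190.0, bar_thickness_sd=6.6,
                localization_sd=10.0))
            fits.append(analyze_side_view(t, seed=i))
        cohort = average_side_views(fits)
        assert cohort.summary.distance == pytest.approx(190.0, abs=1.0)
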