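"""Synthetic-data generator: bookkeeping, distribution laws, determinism."""

import numpy as np
import pytest
from scipy import stats as sps

from stormring import (LinkageConfig, SideViewConfig, TopViewConfig,
                       apply_linkage, generate_side_view, generate_top_view,
                       write_molecule_list)
from stormring.errors import ValidationError


def noiseless_config(**kw):
    base = dict(n_clusters=9, ring_radius=150.0, cluster_angular_jitter=0.0,
                fluorophores_per_cluster=1, cluster_spread=0.0,
                blinks_per_fluorophore=1, exact_blinks=True,
                localization_sd=0.0, background_events=0, seed=0)
    base.update(kw)
    return TopViewConfig(**base)


class TestTopView:
    def test_noiseless_degenerate_case(self):
        t, truth = generate_top_view(noiseless_config())
        assert len(t) == 9
        r = np.hypot(t.x, t.y)
        np.testing.assert_allclose(r, 150.0, atol=1e-9)
        ang = np.sort(np.mod(np.arctan2(t.y, t.x), 2 * np.pi))
        np.testing.assert_allclose(ang, 2 * np.pi * np.arange(9) / 9, atol=1e-9)

    def test_event_count_bookkeeping(self):
        cfg = TopViewConfig(fluorophores_per_cluster=5,
                            blinks_per_fluorophore=10, exact_blinks=True,
                            background_events=40, seed=3)
        t, _ = generate_top_view(cfg)
        assert len(t) == 9 * 5 * 10 + 40

    def test_mean_radius_matches_rice_law(self):
        # pure localization blur around circle points: radii are Rician
        cfg = noiseless_config(localization_sd=10.0, fluorophores_per_cluster=60,
                               blinks_per_fluorophore=20, seed=11)
        t, truth = generate_top_view(cfg)
        emp = np.hypot(t.x, t.y).mean()
        oracle = sps.rice.mean(b=150.0 / 10.0, scale=10.0)
        assert emp == pytest.approx(oracle, abs=3 * 10 / np.sqrt(len(t)))

    def test_radii_follow_rice_distribution(self):
        cfg = noiseless_config(localization_sd=10.0, fluorophores_per_cluster=60,
                               blinks_per_fluorophore=20, seed=4)
        t, _ = generate_top_view(cfg)
        r = np.hypot(t.x, t.y)[:10_000]
        ks = sps.kstest(r, sps.rice(b=15.0, scale=10.0).cdf)
        crit_1pct = 1.63 / np.sqrt(r.size)
        assert ks.statistic < crit_1pct

    def test_seeded_reproducibility_bytes(self, tmp_path):
        cfg = TopViewConfig(seed=9)
        for i in (1, 2):
            t, _ = generate_top_view(cfg)
            write_molecule_list(t, tmp_path / f"run{i}.tsv")
        assert (tmp_path / "run1.tsv").read_bytes() == \
               (tmp_path / "run2.tsv").read_bytes()

    def test_missing_clusters_change_only_those_clusters(self):
        full, tf = generate_top_view(TopViewConfig(seed=5))
        part, tp = generate_top_view(TopViewConfig(seed=5,
                                                   missing_cluster_indices=(0, 4)))
        keep = ~np.isin(tf.fluorophore_cluster[np.maximum(tf.event_fluorophore, 0)],
                        [0, 4]) | (tf.event_fluorophore < 0)
        np.testing.assert_array_equal(full.x[keep], part.x)
        np.testing.assert_array_equal(full.y[keep], part.y)

    def test_invalid_config_lists_fields(self):
        with pytest.raises(ValidationError) as err:
            TopViewConfig(ring_radius=-1, background_events=-2)
        assert "ring_radius" in err.value.fields
        assert "background_events" in err.value.fields


class TestSideView:
    def test_noiseless_separation_exact(self):
        cfg = SideViewConfig(bar_separation=190.0, bar_thickness_sd=0.0,
                             localization_sd=0.0, background_events=0,
                             rotation=0.0, seed=1)
        t, truth = generate_side_view(cfg)
        y_ref = t.y[truth.event_bar == 0].mean()
        y_tgt = t.y[truth.event_bar == 1].mean()
        assert y_tgt - y_ref == pytest.approx(190.0, abs=1e-9)

    def test_rotation_is_rigid(self):
        t0, _ = generate_side_view(SideViewConfig(seed=2, rotation=0.0))
        t1, _ = generate_side_view(SideViewConfig(seed=2, rotation=np.pi / 4))
        d0 = np.hypot(t0.x[:50, None] - t0.x[None, :50],
                      t0.y[:50, None] - t0.y[None, :50])
        d1 = np.hypot(t1.x[:50, None] - t1.x[None, :50],
                      t1.y[:50, None] - t1.y[None, :50])
        np.testing.assert_allclose(d0, d1, atol=1e-9)

    def test_brightness_ratio_expectation(self):
        cfg = SideViewConfig(brightness_ratio=3.0, events_per_bar=4000,
                             background_events=0, seed=7)
        t, truth = generate_side_view(cfg)
        ratio = (t.intensity[truth.event_bar == 0].sum()
                 / t.intensity[truth.event_bar == 1].sum())
        assert 2.5 < ratio < 3.5


class TestApplyLinkage:
    def test_zero_length_antibody_is_identity_in_distribution(self):
        t, truth = generate_top_view(TopViewConfig(seed=8, background_events=0))
        cfg = LinkageConfig(antibody_length=0.0, primary_label_offset=0.0,
                            secondary_offset=0.0, mode="indirect")
        out, _ = apply_linkage(t, truth, cfg, seed=1)
        # same fluorophore positions, fresh blink scatter: means agree
        assert out.x.mean() == pytest.approx(t.x.mean(), abs=1.5)
        assert np.hypot(out.x, out.y).mean() == pytest.approx(
            np.hypot(t.x, t.y).mean(), abs=1.5)

    def test_direct_mean_displacement_half_length(self):
        cfg = noiseless_config(fluorophores_per_cluster=400, seed=13)
        t, truth = generate_top_view(cfg)
        out, _ = apply_linkage(t, truth, LinkageConfig(mode="direct"), seed=2)
        disp = np.hypot(out.x - t.x, out.y - t.y)
        assert disp.mean() == pytest.approx(6.0, abs=0.3)

    def test_indirect_bounded_by_triangle_inequality(self):
        cfg = noiseless_config(fluorophores_per_cluster=400,
                               blinks_per_fluorophore=30, seed=14)
        t, truth = generate_top_view(cfg)
        out, _ = apply_linkage(t, truth, LinkageConfig(mode="indirect"), seed=3)
        disp = np.hypot(out.x - t.x, out.y - t.y)
        assert disp.max() <= 12.0 + 6.0 + 1e-9
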