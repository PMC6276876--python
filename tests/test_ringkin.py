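"""Ring detection, constriction-speed fitting, and ring density."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from furrowquant import ringkin, synthgen
from furrowquant.ringkin import (constriction_speed, detect_rings,
                                 ring_density, track_rings)


def _field(**overrides):
    defaults = dict(n_rings=50, radius0=3.0, slope=0.0, n_frames=1,
                    pixel_size=0.2, noise_sd=0.0, seed=7)
    defaults.update(overrides)
    return synthgen.make_ring_field(synthgen.RingFieldConfig(**defaults))


class TestDetectRings:
    def test_noiseless_50_rings_recall_and_radius(self):
        field = _field()
        det = detect_rings(field.images[0], 1.5, 4.5)
        truth = field.truth
        assert len(det) >= 48
        tree = cKDTree(truth[["x", "y"]].to_numpy())
        d, idx = tree.query(det[["x", "y"]].to_numpy())
        matched = d < 1.0
        assert matched.mean() >= 0.95  # precision
        assert matched.sum() >= 0.95 * len(truth)  # recall
        r_err = np.abs(det["r"].to_numpy()[matched]
                       - truth["r"].to_numpy()[idx[matched]])
        assert r_err.max() < 0.25

    def test_blank_image_no_detections(self):
        det = detect_rings(np.zeros((100, 100)), 1.5, 4.5, pixel_size=0.2)
        assert det.empty

    def test_concentric_rings_both_found(self):
        px = 0.2
        yy, xx = np.mgrid[0:200, 0:200]
        img = np.zeros((200, 200))
        for r_um in (2.0, 3.5):  # radii differ by 7.5 px
            dist = np.hypot(xx - 100, yy - 100) * px
            img += np.exp(-((dist - r_um) ** 2) / (2 * 0.25**2))
        det = detect_rings(img, 1.5, 4.5, pixel_size=px)
        assert len(det) == 2
        assert sorted(det["r"].round(1)) == pytest.approx([2.0, 3.5],
                                                          abs=0.2)

    def test_rmin_not_below_rmax(self):
        with pytest.raises(ValueError):
            detect_rings(np.zeros((50, 50)), 4.0, 2.0, pixel_size=0.2)


class TestConstrictionSpeed:
    def test_closed_form_slope_three_points(self):
        # oracle: OLS on three points by hand: slope = -0.048
        fit = constriction_speed({0: [1.0], 1: [0.952], 2: [0.904]})
        assert fit.slope_per_frame == pytest.approx(-0.048, abs=1e-12)

    def test_constant_diameters_zero_slope(self):
        fit = constriction_speed({0: [2.0, 2.0], 1: [2.0], 2: [2.0]})
        assert fit.slope_per_frame == pytest.approx(0.0, abs=1e-12)

    def test_normalization_anchor_is_frame0_mean(self):
        fit = constriction_speed({0: [2.0, 4.0], 1: [3.0]})
        assert fit.normalized.query("frame == 0")["diameter_norm"] \
            .mean() == pytest.approx(1.0)

    def test_fewer_than_two_frames_rejected(self):
        with pytest.raises(ValueError):
            constriction_speed({0: [1.0, 1.0]})

    def test_slope_recovery_unbiased_at_10pct_noise(self):
        # mean fitted slope over seeds within 5% of the generator slope
        slopes = []
        for seed in range(12):
            field = _field(n_rings=30, slope=-0.03, n_frames=4,
                           noise_sd=0.1, seed=seed)
            diam = {f: 2 * detect_rings(img, 1.5, 4.5)["r"].to_numpy()
                    for f, img in enumerate(field.images)}
            slopes.append(constriction_speed(diam).slope_per_frame)
        assert np.mean(slopes) == pytest.approx(-0.03, rel=0.05)


class TestRingDensity:
    def test_simple_count_per_area(self):
        det = pd.DataFrame({"x": np.linspace(1, 9, 20),
                            "y": np.linspace(1, 9, 20),
                            "r": 1.0, "score": 1.0})
        mask = np.ones((50, 50), bool)  # 10 μm x 10 μm at 0.2 μm pixels
        assert ring_density(det, mask, 0.2) == pytest.approx(0.2)

    def test_zero_area_mask_rejected(self):
        det = pd.DataFrame({"x": [1.0], "y": [1.0], "r": [1.0],
                            "score": [1.0]})
        with pytest.raises(ValueError):
            ring_density(det, np.zeros((10, 10), bool), 0.2)

    def test_printed_count_ratio(self):
        # counts over equal areas: 302 activated / 431 control rings
        mask = np.ones((100, 100), bool)
        rng = np.random.default_rng(0)

        def det_of(n):
            return pd.DataFrame({
                "x": rng.uniform(0, 20, n), "y": rng.uniform(0, 20, n),
                "r": 1.0, "score": 1.0})

        ratio = ring_density(det_of(302), mask, 0.2) \
            / ring_density(det_of(431), mask, 0.2)
        assert ratio == pytest.approx(302 / 431, rel=1e-9)

    @pytest.mark.parametrize("factor", [1.1, 1.35, 2.0])
    def test_compaction_ratio_recovery_within_10pct(self, factor):
        base = synthgen.RingFieldConfig(
            n_rings=256, radius0=3.0, slope=0.0, n_frames=1,
            pixel_size=0.25, spacing=11.0, jitter_sd=0.3, noise_sd=0.05,
            seed=int(factor * 10))
        probe = synthgen.make_ring_field(base)
        h_um, w_um = probe.field_size
        region = (w_um / 2, h_um / 2, 0.22 * min(h_um, w_um))
        counts_in = counts_out = 0.0
        area_in = area_out = 0.0
        for seed in range(3):
            field = synthgen.make_ring_field(dataclasses.replace(
                base, seed=seed * 7 + 1,
                compaction_region=region, compaction_factor=factor))
            det = detect_rings(field.images[0], 1.5, 4.5)
            h, w = field.images[0].shape[1:]
            yy, xx = np.mgrid[0:h, 0:w]
            px = base.pixel_size
            rho = np.hypot(xx * px - region[0], yy * px - region[1])
            inside = rho <= region[2]
            x0, y0, x1, y1 = field.seeded_box
            r_out = 1.3 * region[2] * np.sqrt(factor) + 2 * base.radius0
            outside = (rho > r_out) \
                & (xx * px >= x0) & (xx * px <= x1) \
                & (yy * px >= y0) & (yy * px <= y1)
            counts_in += ring_density(det, inside, px) * inside.sum()
            counts_out += ring_density(det, outside, px) * outside.sum()
            area_in += inside.sum()
            area_out += outside.sum()
        ratio = (counts_in / area_in) / (counts_out / area_out)
        assert ratio == pytest.approx(factor, rel=0.10)


class TestTrackRings:
    def test_tracks_follow_constricting_rings(self):
        field = _field(n_rings=16, slope=-0.04, n_frames=4)
        frames = [detect_rings(img, 1.5, 4.5) for img in field.images]
        tracks = track_rings(frames, max_displacement=1.5)
        persistent = tracks.groupby("track_id")["frame"].nunique()
        assert (persistent == 4).sum() >= 15
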