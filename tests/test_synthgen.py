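"""Generator contracts: determinism, conservation laws, rendering truth."""

import numpy as np
import pytest
from scipy import stats as sps

from furrowquant import synthgen
from furrowquant.synthgen import (MyosinConfig, PulseConfig, RingFieldConfig,
                                  ShapeProgram, TissueConfig,
                                  make_myosin, make_pulse_traces,
                                  make_ring_field, make_tissue,
                                  saturating_rise, decay_fold)


def _small_tissue(**overrides):
    defaults = dict(
        shape_program=ShapeProgram.columnar(area=25.0, length=8.0),
        grid_shape=(3, 3), cell_footprint=5.0, n_slices=10, dz=1.0,
        pixel_size=0.25, noise_sd=0.0, seed=7)
    defaults.update(overrides)
    return make_tissue(TissueConfig(**defaults))


class TestTissue:
    def test_constant_volume_program_has_flat_truth_volume(self):
        program = ShapeProgram.elongating(36.0, 25.0, 40.0, 8,
                                          constant_volume=True)
        tissue = _small_tissue(shape_program=program, n_slices=42,
                               cell_footprint=8.0)
        per_cell = tissue.truth.groupby("cell_id")["volume"]
        cv = (per_cell.std(ddof=0) / per_cell.mean()).max()
        assert cv < 1e-3

    def test_cylinder_program_truth_ab_ratio_is_one(self, cylinder_tissue):
        truth = cylinder_tissue.truth
        assert np.allclose(truth["apical_area"], truth["basal_area"])

    def test_same_seed_bit_identical(self):
        a = _small_tissue(noise_sd=0.05)
        b = _small_tissue(noise_sd=0.05)
        for sa, sb in zip(a.membrane, b.membrane):
            np.testing.assert_array_equal(sa.data, sb.data)
        for la, lb in zip(a.labels, b.labels):
            np.testing.assert_array_equal(la, lb)

    def test_rendering_fidelity_volume_within_2pct(self, cylinder_tissue):
        # measuring truth labels directly reproduces truth-table volumes
        lab = cylinder_tissue.labels[0]
        cfg = cylinder_tissue.config
        truth_vol = cylinder_tissue.truth["volume"].iloc[0]
        for cid in (1, 6, 16):
            measured = (lab == cid).sum() * cfg.pixel_size**2 * cfg.dz
            assert measured == pytest.approx(truth_vol, rel=0.02)

    def test_footprint_below_two_pixels_rejected(self):
        with pytest.raises(ValueError, match="footprint"):
            _small_tissue(cell_footprint=0.4, pixel_size=0.25)

    def test_labels_and_truth_consistent(self):
        tissue = _small_tissue()
        n_occ = int(tissue.truth["length"].iloc[0] / tissue.config.dz)
        occupied = (tissue.labels[0].max(axis=(1, 2)) > 0).sum()
        assert occupied == n_occ


class TestMyosin:
    def _masks(self, tissue):
        h, w = tissue.labels[0].shape[1:]
        ar = np.zeros((h, w), bool)
        ar[:, : w // 2] = True
        return ar, ~ar

    def test_decay_fold_five_noiseless_endpoint(self):
        tissue = _small_tissue(
            shape_program=ShapeProgram.columnar(25.0, 8.0, n_frames=4),
            n_slices=10)
        ar, nr = self._masks(tissue)
        duration = tissue.config.frame_times[-1]
        cfg = MyosinConfig(
            basal_amplitude={"all": decay_fold(5.0, duration)},
            region_masks={"all": ar | nr}, background=0.0, noise_sd=0.0)
        stacks = make_myosin(tissue, cfg)
        basal_idx = int(tissue.truth["length"].iloc[0]) - 1
        first = stacks[0].data[basal_idx].mean()
        last = stacks[-1].data[basal_idx].mean()
        assert last / first == pytest.approx(0.2, rel=1e-6)

    def test_saturating_rise_reaches_fold_at_duration(self):
        amp = saturating_rise(1.6, 360.0)
        assert amp(0.0) == pytest.approx(1.0)
        assert amp(360.0) == pytest.approx(1.6)

    def test_rendered_axial_fwhm_matches_config(self):
        # oracle: dense evaluation of the noiseless rendered profile and
        # direct half-maximum crossing
        tissue = _small_tissue(n_slices=24,
                               shape_program=ShapeProgram.columnar(25.0, 16.0))
        ar, nr = self._masks(tissue)
        cfg = MyosinConfig(
            basal_amplitude={"all": lambda t: 1.0},
            region_masks={"all": ar | nr}, basal_fwhm=3.4,
            background=0.0, noise_sd=0.0)
        stack = make_myosin(tissue, cfg)[0]
        profile = stack.data.mean(axis=(1, 2))
        z = stack.z_um
        dense_z = np.linspace(z[0], z[-1], 20001)
        dense = np.interp(dense_z, z, profile)
        half = dense.max() / 2
        above = dense_z[dense >= half]
        assert above[-1] - above[0] == pytest.approx(3.4, abs=0.1)

    def test_region_not_covering_cells_rejected(self):
        tissue = _small_tissue()
        h, w = tissue.labels[0].shape[1:]
        empty = np.zeros((h, w), bool)
        cfg = MyosinConfig(basal_amplitude={"x": lambda t: 1.0},
                           region_masks={"x": empty})
        with pytest.raises(ValueError, match="covers no cell"):
            make_myosin(tissue, cfg)


class TestRingField:
    def test_truth_diameter_follows_slope(self):
        field = make_ring_field(RingFieldConfig(
            n_rings=9, slope=-0.01, n_frames=5, radius_jitter_sd=0.0,
            seed=0))
        truth = field.truth
        d0 = truth[truth.frame == 0]["r"].mean()
        d4 = truth[truth.frame == 4]["r"].mean()
        assert d4 / d0 == pytest.approx(0.96, rel=1e-9)

    def test_compaction_density_ratio_in_truth(self):
        base = RingFieldConfig(n_rings=400, slope=0.0, n_frames=1,
                               spacing=10.0, jitter_sd=0.3, seed=5)
        probe = make_ring_field(base)
        h_um, w_um = probe.field_size
        region = (w_um / 2, h_um / 2, 0.2 * min(h_um, w_um))
        import dataclasses

        field = make_ring_field(dataclasses.replace(
            base, compaction_region=region, compaction_factor=1.35))
        x0, y0, x1, y1 = field.seeded_box
        t = field.truth
        rho = np.hypot(t.x - region[0], t.y - region[1])
        r_in = region[2]
        n_in = (rho <= r_in).sum()
        area_in = np.pi * r_in**2
        r_out = 1.3 * r_in * np.sqrt(1.35) + 3.0
        sel_out = (rho > r_out) & (t.x >= x0) & (t.x <= x1) \
            & (t.y >= y0) & (t.y <= y1)
        # outside area = seeded box minus the excluded disk
        area_out = (x1 - x0) * (y1 - y0) - np.pi * r_out**2
        ratio = (n_in / area_in) / (sel_out.sum() / area_out)
        assert ratio == pytest.approx(1.35, rel=0.12)

    def test_zero_rings_blank_image(self):
        field = make_ring_field(RingFieldConfig(n_rings=0, n_frames=2))
        assert field.truth.empty
        assert np.all(field.images[0].data == 0)


class TestPulses:
    def test_non_ratchet_noiseless_peaks_at_baseline(self):
        cfg = PulseConfig(n_traces=5, noise_sd=0.0, seed=3)
        ps = make_pulse_traces(cfg)
        assert np.allclose(ps.peaks["area_peak"], cfg.baseline_area)

    def test_ratchet_noiseless_steps_by_lockin(self):
        cfg = PulseConfig(
            n_traces=3, class_mix={"ratchet": 1.0, "non_ratchet": 0.0},
            ratchet_lockin=6.0, noise_sd=0.0, duration=400.0, seed=3)
        ps = make_pulse_traces(cfg)
        for _, grp in ps.peaks.groupby("trace_id"):
            steps = np.diff(grp.sort_values("t_peak")["area_peak"])
            clamped = grp["area_peak"].to_numpy()[1:] <= cfg.min_area
            assert np.allclose(steps[~clamped], -6.0)

    def test_mixture_counts_within_binomial_99ci(self):
        cfg = PulseConfig(
            n_traces=407,
            class_mix={"non_ratchet": 0.85, "ratchet": 0.15}, seed=11)
        ps = make_pulse_traces(cfg)
        n_non = (ps.labels["class"] == "non_ratchet").sum()
        lo = sps.binom.ppf(0.005, 407, 0.85)
        hi = sps.binom.ppf(0.995, 407, 0.85)
        assert lo <= n_non <= hi

    def test_duration_below_two_periods_rejected(self):
        with pytest.raises(ValueError, match="two periods"):
            PulseConfig(duration=100.0, period=90.0)

    def test_determinism(self):
        a = make_pulse_traces(PulseConfig(n_traces=4, seed=9))
        b = make_pulse_traces(PulseConfig(n_traces=4, seed=9))
        assert a.traces.equals(b.traces)
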