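"""Myosin quantification: z-profile fits, levels, projections, fold change."""

import numpy as np
import pytest

from furrowquant import myoquant, synthgen
from furrowquant.io import ImageStack
from furrowquant.myoquant import (PeakNotFoundError, apical_levels,
                                  basal_level, basal_projection, fit_timecourse,
                                  fold_change, zprofile)

FWHM = 2 * np.sqrt(2 * np.log(2))


def _profile_stack(profile, pixel_size=0.25, dz=1.0, shape=(16, 16)):
    data = np.repeat(np.asarray(profile, float)[:, None, None],
                     shape[0], axis=1).repeat(shape[1], axis=2)
    return ImageStack(data=data, pixel_size=pixel_size, dz=dz)


def _gauss(z, center, fwhm, amp=1.0, offset=0.0):
    sigma = fwhm / FWHM
    return offset + amp * np.exp(-((z - center) ** 2) / (2 * sigma**2))


class TestZProfile:
    def test_noiseless_gaussian_recovered_exactly(self):
        z = np.arange(40.0)
        stack = _profile_stack(_gauss(z, 30.0, 4.0, amp=2.0, offset=0.5))
        mask = np.ones((16, 16), bool)
        peak = zprofile(stack, mask)
        assert peak.peak_z == pytest.approx(30.0, abs=0.01)
        assert peak.fwhm == pytest.approx(4.0, abs=0.05)

    def test_two_peak_profile_returns_basal_not_apical(self):
        # oracle: grid search restricted to the basal half
        z = np.arange(40.0)
        profile = (_gauss(z, 4.0, 4.0, amp=5.0)      # bright apical peak
                   + _gauss(z, 31.0, 3.0, amp=1.0))  # dim basal peak
        basal_half = profile[len(profile) // 2:]
        oracle_z = float(np.argmax(basal_half) + len(profile) // 2)
        stack = _profile_stack(profile)
        peak = zprofile(stack, np.ones((16, 16), bool))
        assert peak.peak_z == pytest.approx(oracle_z, abs=1.0)
        assert abs(peak.peak_z - 4.0) > 20  # not captured by the apical peak

    def test_flat_profile_raises(self):
        stack = _profile_stack(np.full(20, 3.0))
        with pytest.raises(PeakNotFoundError):
            zprofile(stack, np.ones((16, 16), bool))

    def test_fit_matches_grid_search_oracle_within_1pct(self):
        # dense grid-search oracle over (center, fwhm) on noiseless profiles
        z = np.arange(36.0)
        for fwhm_true in (2.0, 4.0, 6.0, 8.0):
            profile = _gauss(z, 27.0, fwhm_true, amp=1.7, offset=0.2)
            stack = _profile_stack(profile)
            peak = zprofile(stack, np.ones((16, 16), bool))
            centers = np.linspace(24.0, 30.0, 241)
            widths = np.linspace(0.5 * fwhm_true, 1.5 * fwhm_true, 201)
            best = None
            for c in centers:
                for wd in widths:
                    model = _gauss(z, c, wd, amp=1.7, offset=0.2)
                    sse = np.sum((model - profile) ** 2)
                    if best is None or sse < best[0]:
                        best = (sse, c, wd)
            _, c_star, w_star = best
            assert peak.peak_z == pytest.approx(c_star, rel=0.01)
            assert peak.fwhm == pytest.approx(w_star, rel=0.01)


class TestBasalLevel:
    def test_uniform_intensity_level_independent_of_window(self):
        stack = _profile_stack(np.full(11, 10.0), pixel_size=1.0)
        mask = np.ones((16, 16), bool)
        for window in (3, 5):
            lev = basal_level(stack, mask, peak_z=5.0, window=window)
            assert lev.level == pytest.approx(10.0)

    def test_single_bright_slice_averages_over_window(self):
        stack = _profile_stack([0, 0, 5, 0, 0], pixel_size=1.0)
        lev = basal_level(stack, np.ones((16, 16), bool), peak_z=2.0,
                          window=5)
        assert lev.level == pytest.approx(1.0)

    def test_window_truncated_at_edge_flagged(self):
        stack = _profile_stack(np.arange(6.0), pixel_size=1.0)
        lev = basal_level(stack, np.ones((16, 16), bool), peak_z=5.0,
                          window=5)
        assert lev.truncated

    def test_doubled_amplitude_doubles_level(self):
        # oracle: direct summation on the truth volume
        z = np.arange(20.0)
        mask = np.ones((16, 16), bool)
        levels = []
        for amp in (1.0, 2.0):
            stack = _profile_stack(_gauss(z, 15.0, 3.0, amp=amp))
            levels.append(basal_level(stack, mask, peak_z=15.0).level)
        assert levels[1] / levels[0] == pytest.approx(2.0, rel=1e-9)


class TestFoldChange:
    def test_simple_ratios(self):
        assert fold_change(3.2, 2.0) == pytest.approx(1.6)
        assert fold_change(5.0, 5.0) == pytest.approx(1.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            fold_change(1.0, 0.0)

    def test_net_mesoderm_fold_from_printed_values(self):
        # half-maximal mesoderm reduction ~3.5-fold versus ectoderm
        # ~1.5-fold leaves a net ~2-fold difference
        net = fold_change(3.5, 1.5)
        assert net == pytest.approx(7 / 3, rel=1e-9)
        assert 2.0 <= net <= 2.5


class TestBasalProjection:
    def test_normalized_mean_is_one(self):
        rng = np.random.default_rng(0)
        stack = ImageStack(data=rng.uniform(0.5, 2.0, size=(9, 20, 20)),
                           pixel_size=0.25, dz=1.0)
        ar = np.zeros((20, 20), bool)
        ar[:, :10] = True
        proj = basal_projection(stack, {"AR": (ar, 4.0), "NR": (~ar, 4.0)})
        combined = np.ones((20, 20), bool)
        assert proj[combined].mean() == pytest.approx(1.0)

    def test_stack_of_ones_projects_to_ones(self):
        stack = ImageStack(data=np.ones((7, 10, 10)), pixel_size=0.25,
                           dz=1.0)
        mask = np.ones((10, 10), bool)
        proj = basal_projection(stack, {"all": (mask, 3.0)}, window=5)
        assert np.allclose(proj, 1.0)


class TestApicalLevels:
    def test_identical_cells_all_one(self, cylinder_tissue):
        lab2d = cylinder_tissue.labels[0].max(axis=0)
        z = np.arange(cylinder_tissue.config.n_slices, dtype=float)
        prof = _gauss(z, 2.0, 3.0)
        data = prof[:, None, None] * (cylinder_tissue.labels[0] > 0)
        stack = ImageStack(data=data, pixel_size=0.2, dz=1.0)
        levels = apical_levels(stack, lab2d)
        assert np.allclose(levels.to_numpy(), 1.0)

    def test_two_to_one_cells_normalize_to_thirds(self):
        program = synthgen.ShapeProgram.columnar(36.0, 10.0)
        tissue = synthgen.make_tissue(synthgen.TissueConfig(
            shape_program=program, grid_shape=(1, 2), cell_footprint=6.0,
            n_slices=12, dz=1.0, pixel_size=0.25, seed=0))
        z = np.arange(12.0)
        prof = _gauss(z, 2.0, 3.0)
        vol = np.zeros(tissue.labels[0].shape)
        for cid, amp in ((1, 2.0), (2, 1.0)):
            vol += amp * prof[:, None, None] * (tissue.labels[0] == cid)
        stack = ImageStack(data=vol, pixel_size=0.25, dz=1.0)
        levels = apical_levels(stack, tissue.labels[0].max(axis=0))
        assert levels[1] == pytest.approx(4 / 3, rel=1e-6)
        assert levels[2] == pytest.approx(2 / 3, rel=1e-6)


class TestFitTimecourse:
    def test_exact_quadratic_r2_one(self):
        t = np.arange(8.0)
        y = 1.5 * t**2 - 2 * t + 3
        fit = fit_timecourse(t, y, degree=2)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_data_r2_zero_convention(self):
        fit = fit_timecourse(np.arange(5.0), np.full(5, 2.0), degree=1)
        assert fit.r_squared == 0.0

    def test_exponential_decay_cubic_fit_r2(self):
        # noiseless 5-fold exponential decay sampled 10x, cubic fit
        t = np.linspace(0, 1, 10)
        y = np.exp(-np.log(5) * t)
        fit = fit_timecourse(t, y, degree=3)
        assert fit.r_squared >= 0.95

    def test_degenerate_times_rejected(self):
        with pytest.raises(ValueError):
            fit_timecourse(np.zeros(5), np.arange(5.0), degree=1)


class TestFoldRecoveryProperty:
    @pytest.mark.parametrize("fold", [1.6, 2.0, 3.5, 5.0])
    def test_median_recovered_fold_within_10pct(self, fold, half_masks):
        program = synthgen.ShapeProgram.columnar(25.0, 14.0, n_frames=2)
        tissue = synthgen.make_tissue(synthgen.TissueConfig(
            shape_program=program, grid_shape=(4, 4), cell_footprint=5.0,
            n_slices=20, dz=1.0, pixel_size=0.4, times=[0.0, 300.0], seed=1))
        ar, nr = half_masks(tissue.labels[0].shape[1:])
        recovered = []
        for seed in range(8):
            mcfg = synthgen.MyosinConfig(
                basal_amplitude={
                    "AR": synthgen.decay_fold(fold, 300.0),
                    "NR": lambda t: 1.0},
                region_masks={"AR": ar, "NR": nr},
                basal_fwhm=3.0, background=0.1, noise_sd=0.1, seed=seed)
            stacks = synthgen.make_myosin(tissue, mcfg)
            levels = {}
            for name, mask in (("AR", ar), ("NR", nr)):
                vals = []
                for st in stacks:
                    pk = zprofile(st, mask)
                    vals.append(basal_level(st, mask, pk.peak_z,
                                            background=pk.offset).level)
                levels[name] = vals
            rel = (levels["AR"][0] / levels["AR"][1]) \
                / (levels["NR"][0] / levels["NR"][1])
            recovered.append(rel)
        assert np.median(recovered) == pytest.approx(fold, rel=0.10)
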