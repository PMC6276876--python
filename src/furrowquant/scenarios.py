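"""Benchmark scenarios reproducing the study's headline quantities.

Each function builds a synthetic dataset with the generator defaults that
match the study conditions, runs the corresponding quantification pipeline
end-to-end, and returns ``(value, n)`` where ``n`` is the problem size the
estimate rests on.  The scenarios are deterministic given their seed and are
shared by the acceptance script and the acceptance test suite.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import myoquant, pulses, ringkin, shapefeat, synthgen

__all__ = [
    "ring_speed_ratio", "compaction_density_ratio", "basal_fold_change",
    "z_spread_estimate", "pulse_period_recovery", "non_ratchet_extent",
    "constriction_classification", "mean_cell_length", "cylinder_ab_ratio",
    "wedge_basal_area",
]


def ring_speed_ratio(seed: int = 1) -> tuple[float, int]:
    """Constriction-speed ratio of activated vs control ring fields.

    Two fields of 48 rings (radius 3 μm, 0.2 μm pixels, 5 frames, noise SD
    10% of the ring amplitude) constrict at 4.8% and 1.0% of the initial
    diameter per frame.  Rings are detected per frame, diameters normalized
    to the frame-0 mean, a line fitted per field, and the slope ratio
    returned.
    """
    slopes = {}
    for name, slope, sub in (("AR", -0.048, 0), ("NR", -0.010, 1)):
        field = synthgen.make_ring_field(synthgen.RingFieldConfig(
            n_rings=48, radius0=3.0, slope=slope, n_frames=5,
            pixel_size=0.2, noise_sd=0.1, seed=seed * 10 + sub))
        diam = {
            f: 2.0 * ringkin.detect_rings(img, 1.5, 4.5)["r"].to_numpy()
            for f, img in enumerate(field.images)
        }
        slopes[name] = ringkin.constriction_speed(diam).slope_per_frame
    return slopes["AR"] / slopes["NR"], 2 * 48 * 5


def compaction_density_ratio(seed: int = 1, factor: float = 1.35,
                             n_replicates: int = 3) -> tuple[float, int]:
    """Ring-density ratio between a compacted and an uncompacted region.

    400 rings per replicate field on a jittered grid; coordinates inside a
    central disk are contracted isotropically so the areal density rises by
    ``factor``.  Rings are detected at 10% noise and densities pooled over
    replicates (the study pooled three embryos), measured inside the disk
    versus outside the transition annulus, both within the seeded area.
    """
    base = synthgen.RingFieldConfig(
        n_rings=400, radius0=3.0, slope=0.0, n_frames=1, pixel_size=0.2,
        spacing=10.2, jitter_sd=0.4, noise_sd=0.1, seed=0)
    (h_um, w_um), _ = synthgen.ring_field_geometry(base)
    region = (w_um / 2.0, h_um / 2.0, 0.22 * min(h_um, w_um))
    count_in = count_out = 0.0
    area_in = area_out = 0.0
    n_rings = 0
    for rep in range(n_replicates):
        field = synthgen.make_ring_field(dataclasses.replace(
            base, seed=seed * 100 + rep,
            compaction_region=region, compaction_factor=factor))
        det = ringkin.detect_rings(field.images[0], 1.5, 4.5)
        n_rings += len(det)
        h, w = field.images[0].shape[1:]
        yy, xx = np.mgrid[0:h, 0:w]
        px = base.pixel_size
        rho = np.hypot(xx * px - region[0], yy * px - region[1])
        inside = rho <= region[2]
        x0, y0, x1, y1 = field.seeded_box
        r_out = 1.3 * region[2] * np.sqrt(factor) + 2 * base.radius0
        outside = (rho > r_out) & (xx * px >= x0) & (xx * px <= x1) \
            & (yy * px >= y0) & (yy * px <= y1)
        count_in += ringkin.ring_density(det, inside, px) * inside.sum()
        count_out += ringkin.ring_density(det, outside, px) * outside.sum()
        area_in += inside.sum()
        area_out += outside.sum()
    ratio = (count_in / area_in) / (count_out / area_out)
    return ratio, n_rings


def _columnar_tissue(seed: int, times, n_slices=36, pixel_size=0.25):
    program = synthgen.ShapeProgram.columnar(
        area=36.0, length=30.0, n_frames=len(times))
    return synthgen.make_tissue(synthgen.TissueConfig(
        shape_program=program, grid_shape=(6, 6), cell_footprint=6.0,
        n_slices=n_slices, dz=1.0, pixel_size=pixel_size,
        times=list(times), seed=seed))


def basal_fold_change(seed: int = 1) -> tuple[float, int]:
    """Activated/control basal myosin fold at 6 minutes.

    Paired regions of one tissue imaged every 95 s with a final acquisition
    at 6 min (dz 1 μm, basal layer FWHM 3 μm, 10% noise).  The control
    amplitude is constant; the activated one saturates at 1.6x its initial
    value at 6 min.  Levels come from the full pipeline (4x4 subregion
    z-profile, Gaussian peak fit, 5-slice window, fitted-offset background)
    and the fold is the ratio of the two regions' levels at 6 min, each
    normalized to its initial level.
    """
    times = [0.0, 95.0, 190.0, 285.0, 360.0]
    tissue = _columnar_tissue(seed * 10 + 2, times)
    h, w = tissue.labels[0].shape[1:]
    ar = np.zeros((h, w), bool)
    ar[:, : w // 2] = True
    nr = ~ar
    mcfg = synthgen.MyosinConfig(
        basal_amplitude={"AR": synthgen.saturating_rise(1.6, 360.0),
                         "NR": lambda t: 1.0},
        region_masks={"AR": ar, "NR": nr},
        basal_fwhm=3.0, background=0.1, noise_sd=0.1, seed=seed * 10 + 3)
    stacks = synthgen.make_myosin(tissue, mcfg)
    levels: dict[str, list[float]] = {"AR": [], "NR": []}
    for stack in stacks:
        for name, mask in (("AR", ar), ("NR", nr)):
            peak = myoquant.zprofile(stack, mask)
            lev = myoquant.basal_level(stack, mask, peak.peak_z,
                                       background=peak.offset)
            levels[name].append(lev.level)
    fold = myoquant.fold_change(
        levels["AR"][-1] / levels["AR"][0],
        levels["NR"][-1] / levels["NR"][0])
    return fold, len(times)


def z_spread_estimate(seed: int = 1) -> tuple[float, int]:
    """Estimated axial FWHM of a basal layer generated at 3.4 μm.

    One activated stack (dz 1 μm, 5% noise, constant offset); the pipeline's
    Gaussian z-profile fit reports the z-spread, which stays below the 4 μm
    bound when the true extent is sub-threshold.
    """
    tissue = _columnar_tissue(seed * 10 + 4, [0.0])
    h, w = tissue.labels[0].shape[1:]
    mask = np.ones((h, w), bool)
    mcfg = synthgen.MyosinConfig(
        basal_amplitude={"AR": lambda t: 1.0}, region_masks={"AR": mask},
        basal_fwhm=3.4, background=0.1, noise_sd=0.05, seed=seed * 10 + 5)
    stack = synthgen.make_myosin(tissue, mcfg)[0]
    peak = myoquant.zprofile(stack, mask)
    return peak.fwhm, stack.n_slices


def _pulse_cohort(seed: int, **overrides):
    defaults = dict(
        n_traces=100, class_mix={"non_ratchet": 1.0, "ratchet": 0.0},
        baseline_area=40.0, period=90.0, period_jitter_sd=5.0,
        pulse_amplitude=5.0, sampling_interval=35.0, duration=900.0,
        noise_sd=0.5, seed=seed)
    defaults.update(overrides)
    cfg = synthgen.PulseConfig(**defaults)
    ps = synthgen.make_pulse_traces(cfg)
    per_trace, summary = pulses.cohort_summary(
        ps.traces, min_prominence=2.0 * cfg.noise_sd)
    return ps, per_trace, summary


def pulse_period_recovery(seed: int = 1) -> tuple[float, int]:
    """Cohort mean pulsation period on traces with true spacing N(90, 5) s.

    100 traces sampled every 35 s for 15 min, pulse amplitude 5 μm², noise
    SD 0.5 μm²; peaks detected by local maxima and inter-peak intervals
    pooled over traces.
    """
    _, _, summary = _pulse_cohort(seed * 10 + 6)
    return summary["period_pooled"], summary["n_pulses"]


def non_ratchet_extent(seed: int = 1) -> tuple[float, int]:
    """Cohort mean between-peak area difference of non-ratchet traces.

    Traces oscillate about a constant 40 μm² baseline, so the mean change in
    area between consecutive detected peaks converges to zero.
    """
    _, _, summary = _pulse_cohort(seed * 10 + 7)
    return summary["ratchet_extent_pooled"], summary["n_pulses"]


def constriction_classification(seed: int = 1) -> tuple[float, int]:
    """Fraction of non-constricting cells in an 85/15 mixture of 407 traces.

    Non-ratchet traces return to baseline (never below half the initial
    area); ratchet traces stair-step downward and end well below half, so
    the half-initial-area rule recovers the mixture fraction.
    """
    _, per_trace, summary = _pulse_cohort(
        seed * 10 + 8, n_traces=407,
        class_mix={"non_ratchet": 0.85, "ratchet": 0.15},
        ratchet_lockin=6.0)
    return summary["fraction_non_constricting"], len(per_trace)


def mean_cell_length(seed: int = 1) -> tuple[float, int]:
    """Mean apico-basal length of 16 columnar cells occupying 26 slices."""
    program = synthgen.ShapeProgram.columnar(area=36.0, length=26.0)
    tissue = synthgen.make_tissue(synthgen.TissueConfig(
        shape_program=program, grid_shape=(4, 4), cell_footprint=7.0,
        n_slices=30, dz=1.0, pixel_size=0.2, seed=seed))
    shapes = shapefeat.reconstruct(tissue.labels[0], 0.2, 1.0)
    return float(np.mean([s.length for s in shapes])), len(shapes)


def cylinder_ab_ratio(seed: int = 1) -> tuple[float, int]:
    """A/B ratio of columnar cells (equal area in every slice)."""
    program = synthgen.ShapeProgram.columnar(area=36.0, length=26.0)
    tissue = synthgen.make_tissue(synthgen.TissueConfig(
        shape_program=program, grid_shape=(4, 4), cell_footprint=7.0,
        n_slices=30, dz=1.0, pixel_size=0.2, seed=seed))
    shapes = shapefeat.reconstruct(tissue.labels[0], 0.2, 1.0)
    ratios = [shapefeat.ab_ratio(s) for s in shapes]
    return float(np.mean(ratios)), len(shapes)


def wedge_basal_area(seed: int = 1) -> tuple[float, int]:
    """Mean basal-area feature of wedge cells rendered with a 60 μm² base.

    Wedges run linearly from a 30 μm² apex to a 60 μm² base over 26 slices
    at 0.2 μm pixels; the reported feature is the default 3-slice basal-cap
    mean of the reconstruction.
    """
    program = synthgen.ShapeProgram.wedging(
        30.0, 30.0, 60.0, 60.0, 26.0, 26.0, 1)
    tissue = synthgen.make_tissue(synthgen.TissueConfig(
        shape_program=program, grid_shape=(4, 4), cell_footprint=9.0,
        n_slices=30, dz=1.0, pixel_size=0.2, seed=seed))
    shapes = shapefeat.reconstruct(tissue.labels[0], 0.2, 1.0)
    return float(np.mean([s.basal_area(3) for s in shapes])), len(shapes)
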