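"""End-to-end orchestration: simulate → segment → quantify → statistics.

Stages run in dependency order; every output CSV carries the configuration
hash and seed as ``#`` header lines, so a rerun with the same configuration
reproduces byte-identical tables.  A stage failure raises ``StageError``
naming the stage; tables written by earlier stages are left on disk.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import myoquant, pulses, ringkin, segtrack, shapefeat, stats, synthgen
from .config import PipelineConfig
from .io import write_labels, write_stack, write_table

__all__ = ["StageError", "run_pipeline"]

log = logging.getLogger("furrowquant")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _default_tissue(cfg: PipelineConfig) -> synthgen.TissueConfig:
    block = dict(cfg.tissue)
    n_frames = int(block.pop("n_frames", 4))
    grid = tuple(block.pop("grid_shape", (6, 6)))
    program = synthgen.ShapeProgram.elongating(
        area0=block.pop("cell_area", 36.0),
        length0=block.pop("length0", 10.0),
        length1=block.pop("length1", 14.0),
        n_frames=n_frames,
    )
    return synthgen.TissueConfig(
        shape_program=program,
        grid_shape=grid,
        cell_footprint=block.pop("cell_footprint", 6.0),
        n_slices=int(block.pop("n_slices", 16)),
        dz=cfg.dz,
        pixel_size=cfg.pixel_size,
        noise_sd=block.pop("noise_sd", 0.02),
        frame_interval=cfg.frame_interval,
        seed=cfg.seed,
        **block,
    )


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict[str, Path]:
    """Run the full synthetic pipeline; returns paths of emitted tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config": cfg.digest(), "seed": cfg.seed}
    outputs: dict[str, Path] = {}
    rng_seed = cfg.seed

    # ---- simulate -------------------------------------------------------
    stage = "simulate"
    try:
        tcfg = _default_tissue(cfg)
        tissue = synthgen.make_tissue(tcfg)
        h, w = tissue.labels[0].shape[1:]
        ar_mask = np.zeros((h, w), bool)
        ar_mask[:, : w // 2] = True
        nr_mask = ~ar_mask
        mcfg = synthgen.MyosinConfig(
            basal_amplitude={
                "AR": synthgen.saturating_rise(
                    cfg.myosin.get("ar_fold", 1.6),
                    tcfg.frame_times[-1] or 1.0),
                "NR": lambda t: 1.0,
            },
            region_masks={"AR": ar_mask, "NR": nr_mask},
            basal_fwhm=cfg.myosin.get("basal_fwhm", 3.0),
            noise_sd=cfg.myosin.get("noise_sd", 0.02),
            seed=rng_seed + 1,
        )
        myosin_stacks = synthgen.make_myosin(tissue, mcfg)
        rings = synthgen.make_ring_field(synthgen.RingFieldConfig(
            n_rings=int(cfg.rings.get("n_rings", 25)),
            slope=cfg.rings.get("slope", -0.02),
            noise_sd=cfg.rings.get("noise_sd", 0.05),
            pixel_size=cfg.pixel_size,
            seed=rng_seed + 2,
        ))
        pulse_set = synthgen.make_pulse_traces(synthgen.PulseConfig(
            n_traces=int(cfg.pulses.get("n_traces", 40)),
            class_mix=cfg.pulses.get(
                "class_mix", {"non_ratchet": 0.5, "ratchet": 0.5}),
            seed=rng_seed + 3,
        ))
        for f, stack in enumerate(tissue.membrane):
            write_stack(stack, outdir / f"sim_t{f:03d}_membrane.tif")
            write_stack(myosin_stacks[f], outdir / f"sim_t{f:03d}_myosin.tif")
            write_labels(tissue.labels[f], outdir / f"sim_t{f:03d}_labels.tif")
        outputs["truth"] = write_table(tissue.truth, outdir / "truth.csv",
                                       meta)
        outputs["pulse_traces"] = write_table(
            pulse_set.traces, outdir / "pulse_traces.csv", meta)
        log.info("simulated %d frames", tissue.n_frames)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, exc) from exc

    # ---- segment --------------------------------------------------------
    stage = "segment"
    try:
        params = segtrack.SegParams(**cfg.segmentation)
        seg_volumes = []
        for stack in tissue.membrane:
            n_occ = int((tissue.labels[0].max(axis=(1, 2)) > 0).sum())
            seg = np.zeros_like(tissue.labels[0])
            for iz in range(n_occ):
                filt = segtrack.bandpass(stack.data[iz], cfg.pixel_size,
                                         params)
                seg[iz] = segtrack.segment_slice(filt, cfg.pixel_size,
                                                 params)
            seg_volumes.append(segtrack.track_z(seg, params))
        rows = []
        for f, vol in enumerate(seg_volumes):
            for iz in range(vol.shape[0]):
                from skimage.measure import regionprops

                for region in regionprops(vol[iz]):
                    cy, cx = region.centroid
                    rows.append({
                        "cell_id": region.label, "frame": f, "z": iz,
                        "centroid_x": cx * cfg.pixel_size,
                        "centroid_y": cy * cfg.pixel_size,
                        "area": region.area * cfg.pixel_size ** 2,
                    })
        outputs["tracks"] = write_table(
            pd.DataFrame(rows), outdir / "tracks.csv", meta)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- shapes ---------------------------------------------------------
    stage = "shapes"
    try:
        frames = []
        for f, vol in enumerate(seg_volumes):
            shapes = shapefeat.reconstruct(vol, cfg.pixel_size, cfg.dz)
            tab = shapefeat.features_table(shapes)
            tab.insert(1, "frame", f)
            frames.append(tab)
        features = pd.concat(frames, ignore_index=True)
        outputs["features"] = write_table(
            features, outdir / "features.csv", meta)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- myosin ---------------------------------------------------------
    stage = "myosin"
    try:
        rows = []
        for stack in myosin_stacks:
            for name, mask in (("AR", ar_mask), ("NR", nr_mask)):
                peak = myoquant.zprofile(stack, mask)
                level = myoquant.basal_level(stack, mask, peak.peak_z)
                rows.append({
                    "region": name, "t": stack.t, "level": level.level,
                    "peak_z": peak.peak_z, "fwhm": peak.fwhm,
                })
        levels = pd.DataFrame(rows)
        piv = levels.pivot(index="t", columns="region", values="level")
        rel = (piv["AR"] / piv["AR"].iloc[0]) / (piv["NR"] / piv["NR"].iloc[0])
        fit = myoquant.fit_timecourse(piv.index.to_numpy(), rel.to_numpy(),
                                      degree=2)
        levels["fold_ar_nr"] = levels["t"].map(dict(zip(piv.index, rel)))
        outputs["myosin_levels"] = write_table(
            levels, outdir / "myosin_levels.csv",
            {**meta, "fold_fit_r2": round(fit.r_squared, 4)})
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- rings ----------------------------------------------------------
    stage = "rings"
    try:
        r0 = rings.config.radius0
        detections = [
            ringkin.detect_rings(img, 0.6 * r0, 1.4 * r0)
            for img in rings.images
        ]
        fit = ringkin.constriction_speed(
            {f: 2 * det["r"].to_numpy() for f, det in enumerate(detections)
             if len(det)})
        det_all = pd.concat(
            [det.assign(frame=f) for f, det in enumerate(detections)],
            ignore_index=True)
        outputs["ring_detections"] = write_table(
            det_all, outdir / "ring_detections.csv",
            {**meta, "slope_per_frame": round(fit.slope_per_frame, 5)})
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- pulses + stats -------------------------------------------------
    stage = "pulses"
    try:
        prominence = 2.0 * cfg.pulses.get("noise_sd", 0.5)
        per_trace, summary = pulses.cohort_summary(
            pulse_set.traces, min_prominence=prominence)
        merged = per_trace.merge(
            pulse_set.labels.rename(columns={"class": "true_class"}),
            on="trace_id")
        outputs["pulse_stats"] = write_table(
            merged, outdir / "pulse_stats.csv", {**meta, **{
                k: v for k, v in summary.items() if v is not None}})
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "stats"
    try:
        groups = {
            name: grp["ratchet_extent"].dropna().to_numpy()
            for name, grp in merged.groupby("class")
        }
        report_rows = []
        names = [n for n, g in groups.items() if len(g) >= 2]
        if len(names) >= 2:
            res = stats.ttest2(groups[names[0]], groups[names[1]])
            eff = stats.cohens_d(groups[names[0]], groups[names[1]])
            report_rows.append({
                "comparison": f"{names[0]} vs {names[1]}",
                "method": res.method, "statistic": res.statistic,
                "p_value": res.p_value, "cohens_d": eff.d,
            })
        outputs["stats_report"] = write_table(
            pd.DataFrame(report_rows), outdir / "stats_report.csv", meta)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    return outputs
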