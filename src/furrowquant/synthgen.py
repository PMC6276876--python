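"""Synthetic embryo generator with known ground truth.

Emulates the statistical structure the quantification pipeline assumes for
gastrulating *Drosophila* epithelia:

* a flat sheet of columnar-to-wedge cells on a rectangular grid, rendered as
  generalized frusta (cross-section area interpolated linearly from apical to
  basal) into label volumes and a membrane channel (label borders convolved
  with a Gaussian PSF plus additive noise);
* a basal myosin-II layer whose axial profile is Gaussian with configurable
  FWHM and whose amplitude follows per-region time-courses (exponential decay
  by a fold, or saturating recruitment toward a fold);
* fields of contractile actomyosin rings with linear diameter change per
  frame and optional lateral tissue compaction;
* apical-area pulse traces in ratchet / non-ratchet variants.

Everything is deterministic given the configured seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.segmentation import find_boundaries

from .io import ImageStack

__all__ = [
    "ShapeProgram",
    "TissueConfig",
    "MyosinConfig",
    "RingFieldConfig",
    "PulseConfig",
    "Tissue",
    "RingField",
    "PulseSet",
    "make_tissue",
    "make_myosin",
    "make_ring_field",
    "make_pulse_traces",
    "decay_fold",
    "saturating_rise",
]


# --------------------------------------------------------------------------
# cell-shape programs
# --------------------------------------------------------------------------

@dataclass
class ShapeProgram:
    """Per-frame (apical area, basal area, length) course shared by all cells.

    Units: areas in μm², lengths in μm.  With ``constant_volume`` set the
    areas of every frame are rescaled so the discrete per-cell volume equals
    that of the first frame (time-CV < 0.1% by construction).
    """

    apical_area: np.ndarray
    basal_area: np.ndarray
    length: np.ndarray
    constant_volume: bool = False

    def __post_init__(self) -> None:
        self.apical_area = np.atleast_1d(np.asarray(self.apical_area, float))
        self.basal_area = np.atleast_1d(np.asarray(self.basal_area, float))
        self.length = np.atleast_1d(np.asarray(self.length, float))
        n = len(self.length)
        if not (len(self.apical_area) == len(self.basal_area) == n):
            raise ValueError("shape-program arrays must have equal length")
        if np.any(self.apical_area <= 0) or np.any(self.basal_area <= 0):
            raise ValueError("areas must be positive")
        if np.any(self.length <= 0):
            raise ValueError("lengths must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.length)

    @classmethod
    def columnar(
        cls, area: float, length: float, n_frames: int = 1
    ) -> "ShapeProgram":
        """Cylinders: equal apical and basal cross-section at every frame."""
        ones = np.ones(n_frames)
        return cls(area * ones, area * ones, length * ones)

    @classmethod
    def elongating(
        cls,
        area0: float,
        length0: float,
        length1: float,
        n_frames: int,
        constant_volume: bool = True,
    ) -> "ShapeProgram":
        """Columnar cells lengthening from ``length0`` to ``length1``."""
        length = np.linspace(length0, length1, n_frames)
        area = area0 * np.ones(n_frames)
        return cls(area, area, length, constant_volume=constant_volume)

    @classmethod
    def wedging(
        cls,
        apical0: float,
        apical1: float,
        basal0: float,
        basal1: float,
        length0: float,
        length1: float,
        n_frames: int,
        constant_volume: bool = False,
    ) -> "ShapeProgram":
        return cls(
            np.linspace(apical0, apical1, n_frames),
            np.linspace(basal0, basal1, n_frames),
            np.linspace(length0, length1, n_frames),
            constant_volume=constant_volume,
        )


# --------------------------------------------------------------------------
# tissue
# --------------------------------------------------------------------------

@dataclass
class TissueConfig:
    """Geometry and imaging parameters of a synthetic epithelial sheet."""

    shape_program: ShapeProgram
    grid_shape: tuple[int, int] = (8, 8)  # cells in (ny, nx)
    cell_footprint: float = 6.0           # μm, grid pitch per cell
    n_slices: int = 30
    dz: float = 1.0                        # μm
    pixel_size: float = 0.2                # μm
    membrane_width: float = 0.3            # μm (pre-PSF border thickness)
    psf_sigma: float = 0.25                # μm, lateral Gaussian PSF
    noise_sd: float = 0.0                  # relative to membrane amplitude 1
    frame_interval: float = 30.0           # s
    times: Sequence[float] | None = None   # explicit frame times (s)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cell_footprint", "dz", "pixel_size", "membrane_width",
                     "psf_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_slices < 2:
            raise ValueError("n_slices must be at least 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.cell_footprint / self.pixel_size < 2:
            raise ValueError(
                "cell_footprint smaller than 2 pixels; increase footprint "
                "or decrease pixel_size"
            )
        if self.times is not None:
            times = np.asarray(self.times, float)
            if len(times) != self.shape_program.n_frames:
                raise ValueError("times must match shape-program frames")
            self.times = times

    @property
    def frame_times(self) -> np.ndarray:
        if self.times is not None:
            return np.asarray(self.times, float)
        return np.arange(self.shape_program.n_frames) * self.frame_interval


@dataclass
class Tissue:
    """Generated tissue: membrane series, truth labels, truth feature table."""

    config: TissueConfig
    membrane: list[ImageStack]
    labels: list[np.ndarray]          # per frame, (z, y, x) int
    truth: pd.DataFrame               # cell_id, t, areas, length, volume

    @property
    def n_frames(self) -> int:
        return len(self.labels)


def _slice_areas(program: ShapeProgram, frame: int, dz: float,
                 n_slices: int) -> np.ndarray:
    """Per-slice cross-section areas (μm²) of one frame's frustum."""
    n_occ = int(round(program.length[frame] / dz))
    n_occ = max(2, min(n_occ, n_slices))
    frac = np.arange(n_occ) / (n_occ - 1)
    return (program.apical_area[frame]
            + (program.basal_area[frame] - program.apical_area[frame]) * frac)


def _rescaled_slice_areas(cfg: TissueConfig) -> list[np.ndarray]:
    """Slice-area arrays per frame, volume-rescaled if requested."""
    prog = cfg.shape_program
    per_frame = [_slice_areas(prog, f, cfg.dz, cfg.n_slices)
                 for f in range(prog.n_frames)]
    if prog.constant_volume:
        volumes = np.array([a.sum() * cfg.dz for a in per_frame])
        per_frame = [a * (volumes[0] / v) for a, v in zip(per_frame, volumes)]
    return per_frame


def make_tissue(cfg: TissueConfig) -> Tissue:
    """Render the membrane channel, truth labels and truth feature table."""
    rng = np.random.default_rng(cfg.seed)
    ny, nx = cfg.grid_shape
    px = cfg.pixel_size
    fp_px = cfg.cell_footprint / px
    height = int(round(ny * fp_px))
    width = int(round(nx * fp_px))
    areas_per_frame = _rescaled_slice_areas(cfg)
    times = cfg.frame_times

    membrane: list[ImageStack] = []
    labels: list[np.ndarray] = []
    rows = []
    for f, slice_areas in enumerate(areas_per_frame):
        lab = np.zeros((cfg.n_slices, height, width), dtype=np.int32)
        n_occ = len(slice_areas)
        for gy in range(ny):
            for gx in range(nx):
                cid = gy * nx + gx + 1
                cx = (gx + 0.5) * fp_px
                cy = (gy + 0.5) * fp_px
                for iz, area in enumerate(slice_areas):
                    # round width and height separately so the rendered
                    # pixel count tracks the target area to < 1%
                    area_px = area / px**2
                    w_px = max(int(round(np.sqrt(area_px))), 1)
                    h_px = max(int(round(area_px / w_px)), 1)
                    x0 = max(int(round(cx - w_px / 2.0)), 0)
                    x1 = min(x0 + w_px, width)
                    y0 = max(int(round(cy - h_px / 2.0)), 0)
                    y1 = min(y0 + h_px, height)
                    lab[iz, y0:y1, x0:x1] = cid
        borders = np.zeros(lab.shape, dtype=float)
        for iz in range(n_occ):
            borders[iz] = find_boundaries(lab[iz], mode="thick").astype(float)
        sigma_px = cfg.psf_sigma / px
        img = np.empty_like(borders)
        for iz in range(cfg.n_slices):
            img[iz] = gaussian_filter(borders[iz], sigma_px)
        if cfg.noise_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
        membrane.append(ImageStack(
            data=img, pixel_size=px, dz=cfg.dz,
            frame_interval=cfg.frame_interval, channel="membrane",
            t=float(times[f]),
        ))
        labels.append(lab)
        volume = slice_areas.sum() * cfg.dz
        for cid in range(1, ny * nx + 1):
            rows.append({
                "cell_id": cid,
                "frame": f,
                "t": float(times[f]),
                "apical_area": slice_areas[0],
                "basal_area": slice_areas[-1],
                "length": n_occ * cfg.dz,
                "volume": volume,
            })
    truth = pd.DataFrame(rows)
    return Tissue(config=cfg, membrane=membrane, labels=labels, truth=truth)


# --------------------------------------------------------------------------
# myosin channel
# --------------------------------------------------------------------------

def decay_fold(fold: float, duration: float) -> Callable[[float], float]:
    """Exponential amplitude decay reaching ``1/fold`` at ``duration``.

    The mesodermal basal pool loses ~5-fold over internalization and the
    ectodermal one ~3-fold; both are modelled with this law.
    """
    if fold <= 0:
        raise ValueError("fold must be positive")
    rate = np.log(fold) / duration

    def amp(t: float) -> float:
        return float(np.exp(-rate * t))

    return amp


def saturating_rise(fold: float, duration: float,
                    tau: float | None = None) -> Callable[[float], float]:
    """Saturating recruitment reaching ``fold`` × initial at ``duration``.

    Mimics optogenetic recruitment that saturates (e.g. ~1.6-fold in 6 min):
    ``a(t) = 1 + (fold - 1) * (1 - exp(-t/tau)) / (1 - exp(-duration/tau))``.
    """
    if fold <= 0:
        raise ValueError("fold must be positive")
    tau = duration / 2.5 if tau is None else tau
    norm = 1.0 - np.exp(-duration / tau)

    def amp(t: float) -> float:
        return float(1.0 + (fold - 1.0) * (1.0 - np.exp(-t / tau)) / norm)

    return amp


@dataclass
class MyosinConfig:
    """Per-region basal amplitude courses plus axial geometry of the layer."""

    basal_amplitude: Mapping[str, Callable[[float], float]]
    region_masks: Mapping[str, np.ndarray]
    basal_fwhm: float = 3.0                 # μm
    apical_amplitude: Callable[[float], float] | None = None
    apical_center: float = 1.0              # μm below the apical surface
    background: float = 0.1
    noise_sd: float = 0.0
    base_amplitude: float = 1.0             # intensity scale of amp(t)=1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.basal_fwhm <= 0:
            raise ValueError("basal_fwhm must be positive")
        if self.background < 0 or self.noise_sd < 0:
            raise ValueError("background and noise_sd must be non-negative")
        if set(self.basal_amplitude) != set(self.region_masks):
            raise ValueError("amplitude courses and masks must share regions")


def make_myosin(tissue: Tissue, cfg: MyosinConfig) -> list[ImageStack]:
    """Render the myosin channel on a tissue's geometry.

    The basal layer sits at the basal-most occupied slice of each frame and
    is Gaussian along z with the configured FWHM; in-plane the amplitude is
    uniform within each region mask.
    """
    rng = np.random.default_rng(cfg.seed)
    tcfg = tissue.config
    sigma_z = cfg.basal_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    z = np.arange(tcfg.n_slices) * tcfg.dz
    stacks: list[ImageStack] = []
    for f in range(tissue.n_frames):
        lab = tissue.labels[f]
        footprint = lab.max(axis=0) > 0
        for name, mask in cfg.region_masks.items():
            if mask.shape != footprint.shape:
                raise ValueError(f"region {name!r} mask shape mismatch")
            if not np.any(mask & footprint):
                raise ValueError(f"region {name!r} covers no cell")
        n_occ = int(round(
            tissue.truth.loc[tissue.truth["frame"] == f, "length"].iloc[0]
            / tcfg.dz))
        z_basal = (n_occ - 1) * tcfg.dz
        t = float(tissue.membrane[f].t)
        vol = np.full(lab.shape, cfg.background, dtype=float)
        basal_profile = np.exp(-((z - z_basal) ** 2) / (2 * sigma_z ** 2))
        for name, mask in cfg.region_masks.items():
            amp = cfg.base_amplitude * cfg.basal_amplitude[name](t)
            vol += amp * basal_profile[:, None, None] * mask[None, :, :]
        if cfg.apical_amplitude is not None:
            apical_profile = np.exp(
                -((z - cfg.apical_center) ** 2) / (2 * sigma_z ** 2))
            amp = cfg.base_amplitude * cfg.apical_amplitude(t)
            vol += amp * apical_profile[:, None, None] * footprint[None]
        if cfg.noise_sd > 0:
            vol = vol + rng.normal(0.0, cfg.noise_sd, size=vol.shape)
        stacks.append(ImageStack(
            data=vol, pixel_size=tcfg.pixel_size, dz=tcfg.dz,
            frame_interval=tcfg.frame_interval, channel="myosin", t=t,
        ))
    return stacks


# --------------------------------------------------------------------------
# ring fields
# --------------------------------------------------------------------------

@dataclass
class RingFieldConfig:
    """Field of contractile rings with linear constriction and compaction."""

    n_rings: int = 50
    radius0: float = 3.0            # μm
    slope: float = -0.01            # fractional diameter change per frame
    n_frames: int = 5
    pixel_size: float = 0.2         # μm
    spacing: float | None = None    # grid pitch, μm (default 2.7 * radius0)
    jitter_sd: float = 0.3          # μm, center jitter
    radius_jitter_sd: float = 0.1   # μm, per-ring radius spread
    ring_width: float = 0.25        # μm, Gaussian profile sigma of the ring
    amplitude: float = 1.0
    background: float = 0.0
    noise_sd: float = 0.0           # absolute (amplitude = 1 scale)
    compaction_region: tuple[float, float, float] | None = None
    # (center_x, center_y, radius) in μm of the analyzed (activated) disk
    compaction_factor: float | Callable[[int], float] = 1.0
    # areal density increase applied inside the region (per frame if callable)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius0 <= 0:
            raise ValueError("radius0 must be positive")
        if self.n_rings < 0 or self.n_frames < 1:
            raise ValueError("n_rings and n_frames must be non-negative")
        if self.pixel_size <= 0 or self.ring_width <= 0:
            raise ValueError("pixel_size and ring_width must be positive")

    def factor_at(self, frame: int) -> float:
        if callable(self.compaction_factor):
            return float(self.compaction_factor(frame))
        return float(self.compaction_factor)


@dataclass
class RingField:
    config: RingFieldConfig
    images: list[ImageStack]        # one single-slice stack per frame
    truth: pd.DataFrame             # frame, ring_id, x, y, r, inside
    clipped: int                    # rings dropped for falling out of field
    seeded_box: tuple[float, float, float, float] = (0, 0, 0, 0)
    # (x0, y0, x1, y1) μm bounding box of the seeded grid; density
    # measurements should stay inside it (the border band holds no rings)

    @property
    def field_size(self) -> tuple[float, float]:
        _, h, w = self.images[0].shape
        return (h * self.config.pixel_size, w * self.config.pixel_size)


def ring_field_geometry(cfg: RingFieldConfig
                        ) -> tuple[tuple[float, float],
                                   tuple[float, float, float, float]]:
    """Field size (h, w) μm and seeded-grid box for a config, no rendering."""
    spacing = cfg.spacing if cfg.spacing is not None else 2.7 * cfg.radius0
    n_grid = int(np.ceil(np.sqrt(max(cfg.n_rings, 1))))
    margin = cfg.radius0 + 4 * cfg.ring_width + cfg.jitter_sd * 3
    size = n_grid * spacing + 2 * margin
    size_px = int(round(size / cfg.pixel_size)) * cfg.pixel_size
    box = (margin, margin, margin + n_grid * spacing,
           margin + n_grid * spacing)
    return (size_px, size_px), box


def _compaction_map(xy: np.ndarray, center: np.ndarray, region_r: float,
                    factor: float) -> np.ndarray:
    """Radial pull-in realizing an areal density increase ``factor``.

    Points within ``region_r * sqrt(factor)`` of the center are scaled by
    ``1/sqrt(factor)`` (ending inside the analyzed disk); a transition
    annulus up to ``1.3 * region_r * sqrt(factor)`` interpolates linearly to
    the identity so the map is continuous.
    """
    if factor == 1.0:
        return xy
    s = 1.0 / np.sqrt(factor)
    r_pull = region_r * np.sqrt(factor)      # source radius mapped into disk
    r_outer = 1.3 * r_pull
    d = xy - center
    rho = np.hypot(d[:, 0], d[:, 1])
    out = xy.copy()
    inner = rho <= r_pull
    out[inner] = center + s * d[inner]
    trans = (rho > r_pull) & (rho < r_outer)
    if np.any(trans):
        # map [r_pull, r_outer] onto [s * r_pull, r_outer]
        frac = (rho[trans] - r_pull) / (r_outer - r_pull)
        new_rho = s * r_pull + frac * (r_outer - s * r_pull)
        out[trans] = center + d[trans] * (new_rho / rho[trans])[:, None]
    return out


def make_ring_field(cfg: RingFieldConfig) -> RingField:
    """Render a time series of ring images plus a truth table."""
    rng = np.random.default_rng(cfg.seed)
    spacing = cfg.spacing if cfg.spacing is not None else 2.7 * cfg.radius0
    n_grid = int(np.ceil(np.sqrt(max(cfg.n_rings, 1))))
    margin = cfg.radius0 + 4 * cfg.ring_width + cfg.jitter_sd * 3
    size = n_grid * spacing + 2 * margin
    height = width = int(round(size / cfg.pixel_size))

    # base positions: jittered grid with a random phase (wrapped within the
    # seeded box) so the expected ring density is uniform and lattice
    # alignment with any analysis region averages out across seeds
    gx, gy = np.meshgrid(np.arange(n_grid), np.arange(n_grid))
    base = np.column_stack([
        (gx.ravel() + 0.5) * spacing,
        (gy.ravel() + 0.5) * spacing,
    ])[: cfg.n_rings]
    phase = rng.uniform(0.0, spacing, size=2)
    base = margin + (base + phase) % (n_grid * spacing)
    base = base + rng.normal(0.0, cfg.jitter_sd, size=base.shape)
    radii0 = cfg.radius0 + rng.normal(
        0.0, cfg.radius_jitter_sd, size=len(base))
    radii0 = np.clip(radii0, 0.3 * cfg.radius0, 2.0 * cfg.radius0)

    if cfg.compaction_region is not None:
        region_c = np.asarray(cfg.compaction_region[:2], float)
        region_r = float(cfg.compaction_region[2])
    else:
        region_c, region_r = None, 0.0

    images: list[ImageStack] = []
    rows = []
    clipped = 0
    yy, xx = np.mgrid[0:height, 0:width]
    for f in range(cfg.n_frames):
        scale = 1.0 + cfg.slope * f
        radii = radii0 * scale
        pos = base
        if region_c is not None:
            pos = _compaction_map(base, region_c, region_r, cfg.factor_at(f))
        img = np.full((height, width), cfg.background, dtype=float)
        for rid, ((x, y), r) in enumerate(zip(pos, radii)):
            if r <= 0:
                continue
            x_px, y_px = x / cfg.pixel_size, y / cfg.pixel_size
            r_px = r / cfg.pixel_size
            w_px = cfg.ring_width / cfg.pixel_size
            lo_x = int(max(np.floor(x_px - r_px - 4 * w_px), 0))
            hi_x = int(min(np.ceil(x_px + r_px + 4 * w_px) + 1, width))
            lo_y = int(max(np.floor(y_px - r_px - 4 * w_px), 0))
            hi_y = int(min(np.ceil(y_px + r_px + 4 * w_px) + 1, height))
            if lo_x >= hi_x or lo_y >= hi_y:
                clipped += 1
                continue
            if x_px - r_px < 0 or x_px + r_px >= width \
                    or y_px - r_px < 0 or y_px + r_px >= height:
                clipped += 1
            dist = np.hypot(xx[lo_y:hi_y, lo_x:hi_x] - x_px,
                            yy[lo_y:hi_y, lo_x:hi_x] - y_px)
            img[lo_y:hi_y, lo_x:hi_x] += cfg.amplitude * np.exp(
                -((dist - r_px) ** 2) / (2 * w_px ** 2))
            inside = bool(
                region_c is not None
                and np.hypot(x - region_c[0], y - region_c[1]) <= region_r)
            rows.append({
                "frame": f, "ring_id": rid, "x": x, "y": y,
                "r": r, "inside": inside,
            })
        if cfg.noise_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
        images.append(ImageStack(
            data=img[np.newaxis], pixel_size=cfg.pixel_size, dz=1.0,
            channel="myosin", t=float(f),
        ))
    if clipped:
        warnings.warn(f"{clipped} ring renderings were clipped at the field "
                      "border", stacklevel=2)
    truth = pd.DataFrame(
        rows, columns=["frame", "ring_id", "x", "y", "r", "inside"])
    box = (margin, margin, margin + n_grid * spacing,
           margin + n_grid * spacing)
    return RingField(config=cfg, images=images, truth=truth,
                     clipped=clipped, seeded_box=box)


# --------------------------------------------------------------------------
# pulse traces
# --------------------------------------------------------------------------

@dataclass
class PulseConfig:
    """Apical-area pulse traces in ratchet / non-ratchet variants.

    Non-ratchet traces return to the baseline area after each constriction
    pulse; ratchet traces lock in ``ratchet_lockin`` μm² of constriction per
    pulse, stair-stepping downward (clamped at ``min_area``).
    """

    n_traces: int = 100
    class_mix: Mapping[str, float] = field(
        default_factory=lambda: {"non_ratchet": 1.0, "ratchet": 0.0})
    baseline_area: float = 40.0     # μm²
    period: float = 90.0            # s
    period_jitter_sd: float = 5.0   # s
    pulse_amplitude: float = 5.0    # μm², depth of each constriction dip
    ratchet_lockin: float = 6.0     # μm² locked in per pulse (ratchet class)
    sampling_interval: float = 35.0  # s
    duration: float = 900.0         # s
    noise_sd: float = 0.5           # μm²
    min_area: float = 2.0           # μm², physical floor
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix fractions must sum to 1")
        if any(k not in ("ratchet", "non_ratchet") for k in self.class_mix):
            raise ValueError("classes must be 'ratchet' or 'non_ratchet'")
        if self.sampling_interval >= self.period:
            raise ValueError("sampling_interval must be below the period")
        if self.duration < 2 * self.period:
            raise ValueError(
                "duration must cover at least two periods to define one")
        if self.baseline_area <= 0 or self.pulse_amplitude < 0:
            raise ValueError("baseline_area must be positive")


@dataclass
class PulseSet:
    config: PulseConfig
    traces: pd.DataFrame        # trace_id, t, area
    labels: pd.DataFrame        # trace_id, class, lockin
    peaks: pd.DataFrame         # trace_id, t_peak, area_peak (truth)


def _trace_waveform(t: np.ndarray, peak_times: np.ndarray,
                    peak_areas: np.ndarray, amplitude: float,
                    floor: float) -> np.ndarray:
    """Piecewise waveform: linear ramp between peaks minus a sin² dip."""
    area = np.empty_like(t)
    idx = np.searchsorted(peak_times, t, side="right") - 1
    idx = np.clip(idx, 0, len(peak_times) - 2)
    t0 = peak_times[idx]
    t1 = peak_times[idx + 1]
    a0 = peak_areas[idx]
    a1 = peak_areas[idx + 1]
    frac = (t - t0) / (t1 - t0)
    area = a0 + (a1 - a0) * frac - amplitude * np.sin(np.pi * frac) ** 2
    return np.maximum(area, floor)


def make_pulse_traces(cfg: PulseConfig) -> PulseSet:
    """Generate pulse traces, class labels and per-trace truth peaks."""
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(0.0, cfg.duration + 1e-9, cfg.sampling_interval)
    classes = rng.choice(
        list(cfg.class_mix), size=cfg.n_traces,
        p=list(cfg.class_mix.values()))
    trace_rows, label_rows, peak_rows = [], [], []
    for tid in range(cfg.n_traces):
        is_ratchet = classes[tid] == "ratchet"
        lockin = cfg.ratchet_lockin if is_ratchet else 0.0
        # peak times spanning the trace; start at a random phase
        peaks = [float(rng.uniform(0.2, 0.8) * cfg.period)]
        while peaks[-1] < cfg.duration + cfg.period:
            gap = rng.normal(cfg.period, cfg.period_jitter_sd)
            peaks.append(peaks[-1] + max(gap, 2 * cfg.sampling_interval))
        # prepend a virtual pre-start peak so t=0 lies inside a segment
        first_gap = max(rng.normal(cfg.period, cfg.period_jitter_sd),
                        2 * cfg.sampling_interval)
        peak_times = np.array([peaks[0] - first_gap] + peaks)
        peak_areas = np.maximum(
            cfg.baseline_area - lockin * np.arange(len(peak_times)),
            cfg.min_area)
        area = _trace_waveform(t, peak_times, peak_areas,
                               cfg.pulse_amplitude, cfg.min_area)
        if cfg.noise_sd > 0:
            area = area + rng.normal(0.0, cfg.noise_sd, size=area.shape)
        for ti, ai in zip(t, area):
            trace_rows.append({"trace_id": tid, "t": ti, "area": ai})
        label_rows.append({"trace_id": tid, "class": classes[tid],
                           "lockin": lockin})
        visible = (peak_times >= 0) & (peak_times <= cfg.duration)
        for pt, pa in zip(peak_times[visible], peak_areas[visible]):
            peak_rows.append({"trace_id": tid, "t_peak": pt, "area_peak": pa})
    return PulseSet(
        config=cfg,
        traces=pd.DataFrame(trace_rows),
        labels=pd.DataFrame(label_rows),
        peaks=pd.DataFrame(peak_rows),
    )
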