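"""Actomyosin ring detection and constriction kinetics.

Rings are detected in basal myosin projections by a circular Hough
transform over a radius range, with non-maximum suppression and a sub-pixel
radial refinement of each detected radius.  Constriction speed is the slope
of a line fitted to ring diameters normalized to the mean of the first time
point; tissue compaction is scored as ring density (detections per unit
area) inside versus outside a region mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.feature import canny, peak_local_max
from skimage.transform import hough_circle

from .io import ImageStack

__all__ = ["ConstrictionFit", "detect_rings", "track_rings",
           "constriction_speed", "ring_density"]


@dataclass
class ConstrictionFit:
    """Linear fit of normalized ring diameters versus frame."""

    slope_per_frame: float      # fractional diameter change per frame
    slope_per_s: float | None   # per second, if a frame interval is known
    intercept: float
    r_squared: float
    normalized: pd.DataFrame    # frame, diameter_norm


def _refine_radius(image: np.ndarray, cx: float, cy: float, r_px: float,
                   halfwidth: float = 3.0) -> float:
    """Sub-pixel radius: intensity-weighted mean distance in an annulus."""
    h, w = image.shape
    lo_x = int(max(np.floor(cx - r_px - halfwidth - 1), 0))
    hi_x = int(min(np.ceil(cx + r_px + halfwidth + 2), w))
    lo_y = int(max(np.floor(cy - r_px - halfwidth - 1), 0))
    hi_y = int(min(np.ceil(cy + r_px + halfwidth + 2), h))
    yy, xx = np.mgrid[lo_y:hi_y, lo_x:hi_x]
    dist = np.hypot(xx - cx, yy - cy)
    sel = np.abs(dist - r_px) <= halfwidth
    if not np.any(sel):
        return r_px
    patch = image[lo_y:hi_y, lo_x:hi_x][sel]
    weights = patch - np.percentile(patch, 20)
    weights = np.clip(weights, 0, None)
    total = weights.sum()
    if total <= 0:
        return r_px
    return float(np.sum(weights * dist[sel]) / total)


def _angular_support(norm: np.ndarray, cx: float, cy: float, r_px: float,
                     n_angles: int = 72) -> float:
    """Fraction of perimeter samples lying on bright ridge pixels."""
    from scipy.ndimage import map_coordinates

    theta = np.linspace(0.0, 2 * np.pi, n_angles, endpoint=False)
    xs = cx + r_px * np.cos(theta)
    ys = cy + r_px * np.sin(theta)
    vals = map_coordinates(norm, [ys, xs], order=1, mode="constant")
    return float((vals > 0.5).mean())


def detect_rings(projection: ImageStack | np.ndarray,
                 rmin: float, rmax: float,
                 pixel_size: float | None = None,
                 threshold_rel: float = 0.6,
                 min_support: float = 0.8,
                 edge_mode: str = "ridge",
                 canny_sigma: float = 1.0,
                 refine: bool = True) -> pd.DataFrame:
    """Detect circles of radius ``rmin``..``rmax`` μm in one projection.

    Returns a DataFrame with columns (x, y, r, score), coordinates in μm,
    sorted by descending Hough score.  The Hough transform votes on bright
    ring pixels directly (``edge_mode="ridge"``: intensities above half the
    robust maximum), which avoids the double-contour artifact that gradient
    edges produce on annular profiles; ``edge_mode="canny"`` is available
    for filled or dark-ring images.  Non-maximum suppression removes
    candidates closer than ``rmin`` to an accepted center unless their radii
    differ by more than one pixel (so concentric rings survive).  A blank
    image yields an empty table.
    """
    if isinstance(projection, ImageStack):
        image = projection.data[0] if projection.data.ndim == 3 \
            else projection.data
        pixel_size = projection.pixel_size
    else:
        image = np.asarray(projection, float)
        if pixel_size is None:
            raise ValueError("pixel_size required for a bare array")
    if rmin >= rmax:
        raise ValueError("rmin must be below rmax")
    empty = pd.DataFrame(columns=["x", "y", "r", "score"])
    if np.ptp(image) == 0:
        return empty
    lo, hi = np.percentile(image, [20.0, 99.8])
    if hi <= lo:
        return empty
    norm = np.clip((image - lo) / (hi - lo), 0.0, None)
    if edge_mode == "ridge":
        edges = norm > 0.5
    elif edge_mode == "canny":
        edges = canny(np.clip(norm, 0, 1), sigma=canny_sigma)
    else:
        raise ValueError(f"unknown edge_mode {edge_mode!r}")
    if not edges.any():
        return empty
    rmin_px = max(int(np.floor(rmin / pixel_size)), 3)
    rmax_px = int(np.ceil(rmax / pixel_size))
    radii = np.arange(rmin_px, rmax_px + 1)
    accum = hough_circle(edges, radii)
    # candidate peaks per radius accumulator
    cands = []
    for ri, r_px in enumerate(radii):
        coords = peak_local_max(
            accum[ri], min_distance=rmin_px,
            threshold_abs=0.1, exclude_border=False)
        for cy, cx in coords:
            cands.append((float(accum[ri, cy, cx]), float(cx), float(cy),
                          float(r_px)))
    if not cands:
        return empty
    cands.sort(key=lambda c: -c[0])
    max_score = cands[0][0]
    cands = [c for c in cands if c[0] >= threshold_rel * max_score]
    # refine radii first: accumulator side-peaks of one ring collapse onto
    # the same refined radius and are then removed by the suppression rule,
    # while genuinely concentric rings keep distinct radii
    refined = []
    for score, cx, cy, r_px in cands:
        r_ref = _refine_radius(image, cx, cy, r_px) if refine else r_px
        # a genuine ring is bright along its whole perimeter; tangent arcs
        # threading between neighboring rings are not
        if _angular_support(norm, cx, cy, r_ref) < min_support:
            continue
        refined.append((score, cx, cy, r_ref))
    accepted: list[tuple[float, float, float, float]] = []
    for score, cx, cy, r_px in refined:
        clash = any(
            np.hypot(cx - ax, cy - ay) < rmin_px and abs(r_px - ar) <= 1.0
            for _, ax, ay, ar in accepted)
        if clash:
            continue
        accepted.append((score, cx, cy, r_px))
    rows = [{"x": cx * pixel_size, "y": cy * pixel_size,
             "r": r_px * pixel_size, "score": score}
            for score, cx, cy, r_px in accepted]
    return pd.DataFrame(rows, columns=["x", "y", "r", "score"])


def track_rings(frames: list[pd.DataFrame],
                max_displacement: float) -> pd.DataFrame:
    """Nearest-center matching of detections across consecutive frames.

    Returns a single table with columns (frame, track_id, x, y, r, score);
    detections without a match within ``max_displacement`` μm start new
    tracks.
    """
    rows = []
    next_id = 0
    prev: list[tuple[int, float, float]] = []  # (track_id, x, y)
    for fi, det in enumerate(frames):
        cur: list[tuple[int, float, float]] = []
        taken: set[int] = set()
        for rec in det.itertuples():
            best, best_d = None, np.inf
            for pi, (tid, px, py) in enumerate(prev):
                if pi in taken:
                    continue
                d = np.hypot(rec.x - px, rec.y - py)
                if d < best_d:
                    best, best_d = pi, d
            if best is not None and best_d <= max_displacement:
                tid = prev[best][0]
                taken.add(best)
            else:
                tid = next_id
                next_id += 1
            cur.append((tid, rec.x, rec.y))
            rows.append({"frame": fi, "track_id": tid, "x": rec.x,
                         "y": rec.y, "r": rec.r, "score": rec.score})
        prev = cur
    return pd.DataFrame(
        rows, columns=["frame", "track_id", "x", "y", "r", "score"])


def constriction_speed(diameters_by_frame: dict[int, np.ndarray] | list,
                       frame_interval: float | None = None
                       ) -> ConstrictionFit:
    """Fit a line to population diameters normalized to frame 0's mean.

    ``diameters_by_frame`` maps frame index to the diameters (any unit)
    pooled over rings at that frame; the normalization anchor is the mean of
    the initial frame.  The slope is signed: constriction is negative.
    """
    if isinstance(diameters_by_frame, (list, tuple)):
        diameters_by_frame = dict(enumerate(diameters_by_frame))
    frames = sorted(diameters_by_frame)
    if len(frames) < 2:
        raise ValueError("need at least two frames to fit a slope")
    anchor = np.mean(np.asarray(diameters_by_frame[frames[0]], float))
    if anchor <= 0:
        raise ValueError("initial-frame mean diameter must be positive")
    xs, ys = [], []
    rows = []
    for f in frames:
        d = np.asarray(diameters_by_frame[f], float) / anchor
        xs.append(np.full(len(d), f, dtype=float))
        ys.append(d)
        for v in d:
            rows.append({"frame": f, "diameter_norm": v})
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 0.0 if ss_tot == 0 else 1.0 - np.sum((y - pred) ** 2) / ss_tot
    return ConstrictionFit(
        slope_per_frame=float(slope),
        slope_per_s=float(slope / frame_interval) if frame_interval else None,
        intercept=float(intercept),
        r_squared=float(max(r2, 0.0)),
        normalized=pd.DataFrame(rows),
    )


def ring_density(detections: pd.DataFrame, region_mask: np.ndarray,
                 pixel_size: float) -> float:
    """Ring centers inside the mask per unit mask area (μm⁻²)."""
    mask = np.asarray(region_mask, bool)
    area = mask.sum() * pixel_size ** 2
    if area == 0:
        raise ValueError("zero-area region mask")
    if detections.empty:
        return 0.0
    xi = np.clip((detections["x"].to_numpy() / pixel_size).astype(int),
                 0, mask.shape[1] - 1)
    yi = np.clip((detections["y"].to_numpy() / pixel_size).astype(int),
                 0, mask.shape[0] - 1)
    count = int(mask[yi, xi].sum())
    return count / area
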