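"""Membrane segmentation and overlap-based cell tracking.

A minimal watershed-family segmenter exposing the parameters of the external
tool used in the source workflow: difference-of-Gaussians bandpass thresholds
of 2 and 10 μm, a 2 μm minimum cell size, and a 0.4 minimum spatial and/or
temporal fractional overlap for linking.  Manual vertex correction is out of
scope; externally supplied label volumes are accepted wherever labels are.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import h_minima
from skimage.segmentation import watershed

__all__ = ["SegParams", "bandpass", "segment_slice", "link",
           "track_z", "track_time"]


@dataclass
class SegParams:
    """Parameters of the segmentation / tracking stage (physical units)."""

    bandpass_low: float = 2.0    # μm, small-structure cut-off
    bandpass_high: float = 10.0  # μm, large-structure cut-off
    min_cell_size: float = 2.0   # μm, minimum equivalent diameter
    min_overlap: float = 0.4     # fractional overlap for linking
    h_rel: float = 0.1           # h-minima depth, relative to dynamic range

    def __post_init__(self) -> None:
        if not (0 < self.bandpass_low < self.bandpass_high):
            raise ValueError("need 0 < bandpass_low < bandpass_high")
        if not (0 < self.min_overlap <= 1):
            raise ValueError("min_overlap must be in (0, 1]")
        if self.min_cell_size <= 0:
            raise ValueError("min_cell_size must be positive")


def bandpass(image: np.ndarray, pixel_size: float,
             params: SegParams | None = None) -> np.ndarray:
    """Difference-of-Gaussians bandpass (zero mean on constant input).

    The two thresholds are feature scales in μm; the corresponding Gaussian
    sigmas are ``threshold / 2``.  Structures much smaller than the low or
    larger than the high threshold are suppressed.
    """
    params = params or SegParams()
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    sig_lo = params.bandpass_low / 2.0 / pixel_size
    sig_hi = params.bandpass_high / 2.0 / pixel_size
    if params.bandpass_low / pixel_size < 1:
        raise ValueError("bandpass_low is below one pixel; unresolvable")
    img = np.asarray(image, dtype=float)
    return (ndimage.gaussian_filter(img, sig_lo)
            - ndimage.gaussian_filter(img, sig_hi))


def segment_slice(filtered: np.ndarray, pixel_size: float,
                  params: SegParams | None = None) -> np.ndarray:
    """Watershed segmentation of a bandpassed membrane image.

    Cell interiors are basins of the membrane signal; markers come from
    h-minima with depth ``h_rel`` of the dynamic range.  Regions with an
    equivalent diameter below ``min_cell_size`` are discarded (label 0).
    """
    params = params or SegParams()
    img = np.asarray(filtered, dtype=float)
    if img.ndim != 2:
        raise ValueError("segment_slice expects a 2D image")
    rng_ptp = float(img.max() - img.min())
    if rng_ptp == 0.0:
        warnings.warn("flat image: no cells segmented", stacklevel=2)
        return np.zeros(img.shape, dtype=np.int32)
    minima = h_minima(img, params.h_rel * rng_ptp)
    markers = cc_label(minima)
    labels = watershed(img, markers).astype(np.int32)
    min_diam_px = params.min_cell_size / pixel_size
    for region in regionprops(labels):
        if region.equivalent_diameter_area < min_diam_px:
            labels[labels == region.label] = 0
    return labels


def _overlap_table(a: np.ndarray, b: np.ndarray) -> pd.DataFrame:
    """Pairwise pixel overlaps between two label images of the same shape."""
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    both = (a > 0) & (b > 0)
    if not np.any(both):
        return pd.DataFrame(columns=["a", "b", "inter", "size_a", "size_b"])
    key = a[both].astype(np.int64) * (b.max() + 1) + b[both]
    pairs, counts = np.unique(key, return_counts=True)
    la = pairs // (b.max() + 1)
    lb = pairs % (b.max() + 1)
    sizes_a = np.bincount(a)
    sizes_b = np.bincount(b)
    return pd.DataFrame({
        "a": la, "b": lb, "inter": counts,
        "size_a": sizes_a[la], "size_b": sizes_b[lb],
    })


def link(labels_a: np.ndarray, labels_b: np.ndarray,
         params: SegParams | None = None) -> dict[int, int]:
    """One-to-one correspondence between two label images.

    Regions i and j are linkable iff ``|i ∩ j| / min(|i|, |j|)`` reaches
    ``min_overlap``; assignment is greedy by descending overlap fraction,
    then larger intersection, then lower label ids.  The same rule is used
    across time and across z.
    """
    params = params or SegParams()
    if np.shape(labels_a) != np.shape(labels_b):
        raise ValueError("label images must share a shape")
    tab = _overlap_table(labels_a, labels_b)
    if tab.empty:
        return {}
    tab["frac"] = tab["inter"] / np.minimum(tab["size_a"], tab["size_b"])
    tab = tab[tab["frac"] >= params.min_overlap]
    tab = tab.sort_values(
        ["frac", "inter", "a", "b"], ascending=[False, False, True, True])
    used_a: set[int] = set()
    used_b: set[int] = set()
    mapping: dict[int, int] = {}
    for row in tab.itertuples():
        if row.a in used_a or row.b in used_b:
            continue
        mapping[int(row.a)] = int(row.b)
        used_a.add(row.a)
        used_b.add(row.b)
    return mapping


def track_z(label_slices: np.ndarray,
            params: SegParams | None = None) -> np.ndarray:
    """Link per-slice labels across z into consistent 3D cell ids.

    Track ids start from the apical-most non-empty slice and are propagated
    basally; regions without a qualifying overlap start new ids.
    """
    params = params or SegParams()
    vol = np.asarray(label_slices)
    out = np.zeros_like(vol, dtype=np.int32)
    next_id = 1
    prev_map: dict[int, int] = {}
    for iz in range(vol.shape[0]):
        cur = vol[iz]
        if cur.max() == 0:
            prev_map = {}
            continue
        cur_map: dict[int, int] = {}
        if prev_map:
            corr = link(vol[iz - 1], cur, params)
            for lab_prev, lab_cur in corr.items():
                if lab_prev in prev_map:
                    cur_map[lab_cur] = prev_map[lab_prev]
        for lab in np.unique(cur):
            if lab == 0 or lab in cur_map:
                continue
            cur_map[lab] = next_id
            next_id += 1
        lut = np.zeros(cur.max() + 1, dtype=np.int32)
        for lab, tid in cur_map.items():
            lut[lab] = tid
        out[iz] = lut[cur]
        prev_map = cur_map
    return out


def track_time(label_frames: list[np.ndarray],
               params: SegParams | None = None
               ) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Link 2D label images across time; returns relabeled frames + table.

    The table lists (cell_id, frame, label, centroid_y, centroid_x,
    area_px); areas are in pixels and should be scaled by ``pixel_size**2``
    by the caller.
    """
    params = params or SegParams()
    relabeled: list[np.ndarray] = []
    rows = []
    next_id = 1
    prev_map: dict[int, int] = {}
    prev_frame: np.ndarray | None = None
    for fi, cur in enumerate(label_frames):
        cur = np.asarray(cur)
        cur_map: dict[int, int] = {}
        if prev_frame is not None and prev_map:
            corr = link(prev_frame, cur, params)
            for lab_prev, lab_cur in corr.items():
                if lab_prev in prev_map:
                    cur_map[lab_cur] = prev_map[lab_prev]
        for lab in np.unique(cur):
            if lab == 0 or lab in cur_map:
                continue
            cur_map[lab] = next_id
            next_id += 1
        lut = np.zeros(cur.max() + 1 if cur.size else 1, dtype=np.int32)
        for lab, tid in cur_map.items():
            lut[lab] = tid
        new = lut[cur]
        relabeled.append(new)
        for region in regionprops(new):
            cy, cx = region.centroid
            rows.append({
                "cell_id": region.label, "frame": fi,
                "centroid_y": cy, "centroid_x": cx,
                "area_px": region.area,
            })
        prev_map = cur_map
        prev_frame = cur
    table = pd.DataFrame(
        rows, columns=["cell_id", "frame", "centroid_y", "centroid_x",
                       "area_px"])
    return relabeled, table
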