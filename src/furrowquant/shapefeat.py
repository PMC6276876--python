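"""3D cell-shape reconstruction and feature extraction.

From a label volume with consistent cell ids across z, each cell is
described by its per-slice cross-section areas and centroids.  Derived
features follow the conventions of the quantification workflow:

* length L = occupied-slice count × dz;
* apical / basal areas = mean cross-section over a cap of slices at either
  end (default 3 slices, configurable to the single extreme slice);
* A/B ratio = apical-cap volume divided by basal-cap volume (1 = columnar,
  < 1 = apically constricted wedge);
* volume V = Σ area(z) · dz, with a coefficient-of-variation filter that
  drops cells whose volume deviates from the population mean by more than
  CV = 25%;
* apical anisotropy = major/minor axis ratio of the second-moment ellipse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import regionprops

__all__ = ["CellShape", "reconstruct", "ab_ratio",
           "filter_volume_outliers", "anisotropy", "features_table"]


@dataclass
class CellShape:
    """Per-slice geometry of one reconstructed cell (physical units)."""

    cell_id: int
    z_indices: np.ndarray       # occupied slice indices (may be gap-filled)
    areas: np.ndarray           # μm² per occupied slice
    centroids: np.ndarray       # (n, 2) μm, (y, x) per occupied slice
    dz: float
    incomplete: bool = False    # had a gap > 1 slice; exclude from stats

    @property
    def length(self) -> float:
        """Apico-basal length: occupied slice count × dz (μm)."""
        return len(self.z_indices) * self.dz

    @property
    def volume(self) -> float:
        """Σ area(z) · dz (μm³)."""
        return float(self.areas.sum() * self.dz)

    def apical_area(self, cap_slices: int = 3) -> float:
        """Mean cross-section over the apical-most ``cap_slices`` (μm²)."""
        return float(self.areas[:cap_slices].mean())

    def basal_area(self, cap_slices: int = 3) -> float:
        """Mean cross-section over the basal-most ``cap_slices`` (μm²)."""
        return float(self.areas[-cap_slices:].mean())


def reconstruct(label_volume: np.ndarray, pixel_size: float, dz: float,
                cell_ids: list[int] | None = None) -> list[CellShape]:
    """Reconstruct per-cell shapes from a (z, y, x) label volume.

    Single-slice gaps in a cell's z-extent are filled by linear
    interpolation of area and centroid; larger gaps flag the cell as
    incomplete (to be excluded from statistics).
    """
    vol = np.asarray(label_volume)
    if vol.ndim != 3:
        raise ValueError("label volume must be (z, y, x)")
    if pixel_size <= 0 or dz <= 0:
        raise ValueError("pixel_size and dz must be positive")
    ids = cell_ids if cell_ids is not None else [
        int(i) for i in np.unique(vol) if i > 0]
    # per-slice areas/centroids for all cells in one pass per slice
    per_cell: dict[int, dict[int, tuple[float, float, float]]] = {
        cid: {} for cid in ids}
    for iz in range(vol.shape[0]):
        for region in regionprops(vol[iz]):
            if region.label in per_cell:
                cy, cx = region.centroid
                per_cell[region.label][iz] = (
                    region.area * pixel_size ** 2,
                    cy * pixel_size, cx * pixel_size)
    shapes: list[CellShape] = []
    for cid in ids:
        slices = per_cell[cid]
        if not slices:
            continue
        zs = sorted(slices)
        gaps = np.diff(zs)
        incomplete = bool(np.any(gaps > 2))  # missing run of > 1 slice
        filled_z, areas, cents = [], [], []
        for i, z in enumerate(zs):
            a, cy, cx = slices[z]
            filled_z.append(z)
            areas.append(a)
            cents.append((cy, cx))
            if i + 1 < len(zs) and zs[i + 1] - z == 2:  # one missing slice
                a2, cy2, cx2 = slices[zs[i + 1]]
                filled_z.append(z + 1)
                areas.append((a + a2) / 2)
                cents.append(((cy + cy2) / 2, (cx + cx2) / 2))
        shapes.append(CellShape(
            cell_id=cid,
            z_indices=np.asarray(filled_z),
            areas=np.asarray(areas, float),
            centroids=np.asarray(cents, float),
            dz=dz,
            incomplete=incomplete,
        ))
    return shapes


def ab_ratio(shape: CellShape, cap_slices: int = 3) -> float:
    """Apical-cap volume over basal-cap volume.

    A ratio of 1 indicates a columnar cell; < 1 an apically constricted
    wedge; > 1 an inverted wedge.  Requires at least ``2 * cap_slices``
    occupied slices so the caps do not overlap.
    """
    if cap_slices < 1:
        raise ValueError("cap_slices must be at least 1")
    if len(shape.z_indices) < 2 * cap_slices:
        raise ValueError("too few occupied slices for the requested caps")
    apical = shape.areas[:cap_slices].sum() * shape.dz
    basal = shape.areas[-cap_slices:].sum() * shape.dz
    if basal == 0:
        raise ValueError("zero basal cap volume")
    return float(apical / basal)


def filter_volume_outliers(shapes: list[CellShape],
                           cv: float = 0.25) -> list[CellShape]:
    """Retain cells with |V − mean(V)| ≤ cv · mean(V) (single pass).

    The mean is computed once over all complete cells; the band is not
    re-estimated after removal.
    """
    if not shapes:
        raise ValueError("no shapes to filter")
    volumes = np.array([s.volume for s in shapes])
    mean = volumes.mean()
    keep = np.abs(volumes - mean) <= cv * mean
    return [s for s, k in zip(shapes, keep) if k]


def _polygon_moments(poly: np.ndarray) -> tuple[float, np.ndarray]:
    """Area and central second-moment matrix of a simple polygon."""
    x = poly[:, 0]
    y = poly[:, 1]
    x1 = np.roll(x, -1)
    y1 = np.roll(y, -1)
    cross = x * y1 - x1 * y
    area = cross.sum() / 2.0
    if area == 0:
        raise ValueError("degenerate polygon")
    cx = np.sum((x + x1) * cross) / (6.0 * area)
    cy = np.sum((y + y1) * cross) / (6.0 * area)
    ixx = np.sum((y**2 + y * y1 + y1**2) * cross) / 12.0
    iyy = np.sum((x**2 + x * x1 + x1**2) * cross) / 12.0
    ixy = np.sum((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross) / 24.0
    # shift to centroid; normalize out orientation sign
    sign = np.sign(area)
    ixx = (ixx - area * cy**2) * sign
    iyy = (iyy - area * cx**2) * sign
    ixy = (ixy - area * cx * cy) * sign
    return abs(area), np.array([[ixx, ixy], [ixy, iyy]])


def anisotropy(apical: np.ndarray) -> float:
    """Major/minor axis ratio of the second-moment ellipse (1 = isotropic).

    Accepts either a polygon as an (n, 2) array of (x, y) vertices (exact
    closed-form moments) or a 2D boolean mask (raster moments).
    """
    arr = np.asarray(apical)
    if arr.ndim == 2 and arr.shape[1] == 2 and arr.shape[0] > 2 \
            and not arr.dtype == bool:
        area, m = _polygon_moments(arr.astype(float))
        eig = np.linalg.eigvalsh(m)
        if eig[0] <= 0:
            raise ValueError("degenerate polygon")
        return float(np.sqrt(eig[1] / eig[0]))
    if arr.ndim == 2:
        mask = arr > 0
        if not mask.any():
            raise ValueError("empty mask")
        props = regionprops(mask.astype(np.uint8))[0]
        if props.minor_axis_length == 0:
            raise ValueError("degenerate region")
        return float(props.major_axis_length / props.minor_axis_length)
    raise ValueError("expected an (n, 2) polygon or a 2D mask")


def features_table(shapes: list[CellShape], cap_slices: int = 3,
                   cv: float = 0.25) -> pd.DataFrame:
    """Feature table with the CV-based retained flag.

    Columns: cell_id, length, apical_area, basal_area, ab_ratio, volume,
    incomplete, retained.  Incomplete cells are never retained.
    """
    if not shapes:
        return pd.DataFrame(columns=[
            "cell_id", "length", "apical_area", "basal_area", "ab_ratio",
            "volume", "incomplete", "retained"])
    complete = [s for s in shapes if not s.incomplete]
    retained_ids = {s.cell_id for s in filter_volume_outliers(complete, cv)} \
        if complete else set()
    rows = []
    for s in shapes:
        try:
            ratio = ab_ratio(s, cap_slices)
        except ValueError:
            ratio = np.nan
        rows.append({
            "cell_id": s.cell_id,
            "length": s.length,
            "apical_area": s.apical_area(cap_slices),
            "basal_area": s.basal_area(cap_slices),
            "ab_ratio": ratio,
            "volume": s.volume,
            "incomplete": s.incomplete,
            "retained": s.cell_id in retained_ids and not s.incomplete,
        })
    return pd.DataFrame(rows)
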