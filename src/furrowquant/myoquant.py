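"""Basal and apical myosin-II quantification.

The basal pool is quantified from a z-profile: the region of interest is
subdivided into a grid of subregions whose axial mean-intensity profiles are
averaged (area-weighted), a Gaussian with constant offset is fitted around
the basal-side maximum, and the "level" is read out as the mean integrated
density per unit area over a 5-slice (5 μm) window centered at the fitted
peak.  The width of the fitted Gaussian, reported as FWHM, measures axial
signal spreading (z-spread).  Apical levels are per-cell integrated
densities over a 3-slice window at the apical peak, normalized by the mean
of the combined cell population.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .io import ImageStack

__all__ = [
    "PeakNotFoundError", "ZProfilePeak", "MyosinLevel", "FitResult",
    "zprofile", "basal_level", "fold_change", "basal_projection",
    "apical_levels", "fit_timecourse",
]

_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548


class PeakNotFoundError(RuntimeError):
    """No usable intensity peak on the requested side of the profile."""


@dataclass
class ZProfilePeak:
    """Axial intensity profile with its fitted Gaussian basal peak."""

    profile: np.ndarray     # mean intensity per z slice
    z_um: np.ndarray        # axial coordinate of each slice, μm
    peak_z: float           # fitted center, μm
    amplitude: float        # fitted amplitude above offset
    fwhm: float             # 2.3548 * sigma, μm (the z-spread "width")
    offset: float           # fitted constant background
    fit_residual: float     # RMS residual of the fit

    @property
    def sigma(self) -> float:
        return self.fwhm / _FWHM_PER_SIGMA


@dataclass
class MyosinLevel:
    """Windowed basal level: mean integrated density per area (μm⁻²)."""

    level: float
    window_slices: int
    truncated: bool = False
    t: float = 0.0
    region: str = ""


@dataclass
class FitResult:
    """Least-squares polynomial fit of a level time-course."""

    degree: int
    coefficients: np.ndarray   # highest power first (numpy convention)
    r_squared: float


def _gauss(z, offset, amplitude, center, sigma):
    return offset + amplitude * np.exp(-((z - center) ** 2) / (2 * sigma**2))


def _subregion_profiles(stack: ImageStack, roi_mask: np.ndarray,
                        subgrid: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Axial mean-intensity profile per subregion tile, plus pixel weights."""
    mask = np.asarray(roi_mask, bool)
    if mask.shape != stack.data.shape[1:]:
        raise ValueError("roi_mask shape must match the stack's xy shape")
    if not mask.any():
        raise ValueError("roi_mask is empty")
    gy, gx = subgrid
    if gy < 1 or gx < 1:
        raise ValueError("subgrid must be at least 1x1")
    ys, xs = np.nonzero(mask)
    y_edges = np.linspace(ys.min(), ys.max() + 1, gy + 1)
    x_edges = np.linspace(xs.min(), xs.max() + 1, gx + 1)
    profiles, weights = [], []
    for iy in range(gy):
        for ix in range(gx):
            tile = np.zeros_like(mask)
            tile[int(y_edges[iy]):int(y_edges[iy + 1]),
                 int(x_edges[ix]):int(x_edges[ix + 1])] = True
            sel = tile & mask
            n = int(sel.sum())
            if n == 0:
                continue
            profiles.append(stack.data[:, sel].mean(axis=1))
            weights.append(n)
    return np.asarray(profiles), np.asarray(weights, float)


def zprofile(stack: ImageStack, roi_mask: np.ndarray,
             subgrid: tuple[int, int] = (4, 4)) -> ZProfilePeak:
    """Fit the basal Gaussian peak of a region's axial intensity profile.

    The profile is the area-weighted average over ``subgrid`` subregions of
    the ROI.  The fit (offset + Gaussian) is initialized at the basal-half
    argmax with the center bounded to the basal half, so a brighter apical
    peak cannot capture it.

    Raises
    ------
    PeakNotFoundError
        If the profile is flat or has no local maximum on the basal half.
    """
    profiles, weights = _subregion_profiles(stack, roi_mask, subgrid)
    profile = np.average(profiles, axis=0, weights=weights)
    z = stack.z_um
    if np.ptp(profile) <= 0:
        raise PeakNotFoundError("flat z-profile: no basal peak")
    mid = len(profile) // 2
    basal = profile[mid:]
    i_max = int(np.argmax(basal)) + mid
    # reject a spurious boundary "maximum" created by a decaying apical peak
    if i_max == mid and profile[mid - 1] > profile[mid]:
        raise PeakNotFoundError("no local maximum on the basal half")
    p0 = (float(profile.min()),
          float(profile[i_max] - profile.min()),
          float(z[i_max]),
          2.0 * stack.dz)
    bounds = ([-np.inf, 0.0, z[mid], 0.1 * stack.dz],
              [np.inf, np.inf, z[-1] + stack.dz, z[-1] - z[0] + stack.dz])
    popt, _ = curve_fit(_gauss, z, profile, p0=p0, bounds=bounds,
                        maxfev=20000)
    offset, amplitude, center, sigma = popt
    residual = float(np.sqrt(np.mean((profile - _gauss(z, *popt)) ** 2)))
    return ZProfilePeak(
        profile=profile, z_um=z, peak_z=float(center),
        amplitude=float(amplitude), fwhm=float(_FWHM_PER_SIGMA * sigma),
        offset=float(offset), fit_residual=residual,
    )


def _window_slices(center_idx: int, window: int,
                   n_slices: int) -> tuple[np.ndarray, bool]:
    half = window // 2
    lo = center_idx - half
    hi = center_idx + half + 1
    truncated = lo < 0 or hi > n_slices
    return np.arange(max(lo, 0), min(hi, n_slices)), truncated


def basal_level(stack: ImageStack, roi_mask: np.ndarray, peak_z: float,
                window: int = 5, background: float = 0.0) -> MyosinLevel:
    """Mean integrated density per area over ``window`` slices at the peak.

    Level units are intensity · μm⁻²: per slice, the summed intensity over
    the ROI divided by the ROI area; averaged over the window.  A window
    reaching past the stack edge is truncated and flagged.

    ``background`` (intensity per pixel) is subtracted before integration;
    pass the fitted Gaussian offset of the z-profile to report levels above
    background — the only background correction this pipeline applies.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    mask = np.asarray(roi_mask, bool)
    if not mask.any():
        raise ValueError("roi_mask is empty")
    center_idx = int(round(peak_z / stack.dz))
    if center_idx < 0 or center_idx >= stack.n_slices:
        raise ValueError("peak_z outside the stack")
    sl, truncated = _window_slices(center_idx, window, stack.n_slices)
    area_um2 = mask.sum() * stack.pixel_size ** 2
    densities = (stack.data[sl][:, mask] - background).sum(axis=1) / area_um2
    return MyosinLevel(level=float(densities.mean()),
                       window_slices=len(sl), truncated=truncated,
                       t=stack.t)


def fold_change(level_num: float, level_den: float) -> float:
    """Ratio of two levels (e.g. activated over non-activated region)."""
    if level_den == 0:
        raise ZeroDivisionError("denominator level is zero")
    return level_num / level_den


def basal_projection(stack: ImageStack,
                     regions: Mapping[str, tuple[np.ndarray, float]],
                     window: int = 5) -> np.ndarray:
    """Summed z-projection over the combined basal-peak windows, normalized.

    ``regions`` maps region name to ``(mask, peak_z)``.  The window slices of
    every region are combined (union), summed into one 2D projection, and the
    result is divided by its mean over the combined analyzed area, which is
    therefore exactly 1.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    slice_set: set[int] = set()
    combined_mask = np.zeros(stack.data.shape[1:], dtype=bool)
    for name, (mask, peak_z) in regions.items():
        mask = np.asarray(mask, bool)
        if not mask.any():
            raise ValueError(f"region {name!r} mask is empty")
        center_idx = int(round(peak_z / stack.dz))
        sl, _ = _window_slices(center_idx, window, stack.n_slices)
        slice_set.update(int(i) for i in sl)
        combined_mask |= mask
    proj = stack.data[sorted(slice_set)].sum(axis=0)
    norm = proj[combined_mask].mean()
    if norm == 0:
        raise ValueError("zero mean over the analyzed area")
    return proj / norm


def apical_levels(stack: ImageStack, cell_labels: np.ndarray,
                  window: int = 3,
                  subgrid: tuple[int, int] = (4, 4)) -> pd.Series:
    """Per-cell apical myosin levels, normalized to the population mean.

    The apical peak is located with the same Gaussian-fit procedure as the
    basal one, restricted to the apical half of the profile over the labeled
    area.  Each cell's intensity is integrated over ``window`` slices at the
    peak and divided by the mean integrated density per cell of the combined
    population (population mean = 1).  Cells absent from the apical slices
    get NaN.
    """
    labels = np.asarray(cell_labels)
    if labels.shape != stack.data.shape[1:]:
        raise ValueError("cell_labels shape must match the stack's xy shape")
    footprint = labels > 0
    if not footprint.any():
        raise ValueError("no labeled cells")
    # flip the stack so the apical half becomes the "basal" search half
    flipped = stack.with_data(stack.data[::-1])
    peak = zprofile(flipped, footprint, subgrid=subgrid)
    apical_z = (stack.n_slices - 1) * stack.dz - peak.peak_z
    center_idx = int(round(apical_z / stack.dz))
    sl, _ = _window_slices(center_idx, window, stack.n_slices)
    window_img = stack.data[sl].sum(axis=0)
    ids = np.unique(labels[footprint])
    values = {}
    for cid in ids:
        sel = labels == cid
        values[int(cid)] = float(window_img[sel].sum()) if sel.any() else np.nan
    series = pd.Series(values, name="apical_level")
    mean = series.mean()
    if not np.isfinite(mean) or mean == 0:
        raise ValueError("population mean integrated density is zero")
    return series / mean


def fit_timecourse(t: np.ndarray, levels: np.ndarray,
                   degree: int) -> FitResult:
    """Least-squares polynomial fit with r² = 1 − SSres/SStot.

    Constant data (SStot = 0) yields r² = 0 by convention.
    """
    t = np.asarray(t, float)
    y = np.asarray(levels, float)
    if len(t) < degree + 1:
        raise ValueError("need at least degree + 1 points")
    if np.ptp(t) == 0:
        raise ValueError("degenerate time values")
    coeff = np.polyfit(t, y, degree)
    pred = np.polyval(coeff, t)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return FitResult(degree=degree, coefficients=coeff,
                     r_squared=float(np.clip(r2, 0.0, 1.0)))
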