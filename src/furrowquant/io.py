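"""Calibrated image containers and TIFF/CSV input-output.

All volumes use axis order ``(z, y, x)`` with z index 0 at the apical-most
slice, increasing toward the basal surface.  Physical calibration (pixel size
in the imaging plane, axial step ``dz``, frame interval) travels with the
data so that every downstream measurement can be reported in micrometres and
seconds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile


class FormatError(ValueError):
    """Raised when a file does not match the expected layout."""


@dataclass
class ImageStack:
    """A single 3D intensity volume with physical calibration.

    Parameters
    ----------
    data:
        Array of shape ``(z, y, x)``; converted to float64 on construction.
    pixel_size:
        Lateral pixel size in micrometres.
    dz:
        Axial slice spacing in micrometres.
    frame_interval:
        Time between consecutive volumes of a series, in seconds.
    channel:
        Role tag, e.g. ``"membrane"`` or ``"myosin"``.
    t:
        Acquisition time of this volume in seconds.
    """

    data: np.ndarray
    pixel_size: float
    dz: float
    frame_interval: float = 0.0
    channel: str = ""
    t: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim == 2:
            arr = arr[np.newaxis]
        if arr.ndim != 3:
            raise FormatError(
                f"expected a (z, y, x) volume, got {arr.ndim} dimensions"
            )
        if self.pixel_size <= 0 or self.dz <= 0:
            raise ValueError("pixel_size and dz must be positive")
        self.data = arr

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def z_um(self) -> np.ndarray:
        """Axial coordinate of each slice in micrometres (apical = 0)."""
        return np.arange(self.n_slices) * self.dz

    def with_data(self, data: np.ndarray) -> "ImageStack":
        return replace(self, data=data)


def read_stack(
    path: str | Path,
    pixel_size: float,
    dz: float,
    frame_interval: float = 0.0,
    channel: str = "",
) -> ImageStack:
    """Read a multi-page TIFF as a calibrated ``(z, y, x)`` stack.

    Integer TIFFs are promoted to float without rescaling, so a 16-bit value
    of 1234 reads back as 1234.0.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(path)
    if arr.ndim not in (2, 3):
        raise FormatError(
            f"{path}: expected 2D or 3D TIFF with axis order (z, y, x), "
            f"got shape {arr.shape}"
        )
    return ImageStack(
        data=arr, pixel_size=pixel_size, dz=dz,
        frame_interval=frame_interval, channel=channel,
    )


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as a float32 multi-page TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.data.astype(np.float32),
                     photometric="minisblack")
    return path


def write_labels(labels: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(labels).astype(np.int32),
                     photometric="minisblack")
    return path


def read_labels(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(Path(path))
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"{path}: label TIFF must be integer typed")
    return arr.astype(np.int64)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a single-page TIFF/PNG mask as a boolean array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        from imageio.v3 import imread  # PNG fall-back

        arr = imread(path)
    if arr.ndim == 3:  # collapse RGB
        arr = arr[..., 0]
    return np.asarray(arr) > 0


def config_digest(obj) -> str:
    """Short stable hash of a configuration mapping (for provenance lines)."""
    payload = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def write_table(
    table: pd.DataFrame, path: str | Path, meta: Mapping | None = None
) -> Path:
    """Write a CSV with optional ``# key: value`` provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        table.to_csv(fh, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), comment="#")
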