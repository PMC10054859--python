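"""Shared containers and file I/O for the seagrass monitoring pipeline.

Grids are row-major numpy arrays, 0-based, origin at top-left.  Water depth is
in meters, positive down; land carries NaN depth.  Class maps use the integer
code table in :data:`CLASS_CODES`.  Rasters are written as plain multiband
TIFF with an identity geotransform (no map projection is attached).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

# ---------------------------------------------------------------------------
# class code table
# ---------------------------------------------------------------------------

LAND = 0
DEEP_WATER = 1
SEAGRASS = 2
SAND = 3
INTERTIDAL = 4

CLASS_CODES: Mapping[str, int] = {
    "land": LAND,
    "deep_water": DEEP_WATER,
    "seagrass": SEAGRASS,
    "sand": SAND,
    "intertidal": INTERTIDAL,
}
CLASS_NAMES: Mapping[int, str] = {v: k for k, v in CLASS_CODES.items()}

#: sentinel written to integer rasters for masked / invalid pixels
MASKED_CODE = 255

#: default band ordering (green and NIR positions matter downstream)
DEFAULT_BANDS: tuple[str, ...] = ("blue", "green", "red", "nir", "swir1", "swir2")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class SceneStack:
    """Multiband surface-reflectance grid plus acquisition metadata.

    ``reflectance`` has shape (n_bands, n_rows, n_cols); ``bands`` names each
    slice in order.  ``metadata`` is an arbitrary mapping echoing the
    generating configuration (date, sensor tag, tide height, optics).
    """

    reflectance: np.ndarray
    bands: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.bands = tuple(self.bands)
        if self.reflectance.ndim != 3:
            raise ValueError("reflectance must be (bands, rows, cols)")
        if self.reflectance.shape[0] != len(self.bands):
            raise ValueError(
                f"{self.reflectance.shape[0]} band planes but "
                f"{len(self.bands)} band names"
            )
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.reflectance.shape[1:]

    def band_index(self, name: str) -> int:
        try:
            return self.bands.index(name)
        except ValueError:
            raise KeyError(f"band {name!r} not in {self.bands}") from None

    def band(self, name: str) -> np.ndarray:
        """Return the 2-D plane for one band (a view, not a copy)."""
        return self.reflectance[self.band_index(name)]

    def copy(self) -> "SceneStack":
        return SceneStack(self.reflectance.copy(), self.bands, dict(self.metadata))


@dataclass
class ClassMap:
    """Per-pixel class labels with an exclusion mask.

    ``labels`` holds codes from :data:`CLASS_CODES`; ``mask`` is True where a
    pixel is excluded from analysis (depth-masked, data gap, ...).  Masked
    pixels keep their last label but are ignored by extent, frequency and
    agreement computations.
    """

    labels: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.mask is None:
            self.mask = np.zeros(self.labels.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.labels.shape:
            raise ValueError("mask shape must match labels")
        valid_codes = set(CLASS_NAMES)
        bad = set(np.unique(self.labels[~self.mask])) - valid_codes
        if bad:
            raise ValueError(f"invalid class codes present: {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def copy(self) -> "ClassMap":
        return ClassMap(self.labels.copy(), self.mask.copy())


# ---------------------------------------------------------------------------
# raster / table I/O
# ---------------------------------------------------------------------------


def write_raster(path: str | Path, array: np.ndarray) -> None:
    """Write a 2-D grid or a (bands, rows, cols) stack as a TIFF."""
    arr = np.asarray(array)
    if arr.ndim not in (2, 3):
        raise ValueError("raster must be 2-D or 3-D")
    tifffile.imwrite(str(path), arr)


def read_raster(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)))


def write_scene(path: str | Path, scene: SceneStack) -> None:
    write_raster(path, scene.reflectance.astype(np.float32))


def read_scene(path: str | Path, bands: Sequence[str] = DEFAULT_BANDS,
               metadata: dict | None = None) -> SceneStack:
    arr = read_raster(path).astype(float)
    if arr.ndim == 2:
        arr = arr[None]
    return SceneStack(arr, tuple(bands), metadata or {})


def write_class_map(path: str | Path, cmap: ClassMap) -> None:
    """Integer raster with :data:`MASKED_CODE` marking masked pixels."""
    out = cmap.labels.astype(np.uint8).copy()
    out[cmap.mask] = MASKED_CODE
    write_raster(path, out)


def read_class_map(path: str | Path) -> ClassMap:
    arr = read_raster(path)
    mask = arr == MASKED_CODE
    labels = arr.copy()
    labels[mask] = LAND  # placeholder under the mask
    return ClassMap(labels.astype(np.int16), mask)


def write_covariates(path: str | Path, table: pd.DataFrame) -> None:
    cols = ["year", "season", "enso", "nao", "sst"]
    missing = set(cols) - set(table.columns)
    if missing:
        raise ValueError(f"covariate table missing columns: {sorted(missing)}")
    table.loc[:, cols].to_csv(path, index=False)


def read_covariates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
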