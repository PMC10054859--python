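"""Scene conditioning: dark-object subtraction and scanline gap filling.

Atmospheric correction is the classic dark-object subtraction (DOS): the
darkest NIR pixel over water is taken to have zero surface reflectance, so
whatever the sensor records there is additive path radiance; that pixel's
per-band values are subtracted from the whole scene (clipped at zero).
Restricting the search to a water mask keeps the dark pixel out of shadowed
land and inland ponds.

Gap filling (for scanline-failure stripes) is an iterative 8-neighbour mean
— deliberately simple, documented as a stand-in for purpose-built scanline
repair tools.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core import SceneStack

logger = logging.getLogger(__name__)

_NEIGHBOUR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=float)


@dataclass(frozen=True)
class DarkOffset:
    """Per-band additive offsets read off the darkest NIR water pixel."""

    offsets: np.ndarray
    dark_pixel: tuple[int, int]
    source_band: str

    def __post_init__(self):
        object.__setattr__(self, "offsets", np.asarray(self.offsets, dtype=float))
        if np.any(self.offsets < 0) or not np.all(np.isfinite(self.offsets)):
            raise ValueError("offsets must be finite and >= 0")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "offsets": self.offsets.tolist(),
            "dark_pixel": list(self.dark_pixel),
            "source_band": self.source_band,
        }, indent=2))


def find_dark_offset(scene: SceneStack, water_mask: np.ndarray,
                     source_band: str = "nir") -> DarkOffset:
    """Locate the minimum-NIR water pixel; its band vector is the offset.

    Ties at the minimum resolve to the first pixel in row-major scan order.
    """
    water_mask = np.asarray(water_mask, dtype=bool)
    if water_mask.shape != scene.shape:
        raise ValueError("water mask shape must match scene")
    if not water_mask.any():
        raise ValueError("water mask is empty")
    nir = scene.band(source_band)
    search = np.where(water_mask, nir, np.inf)
    flat = int(np.argmin(search))  # argmin returns first minimum in scan order
    loc = np.unravel_index(flat, search.shape)
    offsets = scene.reflectance[:, loc[0], loc[1]].copy()
    return DarkOffset(offsets=offsets, dark_pixel=(int(loc[0]), int(loc[1])),
                      source_band=source_band)


def dos_correct(scene: SceneStack, offsets: DarkOffset) -> SceneStack:
    """Subtract the per-band dark offsets, clipping at zero.

    Metadata is preserved.  The number of clipped pixels is logged; after
    correction the NIR minimum over the original water mask is exactly 0.
    """
    if offsets.offsets.shape != (len(scene.bands),):
        raise ValueError(
            f"{len(offsets.offsets)} offsets for {len(scene.bands)} bands")
    corrected = scene.reflectance - offsets.offsets[:, None, None]
    clipped = corrected < 0
    if clipped.any():
        logger.info("dos_correct: clipped %d negative values to 0",
                    int(clipped.sum()))
    corrected = np.maximum(corrected, 0.0)
    return SceneStack(reflectance=corrected, bands=scene.bands,
                      metadata=dict(scene.metadata))


def fill_gaps(scene: SceneStack, gap_mask: np.ndarray,
              tol: float = 1e-10, max_iter: int = 1000) -> SceneStack:
    """Fill gap pixels from their 8-neighbourhood, iterated to equilibrium.

    An inward pass first seeds every gap pixel with the mean of its non-gap
    neighbours; the gap region is then relaxed (repeated neighbourhood
    averaging with the non-gap pixels held fixed) until the fill stabilises,
    which reproduces linear ramps across stripes.  Non-gap pixels are never
    touched.  A scene that is entirely gap cannot be filled and raises.
    """
    gap_mask = np.asarray(gap_mask, dtype=bool)
    if gap_mask.shape != scene.shape:
        raise ValueError("gap mask shape must match scene")
    if gap_mask.all():
        raise ValueError("entire scene is gap; nothing to interpolate from")
    out = scene.reflectance.copy()
    valid = ~gap_mask
    remaining = gap_mask.copy()
    while remaining.any():
        n_valid = ndimage.convolve(valid.astype(float), _NEIGHBOUR_KERNEL,
                                   mode="constant", cval=0.0)
        can_fill = remaining & (n_valid > 0)
        if not can_fill.any():
            raise ValueError("isolated gap region with no valid neighbours")
        for bi in range(out.shape[0]):
            s = ndimage.convolve(np.where(valid, out[bi], 0.0),
                                 _NEIGHBOUR_KERNEL, mode="constant", cval=0.0)
            out[bi][can_fill] = s[can_fill] / n_valid[can_fill]
        valid |= can_fill
        remaining &= ~can_fill
    # relax the filled region so multi-pixel stripes interpolate smoothly
    inside = ndimage.convolve(np.ones(gap_mask.shape),
                              _NEIGHBOUR_KERNEL, mode="constant", cval=0.0)
    for bi in range(out.shape[0]):
        band = out[bi]
        for _ in range(max_iter):
            smoothed = ndimage.convolve(band, _NEIGHBOUR_KERNEL,
                                        mode="constant", cval=0.0) / inside
            delta = np.max(np.abs(smoothed[gap_mask] - band[gap_mask])) \
                if gap_mask.any() else 0.0
            band = np.where(gap_mask, smoothed, band)
            if delta < tol:
                break
        out[bi] = band
    return SceneStack(reflectance=out, bands=scene.bands,
                      metadata=dict(scene.metadata))
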