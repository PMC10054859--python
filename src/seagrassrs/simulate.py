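"""Synthetic multispectral scene generator for a shallow seagrass lagoon.

Produces everything the downstream pipeline consumes — a bathymetric DEM,
per-pixel truth (five bottom/land classes and a smooth LAI field under
seagrass), a rendered multiband reflectance scene, reusable training regions
of interest, and a climate covariate table — all as pure functions of a
:class:`SceneConfig` and its seed.

The rendered scene follows the same physics the retrieval inverts: the green
band over submerged vegetated/sand bottom is (R_b/pi)*exp(-(K_d+K_Lu)*H) with
R_b tied to LAI through the shared log-linear law; every band then receives a
per-band additive atmospheric path offset and Gaussian sensor noise.
Optically-deep water is rendered as a full absorber (no bottom or
water-leaving signal), so the darkest NIR pixel carries exactly the path
offset — the assumption dark-object subtraction rests on.

Scene geometry emulates a lagoon cross-section: a land strip, a narrow
intertidal ring, a shallow vegetated shelf (< 2.5 m) and a deep basin.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import (CLASS_CODES, CLASS_NAMES, DEEP_WATER, DEFAULT_BANDS,
                   INTERTIDAL, LAND, SAND, SEAGRASS, ClassMap, SceneStack,
                   write_covariates, write_raster, write_scene)
from .optics_carbon import LAICoefficients, OpticsRecord, klu_from_kd, rb_from_lai, rrs_from_rb

logger = logging.getLogger(__name__)

# distinct RNG streams per generator so each op is independently reproducible
_STREAM_DEM = 0
_STREAM_TRUTH = 1
_STREAM_SCENE = 2
_STREAM_ROIS = 3
_STREAM_COVARIATES = 4

#: constant bottom reflectance of submerged bare sand
SAND_RB = 0.45

# Class mean spectra (band order blue, green, red, nir, swir1, swir2).
# Green entries marked NaN are produced by the physical water-column model
# instead of the library.  Values are plausible surface reflectances for the
# emulated sensor class; separation between them is scaled by
# ``SceneConfig.separation``.
_BASE_SPECTRA = {
    LAND:       np.array([0.060, 0.085, 0.110, 0.420, 0.350, 0.250]),
    DEEP_WATER: np.array([0.000, 0.000, 0.000, 0.000, 0.000, 0.000]),
    SEAGRASS:   np.array([0.022, np.nan, 0.016, 0.005, 0.003, 0.002]),
    SAND:       np.array([0.065, np.nan, 0.055, 0.008, 0.004, 0.003]),
    INTERTIDAL: np.array([0.050, 0.070, 0.065, 0.120, 0.080, 0.060]),
}


@dataclass(frozen=True)
class SceneConfig:
    """All knobs of the synthetic scene, with study-condition defaults.

    Optics default to the long-term means of the emulated system (K_d = 0.734
    1/m at 560 nm, K_Lu = K_d/2pi, tide 0.24 m); the grid is 30 m pixels; the
    LAI field averages 1.6 under seagrass.
    """

    n_rows: int = 128
    n_cols: int = 128
    pixel_size: float = 30.0
    bands: tuple[str, ...] = DEFAULT_BANDS
    green_band: str = "green"
    nir_band: str = "nir"
    date: datetime.date = datetime.date(2010, 10, 15)
    sensor_tag: str = "L5"
    tide_height: float = 0.24
    kd: float = 0.734
    klu: float | None = None  # derived as kd/2pi when None
    path_offset: float | tuple[float, ...] = 0.01
    noise_sd: float = 0.001
    seed: int = 0

    # scene morphology
    land_fraction: float = 0.15
    shelf_fraction: float = 0.45
    deep_threshold: float = 2.5
    max_depth: float = 8.0
    dem_noise_sd: float = 0.15
    constant_depth: float | None = None

    # bottom cover
    seagrass_fraction: float = 0.6  # of shelf pixels
    lai_mean: float = 1.6
    lai_sd: float = 0.3
    lai_max: float = 3.0
    uniform_lai: float | None = None
    lai_coeffs: LAICoefficients = field(default_factory=LAICoefficients)

    # spectral separation multiplier for the class library
    separation: float = 1.0

    def __post_init__(self):
        if self.n_rows < 8 or self.n_cols < 8:
            raise ValueError("grid must be at least 8x8")
        if not self.kd > 0:
            raise ValueError("kd must be positive")
        if self.klu is not None and not self.klu > 0:
            raise ValueError("klu must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if np.any(np.asarray(self.path_offset) < 0):
            raise ValueError("path_offset must be >= 0")
        if self.green_band not in self.bands or self.nir_band not in self.bands:
            raise ValueError("bands must include the green and NIR bands")
        if not 0.0 <= self.seagrass_fraction <= 1.0:
            raise ValueError("seagrass_fraction must be in [0, 1]")

    @property
    def optics(self) -> OpticsRecord:
        klu = self.klu if self.klu is not None else klu_from_kd(self.kd)
        return OpticsRecord(kd=self.kd, klu=klu, date=self.date)

    @property
    def path_offsets(self) -> np.ndarray:
        off = np.asarray(self.path_offset, dtype=float)
        if off.ndim == 0:
            off = np.full(len(self.bands), float(off))
        if off.shape != (len(self.bands),):
            raise ValueError("path_offset must be scalar or one value per band")
        return off

    def with_(self, **kw) -> "SceneConfig":
        return replace(self, **kw)


@dataclass
class TruthMaps:
    """Ground truth for one synthetic scene."""

    class_grid: np.ndarray  # int codes, all five classes
    lai_grid: np.ndarray    # float, 0 outside seagrass
    dem: np.ndarray         # depth m positive down, NaN over land

    def __post_init__(self):
        if not (self.class_grid.shape == self.lai_grid.shape == self.dem.shape):
            raise ValueError("truth grids must share one shape")
        if np.any(self.lai_grid[self.class_grid != SEAGRASS] != 0):
            raise ValueError("LAI must be 0 wherever class != seagrass")

    @property
    def water_mask(self) -> np.ndarray:
        return ~np.isnan(self.dem)


@dataclass
class ROISet:
    """Homogeneous rectangular training regions, 3-6 per class, disjoint.

    ``regions`` is a list of ``(class_code, indices)`` with ``indices`` an
    (n, 2) array of (row, col) pixel positions.
    """

    regions: list[tuple[int, np.ndarray]]

    def counts(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for code, idx in self.regions:
            out[code] = out.get(code, 0) + len(idx)
        return out

    def regions_for(self, code: int) -> list[np.ndarray]:
        return [idx for c, idx in self.regions if c == code]

    def as_mask(self, shape: tuple[int, int]) -> tuple[np.ndarray, pd.DataFrame]:
        """Integer region-id raster (0 = none) plus a region legend table."""
        mask = np.zeros(shape, dtype=np.int32)
        rows = []
        for rid, (code, idx) in enumerate(self.regions, start=1):
            mask[idx[:, 0], idx[:, 1]] = rid
            rows.append({"region_id": rid, "class_code": code,
                         "class_name": CLASS_NAMES[code], "n_pixels": len(idx)})
        return mask, pd.DataFrame(rows)

    @classmethod
    def from_mask(cls, mask: np.ndarray, legend: pd.DataFrame) -> "ROISet":
        regions = []
        for _, row in legend.iterrows():
            idx = np.argwhere(mask == row["region_id"])
            regions.append((int(row["class_code"]), idx))
        return cls(regions)


def _rng(config: SceneConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def class_spectra(separation: float = 1.0) -> dict[int, np.ndarray]:
    """Class mean spectra with separation scaled about the class-library mean."""
    stack = np.array([_BASE_SPECTRA[c] for c in sorted(_BASE_SPECTRA)])
    centre = np.nanmean(stack, axis=0)
    out = {}
    for code in sorted(_BASE_SPECTRA):
        spec = _BASE_SPECTRA[code]
        out[code] = np.where(np.isnan(spec), np.nan,
                             centre + separation * (spec - centre))
    return out


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Standardized Gaussian-smoothed noise field (zero mean, unit sd)."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma,
                                mode="reflect")
    sd = f.std()
    return (f - f.mean()) / sd if sd > 0 else f


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_dem(config: SceneConfig) -> np.ndarray:
    """Smooth bathymetry: land strip, shallow shelf, deep basin.

    Depth increases left to right (column axis): negative (-> NaN, land) over
    the first ``land_fraction`` of columns, then a broad shallow platform
    deepening quadratically to ``deep_threshold`` across the shelf (mean
    shelf depth about a third of the threshold, matching the shallow
    vegetated habitat the scene emulates), then down to ``max_depth``; a
    smooth random perturbation of sd ``dem_noise_sd`` m is added over water.
    ``constant_depth`` short-circuits everything with a flat all-water grid.
    """
    shape = (config.n_rows, config.n_cols)
    if config.constant_depth is not None:
        return np.full(shape, float(config.constant_depth))
    x = (np.arange(config.n_cols) + 0.5) / config.n_cols
    lf, sf = config.land_fraction, config.shelf_fraction
    profile = np.empty(config.n_cols)
    land = x < lf
    shelf = (~land) & (x < lf + sf)
    basin = x >= lf + sf
    profile[land] = (x[land] - lf) / max(lf, 1e-9)  # -1 .. 0
    profile[shelf] = ((x[shelf] - lf) / max(sf, 1e-9)) ** 2 \
        * config.deep_threshold
    profile[basin] = (config.deep_threshold
                      + (x[basin] - lf - sf) / max(1 - lf - sf, 1e-9)
                      * (config.max_depth - config.deep_threshold))
    dem = np.broadcast_to(profile, shape).copy()
    if config.dem_noise_sd > 0:
        dem += config.dem_noise_sd * _smooth_field(_rng(config, _STREAM_DEM),
                                                   shape, sigma=4.0)
    dem[dem < 0] = np.nan  # land
    return dem


def generate_truth(config: SceneConfig, dem: np.ndarray) -> TruthMaps:
    """Assign the five classes and a smooth LAI field on the shelf.

    Land where depth is absent; a thin intertidal ring where water touches
    land; optically-deep water beyond ``deep_threshold``; the remaining shelf
    split into seagrass and sand by thresholding a smooth random field at the
    configured seagrass fraction.
    """
    if dem.shape != (config.n_rows, config.n_cols):
        raise ValueError("dem shape does not match config")
    rng = _rng(config, _STREAM_TRUTH)
    land = np.isnan(dem)
    water = ~land
    ring = ndimage.binary_dilation(land, iterations=2) & water
    deep = water & ~ring & (dem > config.deep_threshold)
    shelf = water & ~ring & ~deep

    classes = np.full(dem.shape, SAND, dtype=np.int16)
    classes[land] = LAND
    classes[ring] = INTERTIDAL
    classes[deep] = DEEP_WATER

    if config.seagrass_fraction > 0 and shelf.any():
        f = _smooth_field(rng, dem.shape, sigma=6.0)
        if config.seagrass_fraction >= 1.0:
            sg = shelf
        else:
            thr = np.quantile(f[shelf], 1.0 - config.seagrass_fraction)
            sg = shelf & (f >= thr)
        classes[sg] = SEAGRASS
    sg = classes == SEAGRASS

    lai = np.zeros(dem.shape)
    if sg.any():
        if config.uniform_lai is not None:
            lai[sg] = config.uniform_lai
        else:
            f = _smooth_field(rng, dem.shape, sigma=8.0)
            lai_field = np.clip(config.lai_mean + config.lai_sd * f,
                                0.0, config.lai_max)
            lai[sg] = lai_field[sg]
    return TruthMaps(class_grid=classes, lai_grid=lai, dem=dem)


def render_scene(truth: TruthMaps, config: SceneConfig) -> SceneStack:
    """Forward-model the truth into a multiband reflectance scene.

    Submerged vegetated/sand bottom contributes (R_b/pi)*exp(-(K_d+K_Lu)*H)
    in the green band (H = depth + tide); other bands and emergent classes
    come from the class spectral library; deep water carries no surface
    signal.  Every band then gains its path offset and Gaussian noise;
    negative results are clipped to 0 (count logged).
    """
    if truth.class_grid.shape != (config.n_rows, config.n_cols):
        raise ValueError("truth shape does not match config")
    rng = _rng(config, _STREAM_SCENE)
    spectra = class_spectra(config.separation)
    nb = len(config.bands)
    shape = truth.class_grid.shape
    refl = np.zeros((nb,) + shape)

    for code, spec in spectra.items():
        sel = truth.class_grid == code
        for bi in range(nb):
            if not np.isnan(spec[bi]):
                refl[bi][sel] = spec[bi]

    # physical green band over submerged bottom (seagrass + sand)
    gi = config.bands.index(config.green_band)
    depth = np.where(np.isnan(truth.dem), 0.0, truth.dem) + config.tide_height
    depth = np.maximum(depth, 0.0)
    optics = config.optics
    sg = truth.class_grid == SEAGRASS
    sd = truth.class_grid == SAND
    rb = np.zeros(shape)
    rb[sg] = rb_from_lai(truth.lai_grid[sg], config.lai_coeffs)
    rb[sd] = SAND_RB
    submerged = sg | sd
    refl[gi][submerged] = rrs_from_rb(rb, depth, optics)[submerged]

    refl += config.path_offsets[:, None, None]
    if config.noise_sd > 0:
        refl += rng.normal(0.0, config.noise_sd, refl.shape)
    clipped = refl < 0
    if clipped.any():
        logger.info("render_scene: clipped %d negative values to 0",
                    int(clipped.sum()))
        refl[clipped] = 0.0

    meta = {
        "date": config.date, "sensor": config.sensor_tag,
        "tide_height": config.tide_height, "kd": optics.kd, "klu": optics.klu,
        "pixel_size": config.pixel_size, "seed": config.seed,
    }
    return SceneStack(reflectance=refl, bands=config.bands, metadata=meta)


def make_rois(truth: TruthMaps, config: SceneConfig,
              n_per_class: tuple[int, int] = (3, 6),
              max_side: int = 12) -> ROISet:
    """Place 3-6 disjoint homogeneous rectangles per class.

    Rectangles are grown at random positions inside each class and never
    reuse a pixel; an explicit error names any class that is absent or too
    fragmented to host the minimum number of regions.
    """
    rng = _rng(config, _STREAM_ROIS)
    lo, hi = n_per_class
    used = np.zeros(truth.class_grid.shape, dtype=bool)
    regions: list[tuple[int, np.ndarray]] = []
    nrow, ncol = truth.class_grid.shape

    for code in sorted(CLASS_NAMES):
        cells = np.argwhere(truth.class_grid == code)
        if len(cells) == 0:
            raise ValueError(f"class {CLASS_NAMES[code]!r} absent from truth")
        target = int(rng.integers(lo, hi + 1))
        placed = 0
        attempts = 0
        while placed < target and attempts < 4000:
            attempts += 1
            r0, c0 = cells[rng.integers(len(cells))]
            h = int(rng.integers(1, max_side + 1))
            w = int(rng.integers(2, max_side + 1))
            r1, c1 = min(r0 + h, nrow), min(c0 + w, ncol)
            block = truth.class_grid[r0:r1, c0:c1]
            if block.size < 2:
                continue
            if np.any(block != code) or np.any(used[r0:r1, c0:c1]):
                continue
            used[r0:r1, c0:c1] = True
            idx = np.argwhere(np.zeros((r1 - r0, c1 - c0)) == 0)
            idx[:, 0] += r0
            idx[:, 1] += c0
            regions.append((int(code), idx))
            placed += 1
        if placed < lo:
            raise ValueError(
                f"could not place {lo} regions for class {CLASS_NAMES[code]!r}"
                f" (placed {placed})")
    return ROISet(regions=regions)


def make_covariates(years: Sequence[int], seasons: Sequence[str] | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Climate covariates (ENSO, NAO indices; SST deg C), one row per scene."""
    years = list(years)
    if seasons is None:
        seasons = ["autumn"] * len(years)
    if len(seasons) != len(years):
        raise ValueError("one season tag per year required")
    rng = np.random.default_rng([seed, _STREAM_COVARIATES])
    enso = rng.normal(0.0, 1.0, len(years))
    nao = rng.normal(0.0, 1.0, len(years))
    sst = 25.0 + 0.3 * enso + rng.normal(0.0, 0.8, len(years))
    return pd.DataFrame({"year": years, "season": list(seasons),
                         "enso": enso, "nao": nao, "sst": sst})


# ---------------------------------------------------------------------------
# convenience: full scene bundle + disk layout
# ---------------------------------------------------------------------------


def simulate_scene(config: SceneConfig) -> tuple[SceneStack, TruthMaps]:
    dem = generate_dem(config)
    truth = generate_truth(config, dem)
    return render_scene(truth, config), truth


def write_bundle(out_dir: str | Path, config: SceneConfig, n_scenes: int = 1,
                 start_year: int = 1990) -> list[Path]:
    """Render ``n_scenes`` annual scenes sharing one geography to ``out_dir``.

    The DEM, truth, ROI mask/legend and covariates are generated once (ROI
    locations are reused across scenes); each scene gets its own noise draw
    via a per-scene seed offset.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dem = generate_dem(config)
    truth = generate_truth(config, dem)
    rois = make_rois(truth, config)
    write_raster(out / "dem.tif", dem.astype(np.float32))
    from .core import write_class_map  # local import to avoid cycle at top
    write_class_map(out / "truth_class.tif", ClassMap(truth.class_grid))
    write_raster(out / "lai_truth.tif", truth.lai_grid.astype(np.float32))
    write_raster(out / "water_mask.tif", truth.water_mask.astype(np.uint8))
    roi_mask, legend = rois.as_mask(truth.class_grid.shape)
    write_raster(out / "roi_mask.tif", roi_mask)
    legend.to_csv(out / "roi_legend.csv", index=False)
    years = [start_year + k for k in range(n_scenes)]
    write_covariates(out / "covariates.csv",
                     make_covariates(years, seed=config.seed))
    paths = []
    for k, year in enumerate(years):
        cfg_k = config.with_(seed=config.seed + 1000 + k,
                             date=datetime.date(year, 10, 15))
        scene = render_scene(truth, cfg_k)
        p = out / f"scene_{year}.tif"
        write_scene(p, scene)
        paths.append(p)
    return paths
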