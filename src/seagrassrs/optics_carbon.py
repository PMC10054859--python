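"""Water-column optics, LAI retrieval, and the biomass/carbon transfer chain.

The seabed signal in the green band (560 nm) reaching the sensor is modelled
with a single-scattering, two-path water column:

    R_rs = (R_b / pi) * exp(-(K_d + K_Lu) * H)

where R_b is bottom reflectance, H the tide-adjusted water depth (m), K_d the
downwelling and K_Lu the upwelling diffuse attenuation coefficient (1/m) at
560 nm, with K_Lu = K_d / 2*pi when not measured directly.  LAI relates to
bottom reflectance through a log-linear law,

    LAI = a + b * ln(R_b) + c,       b < 0,

whose inverse also drives the scene simulator so that retrieval and forward
model are exact mirrors of each other.  Carbon stocks follow from LAI through
fixed transfer coefficients: 500 g fresh biomass per m^2 of seabed per unit
LAI, dry = 0.2 * fresh, aboveground carbon = 0.34 * dry, and belowground
carbon = 3x the aboveground carbon (root/rhizome dominated meadows).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

logger = logging.getLogger(__name__)

#: grams of fresh aboveground biomass per m^2 seabed per unit LAI
FRESH_PER_LAI = 500.0
#: dry biomass fraction of fresh biomass
DRY_FRACTION = 0.2
#: organic carbon fraction of dry biomass
CARBON_FRACTION = 0.34
#: belowground : aboveground biomass ratio
BG_TO_AG = 3.0
#: exponent cap beyond which R_b retrieval is declared invalid
_MAX_EXPONENT = 50.0


@dataclass(frozen=True)
class OpticsRecord:
    """Attenuation coefficients (1/m at 560 nm) for one acquisition date."""

    kd: float
    klu: float
    date: object | None = None

    def __post_init__(self):
        if not self.kd > 0:
            raise ValueError("kd must be positive")
        if not self.klu > 0:
            raise ValueError("klu must be positive")

    @classmethod
    def from_kd(cls, kd: float, date=None) -> "OpticsRecord":
        return cls(kd=kd, klu=klu_from_kd(kd), date=date)

    @property
    def total_attenuation(self) -> float:
        return self.kd + self.klu


@dataclass(frozen=True)
class LAICoefficients:
    """Log-linear LAI(R_b) law: LAI = a + b*ln(R_b) + c.

    ``c`` is the cross-sensor brightness correction (additive in LAI space);
    it defaults to 0 and is set by :func:`calibrate_offset`.  Defaults map
    LAI in [0, 3] onto R_b in about (0.05, 0.60).
    """

    a: float = -0.61
    b: float = -1.2
    c: float = 0.0

    def __post_init__(self):
        if not self.b < 0:
            raise ValueError("slope b must be negative (brighter bottom = less leaf)")


@dataclass
class LAIGrid:
    """Per-pixel leaf area index (unitless) with a validity mask."""

    lai: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        self.lai = np.asarray(self.lai, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.lai.shape:
            raise ValueError("valid mask shape must match lai")
        if np.any(self.lai[self.valid] < 0):
            raise ValueError("LAI must be >= 0 on valid pixels")

    @property
    def mean(self) -> float:
        if not self.valid.any():
            return float("nan")
        return float(self.lai[self.valid].mean())


@dataclass(frozen=True)
class CarbonSummary:
    """Bay-integrated biomass and carbon stocks (Gg) plus areal BGC density."""

    fresh_biomass: float
    dry_biomass: float
    ag_carbon: float
    bg_carbon: float
    total_carbon: float
    bgc_density: float  # g C m^-2, mean over seagrass pixels

    def __post_init__(self):
        for name in ("fresh_biomass", "dry_biomass", "ag_carbon",
                     "bg_carbon", "total_carbon", "bgc_density"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class CalibrationResult:
    """OLS fit of a reference LAI grid on a target LAI grid."""

    slope: float
    offset: float
    slope_ci: tuple[float, float]
    n: int

    @property
    def slope_compatible_with_unity(self) -> bool:
        lo, hi = self.slope_ci
        return lo <= 1.0 <= hi


# ---------------------------------------------------------------------------
# optics
# ---------------------------------------------------------------------------


def klu_from_kd(kd: float) -> float:
    """Upwelling attenuation from downwelling: K_Lu = K_d / (2*pi)."""
    if not kd > 0:
        raise ValueError("kd must be positive")
    return kd / (2.0 * math.pi)


def tide_adjust(dem: np.ndarray, tide_height: float) -> np.ndarray:
    """Water depth at acquisition time: H = dem + tide, clipped at 0.

    Negative adjusted depths (bottom exposed at low tide) are clipped to 0;
    NaN (land) propagates unchanged.
    """
    dem = np.asarray(dem, dtype=float)
    h = dem + tide_height
    emergent = h < 0
    n_emergent = int(np.nansum(emergent))
    if n_emergent:
        logger.info("tide_adjust: %d pixels emergent at this tide", n_emergent)
    return np.where(emergent, 0.0, h)


def rrs_from_rb(rb, depth, optics: OpticsRecord):
    """Forward water-column model: R_rs = (R_b/pi) * exp(-(K_d+K_Lu)*H)."""
    rb = np.asarray(rb, dtype=float)
    depth = np.asarray(depth, dtype=float)
    return (rb / math.pi) * np.exp(-optics.total_attenuation * depth)


def retrieve_rb(green: np.ndarray, depth: np.ndarray,
                optics: OpticsRecord) -> tuple[np.ndarray, np.ndarray]:
    """Invert the water column: R_b = pi * R_rs * exp((K_d+K_Lu)*H).

    Returns ``(rb, valid)``.  Pixels whose exponent would overflow (extreme
    depth) or whose inputs are non-finite are flagged invalid, with R_b NaN.
    """
    green = np.asarray(green, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if green.shape != depth.shape:
        raise ValueError("green and depth grids must share one shape")
    exponent = optics.total_attenuation * depth
    valid = np.isfinite(green) & np.isfinite(depth) & (green >= 0) & (depth >= 0)
    overflow = valid & (exponent > _MAX_EXPONENT)
    if overflow.any():
        logger.warning("retrieve_rb: %d pixels invalidated (attenuation overflow)",
                       int(overflow.sum()))
    valid &= ~overflow
    rb = np.full(green.shape, np.nan)
    rb[valid] = math.pi * green[valid] * np.exp(exponent[valid])
    return rb, valid


def rb_from_lai(lai, coeffs: LAICoefficients = LAICoefficients()):
    """Inverse of the retrieval law; used as the simulator's forward LAI->R_b."""
    lai = np.asarray(lai, dtype=float)
    return np.exp((lai - coeffs.a - coeffs.c) / coeffs.b)


def invert_lai(rb: np.ndarray, coeffs: LAICoefficients = LAICoefficients(),
               valid: np.ndarray | None = None) -> LAIGrid:
    """LAI = max(a + b*ln(R_b) + c, 0); invalid where R_b <= 0."""
    rb = np.asarray(rb, dtype=float)
    if valid is None:
        valid = np.ones(rb.shape, dtype=bool)
    valid = valid & np.isfinite(rb) & (rb > 0)
    lai = np.zeros(rb.shape, dtype=float)
    lai[valid] = np.maximum(
        coeffs.a + coeffs.b * np.log(rb[valid]) + coeffs.c, 0.0)
    return LAIGrid(lai=lai, valid=valid)


# ---------------------------------------------------------------------------
# cross-sensor calibration
# ---------------------------------------------------------------------------


def calibrate_offset(lai_ref: LAIGrid, lai_target: LAIGrid,
                     min_shared: int = 10) -> CalibrationResult:
    """OLS fit lai_ref = slope * lai_target + offset over shared valid pixels.

    When the slope confidence interval includes 1, the fitted intercept is
    the brightness offset to add to the target sensor's LAIs (additive in LAI
    space, applied via :func:`apply_calibration`).
    """
    if lai_ref.lai.shape != lai_target.lai.shape:
        raise ValueError("LAI grids must be co-registered (same shape)")
    shared = lai_ref.valid & lai_target.valid
    n = int(shared.sum())
    if n < min_shared:
        raise ValueError(f"only {n} shared valid pixels (< {min_shared})")
    y = lai_ref.lai[shared]
    x = sm.add_constant(lai_target.lai[shared])
    fit = sm.OLS(y, x).fit()
    ci = fit.conf_int()
    return CalibrationResult(slope=float(fit.params[1]),
                             offset=float(fit.params[0]),
                             slope_ci=(float(ci[1][0]), float(ci[1][1])),
                             n=n)


def apply_calibration(coeffs: LAICoefficients,
                      cal: CalibrationResult) -> LAICoefficients:
    """Fold the fitted brightness offset into the coefficients' c term.

    Only applied when the slope is statistically compatible with 1; otherwise
    the coefficients are returned unchanged and a warning is logged.
    """
    if not cal.slope_compatible_with_unity:
        logger.warning("calibration slope %.3f CI %s excludes 1; offset not applied",
                       cal.slope, cal.slope_ci)
        return coeffs
    return LAICoefficients(a=coeffs.a, b=coeffs.b, c=coeffs.c + cal.offset)


# ---------------------------------------------------------------------------
# carbon chain
# ---------------------------------------------------------------------------


def _chain(fresh_gg: float, mean_lai: float) -> CarbonSummary:
    dry = fresh_gg * DRY_FRACTION
    ag = dry * CARBON_FRACTION
    bg = ag * BG_TO_AG
    return CarbonSummary(
        fresh_biomass=fresh_gg,
        dry_biomass=dry,
        ag_carbon=ag,
        bg_carbon=bg,
        total_carbon=ag + bg,
        bgc_density=FRESH_PER_LAI * DRY_FRACTION * CARBON_FRACTION * BG_TO_AG
        * mean_lai,
    )


def carbon_summary(lai: LAIGrid, pixel_size: float = 30.0) -> CarbonSummary:
    """Integrate the transfer chain over a LAI grid.

    Per-pixel fresh density is 500*LAI g m^-2; totals integrate over the
    pixel area (pixel_size^2 m^2) and convert grams to gigagrams (1e-9).
    """
    if np.any(lai.lai[lai.valid] < 0):
        raise ValueError("negative LAI; clip upstream")
    area_m2 = pixel_size ** 2
    fresh_g = float(np.sum(FRESH_PER_LAI * lai.lai[lai.valid]) * area_m2)
    mean_lai = lai.mean if lai.valid.any() else 0.0
    return _chain(fresh_g * 1e-9, mean_lai)


def carbon_summary_from_mean(mean_lai: float, area_km2: float) -> CarbonSummary:
    """Bay-scale arithmetic from a mean LAI and a total seagrass area."""
    if mean_lai < 0 or area_km2 < 0:
        raise ValueError("mean LAI and area must be non-negative")
    fresh_g = FRESH_PER_LAI * mean_lai * area_km2 * 1e6
    return _chain(fresh_g * 1e-9, mean_lai)
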