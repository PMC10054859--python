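"""Trend statistics for annual seagrass series and per-pixel frequency maps.

The centre piece is the seasonal Mann-Kendall test: the concordance statistic
S is accumulated within each season block and summed, with a tie-corrected
variance and a continuity-corrected two-sided normal p-value; a single season
reduces to the ordinary Mann-Kendall test, and an exact permutation p-value
is available for small n.  The companion slope estimator is the (seasonal)
Theil-Sen median of within-season pairwise slopes.  Trend detectability is
summarised by the gamma statistic — the number of years needed for a trend of
the estimated magnitude to emerge from the series' noise and lag-1
autocorrelation:

    gamma = [ (3.3 * sigma_N / |slope|) * sqrt((1 + phi) / (1 - phi)) ]^(2/3)

with sigma_N the residual standard deviation about the Sen line and phi the
lag-1 autocorrelation of those residuals; it is undefined when the slope is 0.

Tau strength is read on conventional correlation thresholds: |tau| >= 0.5
strong, >= 0.3 moderate, >= 0.1 weak, below that none.

Climate attribution is an ordinary least-squares multiple regression of a
metric on the ENSO and NAO indices (optionally other covariates), reported
with per-coefficient t and p and the adjusted r^2.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import SEAGRASS, ClassMap

logger = logging.getLogger(__name__)

STRENGTH_STRONG = 0.5
STRENGTH_MODERATE = 0.3
STRENGTH_WEAK = 0.1


@dataclass
class AnnualSeries:
    """One metric observed once per (year, season)."""

    years: np.ndarray
    values: np.ndarray
    seasons: np.ndarray | None = None
    name: str = "metric"

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.seasons is None:
            self.seasons = np.zeros(len(self.years), dtype=object)
        self.seasons = np.asarray(self.seasons, dtype=object)
        if not (len(self.years) == len(self.values) == len(self.seasons)):
            raise ValueError("years, values, seasons must align")
        for s in np.unique(self.seasons):
            yr = self.years[self.seasons == s]
            if len(np.unique(yr)) != len(yr):
                logger.warning("duplicate years within season %r", s)

    def __len__(self) -> int:
        return len(self.years)

    def groups(self):
        for s in pd.unique(self.seasons):
            sel = self.seasons == s
            order = np.argsort(self.years[sel], kind="stable")
            yield s, self.years[sel][order], self.values[sel][order]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, value_col: str,
                   year_col: str = "year",
                   season_col: str | None = "season") -> "AnnualSeries":
        seasons = df[season_col].to_numpy() if season_col and season_col in df \
            else None
        return cls(df[year_col].to_numpy(), df[value_col].to_numpy(),
                   seasons, name=value_col)


@dataclass(frozen=True)
class TrendResult:
    """Full trend summary for one annual series."""

    n: int
    tau: float
    p_value: float
    sen_slope: float
    percent_change_per_year: float
    gamma_years: float  # NaN when undefined (slope == 0)
    strength_label: str


@dataclass(frozen=True)
class MKResult:
    tau: float
    p_value: float
    s: int
    var_s: float


@dataclass(frozen=True)
class MLRResult:
    """OLS regression of a metric on climate covariates."""

    predictors: tuple[str, ...]
    beta: dict
    t: dict
    p: dict
    intercept: float
    adjusted_r2: float
    n: int


@dataclass
class FrequencyGrid:
    """Per-pixel fraction of scenes in which seagrass was present."""

    frequency: np.ndarray  # in [0,1], NaN where never valid
    n_scenes: int

    def __post_init__(self):
        vals = self.frequency[np.isfinite(self.frequency)]
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("frequency must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Mann-Kendall
# ---------------------------------------------------------------------------


def _mk_s_var(values: np.ndarray) -> tuple[int, float, int]:
    """S, tie-corrected Var(S) and the pair count for one season block."""
    n = len(values)
    s = 0
    for i, j in itertools.combinations(range(n), 2):
        s += int(np.sign(values[j] - values[i]))
    var = n * (n - 1) * (2 * n + 5) / 18.0
    _, tie_counts = np.unique(values, return_counts=True)
    for t in tie_counts[tie_counts > 1]:
        var -= t * (t - 1) * (2 * t + 5) / 18.0
    return s, var, n * (n - 1) // 2


def mann_kendall(series: AnnualSeries, method: str = "normal") -> MKResult:
    """(Seasonal) Mann-Kendall test for a monotonic trend.

    S and its tie-corrected variance accumulate over season blocks; tau is
    S over the total number of within-season pairs.  ``method='normal'``
    gives the continuity-corrected two-sided normal p; ``method='exact'``
    (single season, n <= 9) enumerates the permutation distribution of S.
    An all-tied series returns tau 0, p 1 with a warning.
    """
    s_total, var_total, pairs = 0, 0.0, 0
    blocks = []
    for _, _, vals in series.groups():
        if len(vals) < 2:
            continue
        s, var, d = _mk_s_var(vals)
        s_total += s
        var_total += var
        pairs += d
        blocks.append(vals)
    if pairs == 0:
        raise ValueError("need at least one season with >= 2 observations")
    tau = s_total / pairs
    if var_total == 0:
        logger.warning("mann_kendall: all values tied; no trend information")
        return MKResult(tau=0.0, p_value=1.0, s=s_total, var_s=0.0)
    if method == "exact":
        if len(blocks) != 1 or len(blocks[0]) > 9:
            raise ValueError("exact p available for a single season with n <= 9")
        p = _mk_exact_p(blocks[0], s_total)
    elif method == "normal":
        if s_total > 0:
            z = (s_total - 1) / math.sqrt(var_total)
        elif s_total < 0:
            z = (s_total + 1) / math.sqrt(var_total)
        else:
            z = 0.0
        p = 2.0 * stats.norm.sf(abs(z))
    else:
        raise ValueError(f"unknown method {method!r}")
    return MKResult(tau=tau, p_value=float(p), s=s_total, var_s=var_total)


def _mk_exact_p(values: np.ndarray, s_obs: int) -> float:
    """Two-sided permutation p: P(|S| >= |S_obs|) over all value orderings."""
    hits = total = 0
    for perm in itertools.permutations(values):
        s, _, _ = _mk_s_var(np.asarray(perm))
        total += 1
        if abs(s) >= abs(s_obs):
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# slope, change rate, detectability
# ---------------------------------------------------------------------------


def theil_sen(series: AnnualSeries) -> float:
    """Median of within-season pairwise slopes; duplicate-year pairs skipped."""
    slopes = []
    for _, years, vals in series.groups():
        for i, j in itertools.combinations(range(len(vals)), 2):
            dy = years[j] - years[i]
            if dy == 0:
                continue
            slopes.append((vals[j] - vals[i]) / dy)
    if not slopes:
        raise ValueError("no valid pairs for slope estimation")
    return float(np.median(slopes))


def percent_change(slope: float, series: AnnualSeries) -> float:
    """Percent change per year: 100 * slope / mean(series)."""
    mean = float(np.mean(series.values))
    if mean == 0:
        logger.warning("percent_change undefined: series mean is 0")
        return float("nan")
    return 100.0 * slope / mean


def percent_decline(before: float, after: float) -> float:
    """Percent change between two extents: 100 * (before - after) / before."""
    if before == 0:
        raise ValueError("undefined for a zero baseline")
    return 100.0 * (before - after) / before


#: default detectability factor (approx. z_{0.975} + z_{0.90} for the
#: conventional noise-to-trend formulation)
GAMMA_FACTOR = 3.3


def gamma_from_parameters(sigma: float, phi: float, slope: float,
                          factor: float = GAMMA_FACTOR) -> float:
    """Closed-form detectability horizon at fixed noise and autocorrelation."""
    if slope == 0:
        return float("nan")
    if sigma == 0:
        return 0.0  # a noiseless trend is detectable immediately
    phi = min(max(phi, -0.99), 0.99)
    base = (factor * sigma / abs(slope)) * math.sqrt((1 + phi) / (1 - phi))
    return base ** (2.0 / 3.0)


def gamma_years(series: AnnualSeries, slope: float,
                factor: float = GAMMA_FACTOR) -> float:
    """Years of record needed for the trend to overcome series variability.

    Residuals are taken about the Sen line (median intercept); sigma_N is
    their standard deviation and phi their lag-1 autocorrelation in time
    order.  Returns NaN when the slope is exactly 0 (no trend to detect).
    The ``factor`` multiplying the noise-to-trend ratio is exposed because
    conventions differ with the sampling cadence the noise estimate refers
    to; the default matches the monthly-cadence literature form.
    """
    if len(series) < 4:
        raise ValueError("need n >= 4")
    if slope == 0:
        return float("nan")
    order = np.argsort(series.years, kind="stable")
    years = series.years[order]
    values = series.values[order]
    intercept = float(np.median(values - slope * years))
    resid = values - (intercept + slope * years)
    sigma = float(np.std(resid, ddof=1))
    r = resid - resid.mean()
    denom = float(np.sum(r * r))
    phi = float(np.sum(r[1:] * r[:-1]) / denom) if denom > 0 else 0.0
    return gamma_from_parameters(sigma, phi, slope, factor=factor)


def strength_label(tau: float) -> str:
    """Label |tau| as none / weak / moderate / strong."""
    if not -1.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [-1, 1]")
    a = abs(tau)
    if a >= STRENGTH_STRONG:
        return "strong"
    if a >= STRENGTH_MODERATE:
        return "moderate"
    if a >= STRENGTH_WEAK:
        return "weak"
    return "none"


def trend_summary(series: AnnualSeries) -> TrendResult:
    """The full per-series trend row: tau, p, slope, %change, gamma, label."""
    mk = mann_kendall(series)
    slope = theil_sen(series)
    return TrendResult(
        n=len(series), tau=mk.tau, p_value=mk.p_value, sen_slope=slope,
        percent_change_per_year=percent_change(slope, series),
        gamma_years=gamma_years(series, slope),
        strength_label=strength_label(mk.tau),
    )


# ---------------------------------------------------------------------------
# frequency map
# ---------------------------------------------------------------------------


def frequency_map(classmaps: list[ClassMap]) -> FrequencyGrid:
    """Per pixel: seagrass scene count over valid scene count.

    Masked scenes drop out of both numerator and denominator at that pixel;
    pixels valid in no scene are NaN.
    """
    if not classmaps:
        raise ValueError("empty class map stack")
    shape = classmaps[0].shape
    num = np.zeros(shape)
    den = np.zeros(shape)
    for cm in classmaps:
        if cm.shape != shape:
            raise ValueError("class maps must be co-registered")
        valid = ~cm.mask
        num += valid & (cm.labels == SEAGRASS)
        den += valid
    freq = np.full(shape, np.nan)
    ok = den > 0
    freq[ok] = num[ok] / den[ok]
    return FrequencyGrid(frequency=freq, n_scenes=len(classmaps))


# ---------------------------------------------------------------------------
# climate-driver regression
# ---------------------------------------------------------------------------


def mlr_drivers(series: AnnualSeries, covariates: pd.DataFrame,
                predictors: tuple[str, ...] = ("enso", "nao")) -> MLRResult:
    """OLS of the metric on intercept + climate predictors, matched on year."""
    df = covariates.set_index("year")
    try:
        x = df.loc[series.years, list(predictors)].to_numpy(dtype=float)
    except KeyError as exc:
        raise ValueError(f"covariates missing required rows/columns: {exc}")
    y = series.values
    n, k = x.shape
    if n <= k + 1:
        raise ValueError("need n > number of predictors + 1")
    design = sm.add_constant(x)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        culprits = [p for i, p in enumerate(predictors)
                    if np.linalg.matrix_rank(np.delete(design, i + 1, axis=1))
                    == np.linalg.matrix_rank(design)]
        raise ValueError(f"rank-deficient design; collinear columns: {culprits}")
    fit = sm.OLS(y, design).fit()
    return MLRResult(
        predictors=tuple(predictors),
        beta={p: float(fit.params[i + 1]) for i, p in enumerate(predictors)},
        t={p: float(fit.tvalues[i + 1]) for i, p in enumerate(predictors)},
        p={p: float(fit.pvalues[i + 1]) for i, p in enumerate(predictors)},
        intercept=float(fit.params[0]),
        adjusted_r2=float(fit.rsquared_adj),
        n=n,
    )
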