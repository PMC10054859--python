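"""Presence/absence map comparison: confusion counts, kappa, McNemar.

Two co-registered classifications are reduced to seagrass presence/absence
and compared over their co-valid pixels.  The report carries precision,
recall and F-measure for both the presence and the absence class, the
overall accuracy, and Cohen's kappa (chance-corrected agreement, -1 perfect
disagreement to 1 perfect agreement).  Paired disagreement is tested with
McNemar's chi^2 = (b - c)^2 / (b + c) on the discordant counts (continuity
correction available behind a flag).  Ratios with zero denominators are
reported as NaN rather than 0 so tables cannot silently inflate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import SEAGRASS, ClassMap


@dataclass
class PresenceGrid:
    """Binary seagrass presence with a validity mask."""

    presence: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        self.presence = np.asarray(self.presence, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.presence.shape != self.valid.shape:
            raise ValueError("presence and valid grids must share one shape")


@dataclass(frozen=True)
class ConfusionTable:
    """Paired 2x2 counts: a both present, b A-only, c B-only, d both absent."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def swapped(self) -> "ConfusionTable":
        """The table with the two maps exchanged (b and c swap)."""
        return ConfusionTable(a=self.a, b=self.c, c=self.b, d=self.d)


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f_measure: float


@dataclass(frozen=True)
class AgreementReport:
    presence: ClassMetrics
    absence: ClassMetrics
    overall_accuracy: float
    kappa: float


@dataclass(frozen=True)
class McNemarResult:
    chi_square: float
    p_value: float
    b: int
    c: int


# ---------------------------------------------------------------------------


def binarize(cmap: ClassMap) -> PresenceGrid:
    """Seagrass -> present; every other unmasked class -> absent."""
    return PresenceGrid(presence=(cmap.labels == SEAGRASS) & ~cmap.mask,
                        valid=~cmap.mask)


def confusion(map_a: PresenceGrid, map_b: PresenceGrid) -> ConfusionTable:
    """2x2 counts over pixels valid in both maps."""
    if map_a.presence.shape != map_b.presence.shape:
        raise ValueError("maps must be co-registered")
    ok = map_a.valid & map_b.valid
    pa, pb = map_a.presence[ok], map_b.presence[ok]
    return ConfusionTable(a=int(np.sum(pa & pb)),
                          b=int(np.sum(pa & ~pb)),
                          c=int(np.sum(~pa & pb)),
                          d=int(np.sum(~pa & ~pb)))


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; NaN when both are 0/undefined."""
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        return float("nan")
    return 2.0 * precision * recall / (precision + recall)


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def report(conf: ConfusionTable) -> AgreementReport:
    """Precision/recall/F per class, overall accuracy and Cohen's kappa.

    Presence precision a/(a+b) and recall a/(a+c) treat map A as the
    classification and map B as the reference; absence metrics mirror them
    on d.  Kappa compares observed agreement p_o = (a+d)/n with the chance
    agreement p_e from the marginal products.
    """
    if conf.n == 0:
        raise ValueError("empty confusion table")
    a, b, c, d, n = conf.a, conf.b, conf.c, conf.d, conf.n
    pres = ClassMetrics(precision=_ratio(a, a + b), recall=_ratio(a, a + c),
                        f_measure=f_measure(_ratio(a, a + b), _ratio(a, a + c)))
    abs_ = ClassMetrics(precision=_ratio(d, d + c), recall=_ratio(d, d + b),
                        f_measure=f_measure(_ratio(d, d + c), _ratio(d, d + b)))
    p_o = (a + d) / n
    p_e = ((a + b) * (a + c) + (c + d) * (b + d)) / (n * n)
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e != 1.0 else float("nan")
    return AgreementReport(presence=pres, absence=abs_,
                           overall_accuracy=p_o, kappa=kappa)


def mcnemar(conf: ConfusionTable, continuity_correction: bool = False) -> McNemarResult:
    """McNemar's test on the discordant cells.

    chi^2 = (b - c)^2 / (b + c) (or (|b - c| - 1)^2 / (b + c) with the
    continuity correction), p from chi^2 with 1 df.
    """
    b, c = conf.b, conf.c
    if b + c == 0:
        raise ValueError("no discordant pixels; McNemar undefined")
    diff = abs(b - c) - 1 if continuity_correction else b - c
    diff = max(diff, 0) if continuity_correction else diff
    chi2 = diff ** 2 / (b + c)
    p = float(stats.chi2.sf(chi2, df=1))
    return McNemarResult(chi_square=float(chi2), p_value=p, b=b, c=c)


# difference-map codes
BOTH_ABSENT = 0
A_ONLY = 1
B_ONLY = 2
BOTH_PRESENT = 3
INVALID = 255


def difference_map(map_a: PresenceGrid, map_b: PresenceGrid) -> np.ndarray:
    """Coded agreement grid: both-absent 0, A-only 1, B-only 2, both 3.

    Pixels not co-valid carry :data:`INVALID`.  Code counts equal the
    confusion-table cells by construction.
    """
    if map_a.presence.shape != map_b.presence.shape:
        raise ValueError("maps must be co-registered")
    out = np.full(map_a.presence.shape, INVALID, dtype=np.uint8)
    ok = map_a.valid & map_b.valid
    pa, pb = map_a.presence, map_b.presence
    out[ok & pa & pb] = BOTH_PRESENT
    out[ok & pa & ~pb] = A_ONLY
    out[ok & ~pa & pb] = B_ONLY
    out[ok & ~pa & ~pb] = BOTH_ABSENT
    return out
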