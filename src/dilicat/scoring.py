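"""IQR-band scoring of injury cases against a drug phenotype.

Each of the three case parameters is classified into a band relative to
the phenotype's percentile profile and converted to a percentage of the
parameter's maximum points:

====================  =========================================  ==========
band                  location                                   percentage
====================  =========================================  ==========
IQR                   within [Q1, Q3]                            100
P15_25                [P15, Q1) or (Q3, P85]                      50
P10_15                [P10, P15) or (P85, P90]                    25
TAIL_IN_RANGE         inside the range, beyond P10/P90             0
OUT_OF_RANGE          outside the observed range, within fences  -25
OUTLIER               inside the range but beyond a fence        -25
OUT_AND_OUTLIER       outside the range AND beyond a fence       -50
====================  =========================================  ==========

Standard parameters carry a 20-point maximum; the single *weighted*
parameter — the one most discriminating between drug and comparator —
carries 40.  Totals therefore lie in [-40, 80].

Band edges: IQR endpoints belong to the IQR (100 %); the outer edge of
each percentile band belongs to the band nearer the median; range
endpoints count as in-range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

from .phenotype import PARAMETERS, CaseFeatures, DiliPhenotype, PercentileProfile

__all__ = [
    "Band",
    "BandClassification",
    "WeightScheme",
    "ParameterScore",
    "CaseScore",
    "classify",
    "score_case",
    "score_cohort",
]


class Band(str, Enum):
    IQR = "IQR"
    P15_25 = "P15_25"
    P10_15 = "P10_15"
    TAIL_IN_RANGE = "TAIL_IN_RANGE"
    OUT_OF_RANGE = "OUT_OF_RANGE"
    OUTLIER = "OUTLIER"
    OUT_AND_OUTLIER = "OUT_AND_OUTLIER"


#: Fixed band -> percentage-of-points mapping.
BAND_PERCENTAGE = {
    Band.IQR: 100,
    Band.P15_25: 50,
    Band.P10_15: 25,
    Band.TAIL_IN_RANGE: 0,
    Band.OUT_OF_RANGE: -25,
    Band.OUTLIER: -25,
    Band.OUT_AND_OUTLIER: -50,
}


@dataclass(frozen=True)
class BandClassification:
    band: Band
    percentage: int


@dataclass(frozen=True)
class WeightScheme:
    """Which parameter is doubled, and the point maxima."""

    weighted_parameter: str
    standard_max: int = 20
    weighted_max: int = 40
    reason: str = ""

    def __post_init__(self) -> None:
        if self.weighted_parameter not in PARAMETERS:
            raise ValueError(f"unknown weighted parameter {self.weighted_parameter!r}")

    def max_points(self, parameter: str) -> int:
        return self.weighted_max if parameter == self.weighted_parameter else self.standard_max


@dataclass(frozen=True)
class ParameterScore:
    value: float
    band: Band
    percentage: int
    points: float
    weighted: bool = False


@dataclass(frozen=True)
class CaseScore:
    case_id: str
    arm: Optional[str]
    parameters: dict = field(default_factory=dict)  # name -> ParameterScore

    @property
    def total(self) -> float:
        return sum(p.points for p in self.parameters.values())


def classify(value: float, profile: PercentileProfile) -> BandClassification:
    """Classify one parameter value against a percentile profile.

    Precedence: outside the observed range *and* beyond a fence scores
    -50 %; outside the range only, or inside the range but beyond a
    fence, scores -25 %; otherwise the percentile band applies.
    """
    if value is None or not math.isfinite(value):
        raise ValueError(f"cannot classify non-finite value {value!r}")
    in_range = profile.range_min <= value <= profile.range_max
    beyond_fence = value < profile.fence_low or value > profile.fence_high

    if not in_range and beyond_fence:
        band = Band.OUT_AND_OUTLIER
    elif not in_range:
        band = Band.OUT_OF_RANGE
    elif beyond_fence:
        band = Band.OUTLIER
    elif profile.q25 <= value <= profile.q75:
        band = Band.IQR
    elif profile.q15 <= value < profile.q25 or profile.q75 < value <= profile.q85:
        band = Band.P15_25
    elif profile.q10 <= value < profile.q15 or profile.q85 < value <= profile.q90:
        band = Band.P10_15
    else:
        band = Band.TAIL_IN_RANGE
    return BandClassification(band=band, percentage=BAND_PERCENTAGE[band])


def _points(percentage: int, max_points: int) -> float:
    raw = percentage * max_points
    return raw // 100 if raw % 100 == 0 else raw / 100


def score_case(
    case: CaseFeatures,
    phenotype: DiliPhenotype,
    weights: WeightScheme,
    table_outlier_compat: bool = False,
) -> CaseScore:
    """Score a complete case against a phenotype.

    Every parameter contributes ``percentage * max_points / 100`` where
    the maximum is 40 for the weighted parameter and 20 otherwise.
    """
    missing = [p for p in PARAMETERS if getattr(case, p) is None]
    if missing:
        raise ValueError(f"case {case.case_id!r} missing parameter(s) {missing}; scoring requires a complete triple")
    params: dict[str, ParameterScore] = {}
    for name in PARAMETERS:
        value = getattr(case, name)
        cls = classify(value, phenotype.profile(name))
        maxpts = weights.max_points(name)
        if table_outlier_compat and cls.band is Band.OUTLIER:
            pts: float = -10  # legacy fixed deduction, irrespective of weighting
        else:
            pts = _points(cls.percentage, maxpts)
        params[name] = ParameterScore(
            value=value,
            band=cls.band,
            percentage=cls.percentage,
            points=pts,
            weighted=(name == weights.weighted_parameter),
        )
    return CaseScore(case_id=case.case_id, arm=case.arm, parameters=params)


def score_cohort(
    cases: Iterable[CaseFeatures],
    phenotype: DiliPhenotype,
    weights: WeightScheme,
    table_outlier_compat: bool = False,
) -> list[CaseScore]:
    """Score a cohort case by case, preserving input order."""
    out = []
    for case in cases:
        try:
            out.append(score_case(case, phenotype, weights, table_outlier_compat))
        except ValueError as exc:
            raise ValueError(f"while scoring case {case.case_id!r}: {exc}") from exc
    return out
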