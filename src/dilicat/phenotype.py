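"""Drug-specific DILI phenotypes: per-parameter percentile profiles.

A drug's liver-injury phenotype is the empirical distribution of three
onset parameters over its accrued injury cases:

* **latency** — days from first dose to the qualifying liver-test
  elevation,
* **R-value** — (ALT in xULN) / (ALP in xULN) at onset (high =
  hepatocellular, low = cholestatic),
* **AST/ALT ratio** — the de Ritis ratio at onset.

Each parameter is summarised by a :class:`PercentileProfile` (median,
quartiles, 10/15/85/90th percentile cuts, observed range, and asymmetric
outlier fences).  Phenotypes are refined iteratively as new cases accrue
by rebuilding over the union of case sets.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence

import numpy as np

from .quantiles import DIALECTS, outlier_fences, percentile

__all__ = [
    "PARAMETERS",
    "CaseFeatures",
    "PercentileProfile",
    "DiliPhenotype",
    "build_phenotype",
    "refine_phenotype",
]

#: Phenotype parameters, in canonical order.
PARAMETERS = ("latency_days", "r_value", "ast_alt_ratio")

#: Default minimum number of cases required to build a phenotype.
DEFAULT_MIN_CASES = 5


@dataclass(frozen=True)
class CaseFeatures:
    """One liver-injury case reduced to its three phenotype parameters.

    A parameter may be ``None`` when it could not be derived (e.g. no
    same-day ALP for the R-value); such a case is excluded from that
    parameter's profile but may still contribute to the others.  Scoring
    a case, by contrast, requires the complete triple.
    """

    case_id: str
    drug: str
    latency_days: Optional[float] = None
    r_value: Optional[float] = None
    ast_alt_ratio: Optional[float] = None
    arm: Optional[str] = None  # "drug" / "comparator" where relevant

    def __post_init__(self) -> None:
        for name in PARAMETERS:
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(
                    f"case {self.case_id!r}: {name} must be positive when present, got {v}"
                )

    def is_complete(self) -> bool:
        return all(getattr(self, p) is not None for p in PARAMETERS)


@dataclass(frozen=True)
class PercentileProfile:
    """Percentile summary of one phenotype parameter.

    Invariants: the quantile chain q10 <= q15 <= q25 <= median <= q75 <=
    q85 <= q90 is monotone and bracketed by the observed range; fences
    follow the asymmetric IQR rule.
    """

    median: float
    q10: float
    q15: float
    q25: float
    q75: float
    q85: float
    q90: float
    range_min: float
    range_max: float
    fence_low: float
    fence_high: float
    n_cases: int
    quantile_dialect: str

    def __post_init__(self) -> None:
        chain = (self.q10, self.q15, self.q25, self.median, self.q75, self.q85, self.q90)
        if any(b < a for a, b in zip(chain, chain[1:])):
            raise ValueError(f"non-monotone quantile chain: {chain}")
        if self.range_min > self.q10 or self.q90 > self.range_max:
            raise ValueError("quantile chain escapes the observed range")

    @classmethod
    def from_values(cls, values: Sequence[float], dialect: str = "inclusive") -> "PercentileProfile":
        """Build a profile from raw parameter values."""
        arr = np.asarray(list(values), dtype=float)
        if arr.size < 2:
            raise ValueError("at least two values are required for a percentile profile")
        q = {p: percentile(arr, p, dialect) for p in (0.10, 0.15, 0.25, 0.50, 0.75, 0.85, 0.90)}
        low, high = outlier_fences(q[0.25], q[0.75])
        return cls(
            median=q[0.50],
            q10=q[0.10],
            q15=q[0.15],
            q25=q[0.25],
            q75=q[0.75],
            q85=q[0.85],
            q90=q[0.90],
            range_min=float(arr.min()),
            range_max=float(arr.max()),
            fence_low=low,
            fence_high=high,
            n_cases=int(arr.size),
            quantile_dialect=dialect,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PercentileProfile":
        expected = set(cls.__dataclass_fields__)
        found = set(d)
        if expected != found:
            raise ValueError(
                f"percentile profile schema mismatch: expected keys {sorted(expected)}, found {sorted(found)}"
            )
        if d["quantile_dialect"] not in DIALECTS:
            raise ValueError(f"unknown quantile dialect {d['quantile_dialect']!r}")
        return cls(**d)


@dataclass(frozen=True)
class DiliPhenotype:
    """A drug's DILI phenotype: one percentile profile per parameter."""

    drug: str
    version_tag: str
    latency_days: PercentileProfile
    r_value: PercentileProfile
    ast_alt_ratio: PercentileProfile
    quantile_dialect: str
    source_case_ids: tuple = field(default_factory=tuple)

    def profile(self, parameter: str) -> PercentileProfile:
        if parameter not in PARAMETERS:
            raise KeyError(f"unknown phenotype parameter {parameter!r}")
        return getattr(self, parameter)

    @property
    def n_cases(self) -> int:
        return len(self.source_case_ids)

    def to_dict(self) -> dict:
        return {
            "drug": self.drug,
            "version_tag": self.version_tag,
            "quantile_dialect": self.quantile_dialect,
            "source_case_ids": list(self.source_case_ids),
            "profiles": {p: self.profile(p).to_dict() for p in PARAMETERS},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiliPhenotype":
        expected = {"drug", "version_tag", "quantile_dialect", "source_case_ids", "profiles"}
        if set(d) != expected:
            raise ValueError(
                f"phenotype schema mismatch: expected keys {sorted(expected)}, found {sorted(d)}"
            )
        if d["quantile_dialect"] not in DIALECTS:
            raise ValueError(f"unknown quantile dialect {d['quantile_dialect']!r}")
        profiles = {p: PercentileProfile.from_dict(d["profiles"][p]) for p in PARAMETERS}
        return cls(
            drug=d["drug"],
            version_tag=d["version_tag"],
            quantile_dialect=d["quantile_dialect"],
            source_case_ids=tuple(d["source_case_ids"]),
            **profiles,
        )


def build_phenotype(
    cases: Iterable[CaseFeatures],
    drug: Optional[str] = None,
    dialect: str = "inclusive",
    min_cases: int = DEFAULT_MIN_CASES,
    force: bool = False,
    version_tag: str = "v1",
) -> DiliPhenotype:
    """Build a drug phenotype from a set of same-drug injury cases.

    Parameters
    ----------
    cases
        The drug's accrued injury cases.  Cases missing a parameter are
        excluded from that parameter's profile (with a warning).
    drug
        Drug name; inferred from the cases when omitted.  All cases must
        carry the same drug.
    dialect
        Quantile interpolation dialect for every profile.
    min_cases
        Minimum case count; below it an error is raised unless
        ``force=True`` (then a warning is emitted).
    """
    case_list = list(cases)
    if not case_list:
        raise ValueError("cannot build a phenotype from zero cases")
    drugs = {c.drug for c in case_list}
    if drug is None:
        if len(drugs) > 1:
            raise ValueError(f"cases span multiple drugs: {sorted(drugs)}")
        drug = next(iter(drugs))
    elif drugs - {drug}:
        raise ValueError(f"cases for {sorted(drugs - {drug})} mixed into {drug!r} phenotype")
    ids = [c.case_id for c in case_list]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate case ids in phenotype input")
    if len(case_list) < min_cases:
        msg = f"only {len(case_list)} case(s) for {drug!r}; minimum is {min_cases}"
        if not force:
            raise ValueError(msg)
        warnings.warn(msg + " (forced)", stacklevel=2)

    profiles = {}
    for param in PARAMETERS:
        values = [getattr(c, param) for c in case_list]
        present = [v for v in values if v is not None]
        if len(present) < len(values):
            missing = [c.case_id for c in case_list if getattr(c, param) is None]
            warnings.warn(
                f"{param}: case(s) {missing} lack a value and are excluded from this profile",
                stacklevel=2,
            )
        profiles[param] = PercentileProfile.from_values(present, dialect)

    return DiliPhenotype(
        drug=drug,
        version_tag=version_tag,
        quantile_dialect=dialect,
        source_case_ids=tuple(sorted(ids)),
        **profiles,
    )


def _bump_version(tag: str) -> str:
    m = re.fullmatch(r"v(\d+)", tag)
    return f"v{int(m.group(1)) + 1}" if m else tag + "+1"


def refine_phenotype(
    old_cases: Iterable[CaseFeatures],
    new_cases: Iterable[CaseFeatures],
    drug: Optional[str] = None,
    dialect: str = "inclusive",
    min_cases: int = DEFAULT_MIN_CASES,
    force: bool = False,
    base_version: str = "v1",
) -> DiliPhenotype:
    """Merge a new batch of cases into an existing case set and rebuild.

    Statistic-by-statistic the result equals :func:`build_phenotype` on
    the union — refinement is order-independent and path-independent.
    """
    old_list, new_list = list(old_cases), list(new_cases)
    overlap = {c.case_id for c in old_list} & {c.case_id for c in new_list}
    if overlap:
        raise ValueError(f"duplicate case ids between old and new sets: {sorted(overlap)}")
    return build_phenotype(
        old_list + new_list,
        drug=drug,
        dialect=dialect,
        min_cases=min_cases,
        force=force,
        version_tag=_bump_version(base_version),
    )
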