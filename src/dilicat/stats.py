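"""Statistical procedures for phenotype comparison.

Three tests drive the method's decision rules:

* a tie-corrected asymptotic **Mann-Whitney** rank test comparing the
  raw parameter values (or IQR distances) of drug vs comparator cases —
  U = 0 signals completely non-overlapping distributions;
* the **Mantel-Haenszel linear-by-linear trend test** on total scores,
  chi-square = (N - 1) * r^2 with 1 df where r is the Pearson
  correlation of the binary arm indicator with the score — sensitive to
  the magnitude of the ordinal scores, not just their sign;
* a **Pearson chi-square** (no continuity correction) on 2x2 incidence
  tables of liver events per arm.

The weighted-parameter selection rule picks the parameter with the
smallest Mann-Whitney p-value (rounded to three decimals, ties broken by
the smaller U); latency is the a-priori default when no comparator data
exist or no parameter reaches significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .phenotype import PARAMETERS, CaseFeatures
from .scoring import WeightScheme

__all__ = [
    "RankTestResult",
    "TrendTestResult",
    "ContingencyResult",
    "mann_whitney",
    "mantel_haenszel_trend",
    "chi_square_2x2",
    "select_weighted_parameter",
    "iqr_distance",
]


class StatisticalError(ValueError):
    """A statistical precondition failed (empty group, zero margin...)."""


@dataclass(frozen=True)
class RankTestResult:
    u: float  # min(U, U') — 0 means no overlap between the groups
    u_other: float
    z: float
    p_two_sided: float
    tie_correction_applied: bool
    n1: int
    n2: int


@dataclass(frozen=True)
class TrendTestResult:
    chi_square: float
    df: int
    p: float
    n: int


@dataclass(frozen=True)
class ContingencyResult:
    chi_square: float
    df: int
    p: float


def mann_whitney(group_a: Iterable[float], group_b: Iterable[float]) -> RankTestResult:
    """Tie-corrected asymptotic Mann-Whitney rank test, two-sided.

    Midranks are assigned to ties; U is derived from the rank sum of
    group a; z uses the tie-corrected variance

        sigma^2 = (n1 n2 / 12) * [(N + 1) - sum(t^3 - t) / (N (N - 1))]

    with no continuity correction, and the p-value comes from the normal
    approximation.  The reported ``u`` is min(U, U'); a value of zero
    means the two samples do not overlap at all.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatisticalError("both groups must be non-empty for the Mann-Whitney test")
    n1, n2 = a.size, b.size
    n = n1 + n2
    ranks = sps.rankdata(np.concatenate([a, b]))  # midranks for ties
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1

    _, counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = float(((counts**3 - counts).sum()))
    has_ties = tie_term > 0
    sigma_sq = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    mu = n1 * n2 / 2.0
    if sigma_sq <= 0:
        warnings.warn("all values identical across both groups; p set to 1", stacklevel=2)
        z, p = 0.0, 1.0
    else:
        z = (u1 - mu) / np.sqrt(sigma_sq)
        p = 2.0 * sps.norm.sf(abs(z))
    return RankTestResult(
        u=float(min(u1, u2)),
        u_other=float(max(u1, u2)),
        z=float(z),
        p_two_sided=float(min(p, 1.0)),
        tie_correction_applied=has_ties,
        n1=int(n1),
        n2=int(n2),
    )


def mantel_haenszel_trend(group_labels: Sequence, scores: Iterable[float]) -> TrendTestResult:
    """Linear-by-linear association test: chi-square = (N - 1) r^2, 1 df."""
    y = np.asarray(list(scores), dtype=float)
    labels = list(group_labels)
    if len(labels) != y.size:
        raise StatisticalError("labels and scores must have equal length")
    uniq = sorted(set(labels), key=str)
    if len(uniq) != 2:
        raise StatisticalError(f"exactly two group labels required, got {uniq}")
    x = np.asarray([uniq.index(g) for g in labels], dtype=float)
    n = y.size
    if n < 3:
        raise StatisticalError("at least three observations required for the trend test")
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        raise StatisticalError("correlation undefined: scores or labels are constant")
    r = np.corrcoef(x, y)[0, 1]
    chi = (n - 1) * r**2
    return TrendTestResult(chi_square=float(chi), df=1, p=float(sps.chi2.sf(chi, 1)), n=int(n))


def chi_square_2x2(events_a: int, n_a: int, events_b: int, n_b: int) -> ContingencyResult:
    """Pearson chi-square on a 2x2 events/no-events table, no continuity
    correction, 1 df."""
    for events, n, name in ((events_a, n_a, "a"), (events_b, n_b, "b")):
        if not 0 <= events <= n:
            raise StatisticalError(f"group {name}: need 0 <= events ({events}) <= n ({n})")
    table = np.array([[events_a, n_a - events_a], [events_b, n_b - events_b]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise StatisticalError("chi-square undefined: a table margin is zero")
    chi, p, df, _ = sps.chi2_contingency(table, correction=False)
    return ContingencyResult(chi_square=float(chi), df=int(df), p=float(p))


def iqr_distance(value: float, q25: float, q75: float) -> float:
    """Distance from the IQR: 0 inside [q25, q75], else the gap to the
    nearer bound.  Used by the report-style distance tests."""
    if value < q25:
        return q25 - value
    if value > q75:
        return value - q75
    return 0.0


def select_weighted_parameter(
    drug_cases: Sequence[CaseFeatures],
    comparator_cases: Sequence[CaseFeatures],
    alpha: float = 0.05,
) -> WeightScheme:
    """Choose the weighted parameter from a drug-vs-comparator batch.

    Runs the Mann-Whitney test on each parameter's raw values; the
    parameter with the smallest p (at three decimals; ties broken by the
    smaller U) is weighted, provided it is significant at ``alpha``.
    With no comparator cases, or no significant parameter, latency is
    the a-priori default.
    """
    if not comparator_cases:
        return WeightScheme("latency_days", reason="default: no comparator cases available")
    candidates: list[tuple[float, float, float, str]] = []
    for param in PARAMETERS:
        a = [getattr(c, param) for c in drug_cases if getattr(c, param) is not None]
        b = [getattr(c, param) for c in comparator_cases if getattr(c, param) is not None]
        if not a or not b:
            continue
        res = mann_whitney(a, b)
        candidates.append((round(res.p_two_sided, 3), res.u, res.p_two_sided, param))
    if not candidates:
        return WeightScheme("latency_days", reason="default: no parameter comparable across arms")
    p3, u, p_full, best = min(candidates)
    if p_full >= alpha:
        return WeightScheme(
            "latency_days",
            reason=f"default: no parameter significant at alpha={alpha} (best {best} p={p3})",
        )
    return WeightScheme(best, reason=f"smallest Mann-Whitney p={p3} (U={u})")
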