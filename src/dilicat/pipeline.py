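"""Stepwise phenotype development as cases accrue across study batches.

The procedure mimics a drug-development programme where injury cases
arrive in batches:

1. build a preliminary drug phenotype from the first batch's drug-arm
   cases;
2. validate it on the next batch — score that batch's drug and
   comparator cases against the current phenotype, select the weighted
   parameter from the batch's drug-vs-comparator comparison, and test
   the total scores with the linear-by-linear trend test;
3. merge the new drug cases into the cumulative set and rebuild
   (refine) the phenotype;
4. repeat steps 2-3 for each further batch.

The cumulative phenotype after k iterations equals a single build over
the union of the first k batches' drug cases — there is no path
dependence.  Batches with zero events are recorded as skipped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .phenotype import CaseFeatures, DiliPhenotype, build_phenotype, DEFAULT_MIN_CASES
from .scoring import WeightScheme, score_cohort
from .stats import (
    ContingencyResult,
    StatisticalError,
    TrendTestResult,
    chi_square_2x2,
    mantel_haenszel_trend,
    select_weighted_parameter,
)

__all__ = [
    "StudyBatch",
    "PipelineConfig",
    "IterationRecord",
    "run_stepwise",
    "compare_incidence",
    "IncidenceResult",
]


@dataclass(frozen=True)
class StudyBatch:
    """One accrual batch of injury cases, with arm labels on the cases."""

    batch_id: str
    cases: tuple = ()

    def arm_cases(self, arm: str) -> list[CaseFeatures]:
        return [c for c in self.cases if c.arm == arm]


@dataclass(frozen=True)
class PipelineConfig:
    """Stepwise-run configuration.

    ``dialects`` gives the quantile dialect per phenotype version
    (version k uses entry ``min(k, len) - 1``; a single string applies
    throughout).  The published reproduction pins ``("inclusive",
    "exclusive")``: preliminary phenotype inclusive, refinements
    exclusive.  ``weighting`` is ``"per_batch"`` (select from the
    current validation batch), ``"pooled"`` (select from all accrued
    drug vs comparator cases) or ``"frozen"`` (keep
    ``frozen_parameter`` throughout).
    """

    dialects: Union[str, tuple] = "inclusive"
    min_cases: int = DEFAULT_MIN_CASES
    alpha: float = 0.05
    weighting: str = "per_batch"
    frozen_parameter: str = "latency_days"
    table_outlier_compat: bool = False
    force: bool = False

    def dialect_for(self, version: int) -> str:
        if isinstance(self.dialects, str):
            return self.dialects
        return self.dialects[min(version, len(self.dialects)) - 1]

    @classmethod
    def reproduction(cls) -> "PipelineConfig":
        """The configuration reproducing the published ximelagatran run."""
        return cls(dialects=("inclusive", "exclusive"))


@dataclass
class IterationRecord:
    """Everything one stepwise iteration produced."""

    step_index: int
    batch_id: str
    phenotype: Optional[DiliPhenotype] = None
    weight_scheme: Optional[WeightScheme] = None
    scores: list = field(default_factory=list)
    trend: Optional[TrendTestResult] = None
    skipped: bool = False
    notes: str = ""

    def to_dict(self) -> dict:
        return {
            "step_index": self.step_index,
            "batch_id": self.batch_id,
            "skipped": self.skipped,
            "notes": self.notes,
            "phenotype": None if self.phenotype is None else self.phenotype.to_dict(),
            "weight_scheme": None
            if self.weight_scheme is None
            else {
                "weighted_parameter": self.weight_scheme.weighted_parameter,
                "standard_max": self.weight_scheme.standard_max,
                "weighted_max": self.weight_scheme.weighted_max,
                "reason": self.weight_scheme.reason,
            },
            "scores": [
                {
                    "case_id": s.case_id,
                    "arm": s.arm,
                    "total": s.total,
                    "points": {k: v.points for k, v in s.parameters.items()},
                }
                for s in self.scores
            ],
            "trend": None
            if self.trend is None
            else {"chi_square": self.trend.chi_square, "df": self.trend.df, "p": self.trend.p, "n": self.trend.n},
        }

    def to_markdown(self) -> str:
        lines = [f"### Step {self.step_index}: batch {self.batch_id}"]
        if self.skipped:
            lines.append(f"*skipped* — {self.notes}")
            return "\n".join(lines)
        if self.weight_scheme is not None:
            lines.append(
                f"- weighted parameter: **{self.weight_scheme.weighted_parameter}** ({self.weight_scheme.reason})"
            )
        if self.scores:
            lines.append("")
            lines.append("| case | arm | total |")
            lines.append("|------|-----|-------|")
            for s in self.scores:
                lines.append(f"| {s.case_id} | {s.arm} | {s.total} |")
        if self.trend is not None:
            lines.append("")
            lines.append(
                f"- trend test: chi-square {self.trend.chi_square:.3f} (1 df), p = {self.trend.p:.3f}"
            )
        if self.phenotype is not None:
            lines.append(
                f"- phenotype {self.phenotype.version_tag} "
                f"({self.phenotype.quantile_dialect} dialect, n = {self.phenotype.n_cases})"
            )
        return "\n".join(lines)


def run_stepwise(batches: Sequence[StudyBatch], config: PipelineConfig = PipelineConfig()) -> list[IterationRecord]:
    """Run the full accrual loop over ordered study batches.

    The first non-empty batch seeds the preliminary phenotype from its
    drug-arm cases; every later batch is scored against the current
    phenotype (never against one its own cases helped build) before its
    drug cases are merged in.
    """
    ids = [b.batch_id for b in batches]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate batch ids: {ids}")
    records: list[IterationRecord] = []
    cumulative_drug: list[CaseFeatures] = []
    pooled_comparator: list[CaseFeatures] = []
    phenotype: Optional[DiliPhenotype] = None
    version = 0

    for step, batch in enumerate(batches, start=1):
        rec = IterationRecord(step_index=step, batch_id=batch.batch_id)
        drug_cases = batch.arm_cases("drug")
        comp_cases = batch.arm_cases("comparator")

        if not batch.cases:
            rec.skipped = True
            rec.notes = "no liver events in this batch"
            records.append(rec)
            continue

        if phenotype is None:
            if len(drug_cases) < config.min_cases and not config.force:
                raise ValueError(
                    f"batch {batch.batch_id!r}: {len(drug_cases)} drug-arm case(s) "
                    f"cannot seed a phenotype (minimum {config.min_cases})"
                )
            version = 1
            phenotype = build_phenotype(
                drug_cases,
                dialect=config.dialect_for(version),
                min_cases=config.min_cases,
                force=config.force,
                version_tag=f"v{version}",
            )
            cumulative_drug = list(drug_cases)
            pooled_comparator = list(comp_cases)
            rec.phenotype = phenotype
            rec.notes = "preliminary phenotype (no validation possible on the seed batch)"
            records.append(rec)
            continue

        # Leakage guard: a case must never be scored against a phenotype
        # version it helped build.
        overlap = {c.case_id for c in batch.cases} & set(phenotype.source_case_ids)
        if overlap:
            raise ValueError(
                f"batch {batch.batch_id!r}: case(s) {sorted(overlap)} already inside "
                f"phenotype {phenotype.version_tag}; refusing to score them against it"
            )

        if config.weighting == "frozen":
            scheme = WeightScheme(config.frozen_parameter, reason="frozen by configuration")
        elif config.weighting == "pooled":
            scheme = select_weighted_parameter(
                cumulative_drug + drug_cases, pooled_comparator + comp_cases, alpha=config.alpha
            )
        elif config.weighting == "per_batch":
            scheme = select_weighted_parameter(drug_cases, comp_cases, alpha=config.alpha)
        else:
            raise ValueError(f"unknown weighting mode {config.weighting!r}")

        scorable = [c for c in batch.cases if c.is_complete()]
        rec.weight_scheme = scheme
        rec.scores = score_cohort(scorable, phenotype, scheme, config.table_outlier_compat)

        labels = [s.arm for s in rec.scores]
        totals = [s.total for s in rec.scores]
        try:
            rec.trend = mantel_haenszel_trend(labels, totals)
        except StatisticalError as exc:
            rec.notes = f"trend test unavailable: {exc}"

        version += 1
        phenotype = build_phenotype(
            cumulative_drug + drug_cases,
            dialect=config.dialect_for(version),
            min_cases=config.min_cases,
            force=config.force,
            version_tag=f"v{version}",
        )
        cumulative_drug.extend(drug_cases)
        pooled_comparator.extend(comp_cases)
        rec.phenotype = phenotype
        records.append(rec)

    return records


@dataclass(frozen=True)
class IncidenceResult:
    events_drug: int
    n_drug: int
    events_comparator: int
    n_comparator: int
    pct_drug: float
    pct_comparator: float
    test: ContingencyResult


def compare_incidence(batch: StudyBatch, arm_sizes: tuple[int, int]) -> IncidenceResult:
    """Compare per-arm event incidence for one batch against the arm
    denominators ``(n_drug, n_comparator)``."""
    n_drug, n_comp = arm_sizes
    e_drug = len(batch.arm_cases("drug"))
    e_comp = len(batch.arm_cases("comparator"))
    if e_drug > n_drug or e_comp > n_comp:
        raise StatisticalError("arm sizes smaller than event counts")
    test = chi_square_2x2(e_drug, n_drug, e_comp, n_comp)
    return IncidenceResult(
        events_drug=e_drug,
        n_drug=n_drug,
        events_comparator=e_comp,
        n_comparator=n_comp,
        pct_drug=100.0 * e_drug / n_drug,
        pct_comparator=100.0 * e_comp / n_comp,
        test=test,
    )


def records_to_json(records: Sequence[IterationRecord]) -> str:
    return json.dumps([r.to_dict() for r in records], indent=2)


def records_to_markdown(records: Sequence[IterationRecord]) -> str:
    return "\n\n".join(r.to_markdown() for r in records) + "\n"
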