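"""Scikit-learn-style estimator facade over the phenotype/scoring core.

Learning a drug's injury phenotype from reference cases is a ``fit``;
scoring new cases against it is a ``transform``.  The estimator wraps
:func:`dilicat.phenotype.build_phenotype` and
:func:`dilicat.scoring.score_cohort`, composes with sklearn pipelines
and ``clone``, and exposes the fitted phenotype and weight scheme as
trailing-underscore attributes.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .phenotype import PARAMETERS, CaseFeatures, build_phenotype
from .scoring import WeightScheme, score_cohort
from .stats import select_weighted_parameter

__all__ = ["DiliCatScorer"]


def _as_cases(X, arm: Optional[np.ndarray] = None, drug: str = "drug") -> list[CaseFeatures]:
    """Coerce a DataFrame (or (n, 3) array in canonical parameter
    order) into case features."""
    if isinstance(X, pd.DataFrame):
        missing = set(PARAMETERS) - set(X.columns)
        if missing:
            raise ValueError(f"case table missing column(s) {sorted(missing)}")
        ids = X["case_id"].astype(str).tolist() if "case_id" in X.columns else [f"case-{i}" for i in range(len(X))]
        vals = X.loc[:, list(PARAMETERS)].to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != len(PARAMETERS):
            raise ValueError(f"expected an (n, {len(PARAMETERS)}) array ordered {PARAMETERS}")
        ids = [f"case-{i}" for i in range(arr.shape[0])]
        vals = arr
    arms = ["drug"] * len(ids) if arm is None else ["drug" if a else "comparator" for a in arm]
    return [
        CaseFeatures(
            case_id=i,
            drug=drug if a == "drug" else "comparator",
            latency_days=v[0],
            r_value=v[1],
            ast_alt_ratio=v[2],
            arm=a,
        )
        for i, v, a in zip(ids, vals, arms)
    ]


class DiliCatScorer(BaseEstimator, TransformerMixin):
    """Learn a drug phenotype from reference cases and score new ones.

    Parameters
    ----------
    dialect : {"inclusive", "exclusive"}
        Quantile interpolation dialect for the fitted profiles.
    weighted_parameter : {"auto", "latency_days", "r_value", "ast_alt_ratio"}
        Parameter whose points are doubled.  ``"auto"`` selects it from
        the drug-vs-comparator comparison at fit time (requires ``y``);
        latency is the fallback default.
    min_cases : int
        Minimum number of drug-arm cases required to fit.
    alpha : float
        Significance gate for the automatic weighting selection.
    force : bool
        Fit below ``min_cases`` with a warning instead of an error.
    table_outlier_compat : bool
        Score in-range outliers with the legacy fixed -10 points.

    Attributes
    ----------
    phenotype_ : DiliPhenotype
        The fitted per-parameter percentile profiles.
    weight_scheme_ : WeightScheme
        The weighting applied by :meth:`transform`.
    n_features_in_ : int

    Examples
    --------
    >>> import pandas as pd
    >>> from dilicat.datasets import sportif2_cases, sportif3_subset1_cases
    >>> ref = pd.DataFrame([{"latency_days": c.latency_days, "r_value": c.r_value,
    ...                      "ast_alt_ratio": c.ast_alt_ratio} for c in sportif2_cases()])
    >>> scorer = DiliCatScorer(weighted_parameter="ast_alt_ratio").fit(ref)
    >>> new = pd.DataFrame([{"latency_days": 43, "r_value": 3.32, "ast_alt_ratio": 0.64}])
    >>> int(scorer.transform(new)["total"].iloc[0])
    25
    """

    def __init__(
        self,
        dialect: str = "inclusive",
        weighted_parameter: str = "auto",
        min_cases: int = 5,
        alpha: float = 0.05,
        force: bool = False,
        table_outlier_compat: bool = False,
    ):
        self.dialect = dialect
        self.weighted_parameter = weighted_parameter
        self.min_cases = min_cases
        self.alpha = alpha
        self.force = force
        self.table_outlier_compat = table_outlier_compat

    def fit(self, X, y=None):
        """Fit the phenotype from ``X``.

        ``X`` holds the three parameters per case (DataFrame or (n, 3)
        array ordered latency, R, ratio).  ``y``, when given, is a
        boolean/binary arm indicator (truthy = drug arm); the phenotype
        is built from the drug rows and, with
        ``weighted_parameter="auto"``, the weighting is selected from
        the drug-vs-comparator comparison.
        """
        arm = None if y is None else np.asarray(y)
        cases = _as_cases(X, arm)
        drug_cases = [c for c in cases if c.arm == "drug"]
        comp_cases = [c for c in cases if c.arm == "comparator"]
        if not drug_cases:
            raise ValueError("no drug-arm cases to fit a phenotype from")
        self.phenotype_ = build_phenotype(
            drug_cases, dialect=self.dialect, min_cases=self.min_cases, force=self.force
        )
        if self.weighted_parameter == "auto":
            self.weight_scheme_ = select_weighted_parameter(drug_cases, comp_cases, alpha=self.alpha)
        else:
            self.weight_scheme_ = WeightScheme(self.weighted_parameter, reason="fixed by configuration")
        self.n_features_in_ = len(PARAMETERS)
        return self

    def transform(self, X) -> pd.DataFrame:
        """Score cases in ``X`` against the fitted phenotype.

        Returns a DataFrame with one row per case: per-parameter points
        and band labels, and the ``total`` score in [-40, 80].
        """
        if not hasattr(self, "phenotype_"):
            raise ValueError("this DiliCatScorer instance is not fitted yet")
        cases = _as_cases(X)
        scores = score_cohort(
            cases, self.phenotype_, self.weight_scheme_, self.table_outlier_compat
        )
        rows = []
        for s in scores:
            row: dict = {"case_id": s.case_id}
            for name, ps in s.parameters.items():
                row[f"{name}_points"] = ps.points
                row[f"{name}_band"] = ps.band.value
            row["total"] = s.total
            rows.append(row)
        return pd.DataFrame(rows)

    def score_samples(self, X) -> np.ndarray:
        """Total score per case (higher = closer to the fitted phenotype)."""
        return self.transform(X)["total"].to_numpy()
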