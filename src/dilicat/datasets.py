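"""Published ximelagatran worked-example data, transcribed as fixtures.

The ximelagatran clinical programme (the four SPORTIF atrial-fibrillation
trials, ximelagatran vs adjusted-dose warfarin) is the method's reference
worked example.  This module ships the case values and the expected
phenotype statistics and scores needed to reproduce it end to end:

* the five SPORTIF 2 ximelagatran injury cases that seed the preliminary
  phenotype (inclusive quantile dialect),
* the eight SPORTIF 3 subset-1 validation cases (five ximelagatran,
  three warfarin) with their published per-parameter points and totals,
* the expected statistics of the preliminary phenotype and of the
  10-case refined phenotype version 2 (exclusive dialect).

R-values of the SPORTIF 2 cases are carried at the two-decimal precision
recoverable from the published summary statistics (the case listing
rounds them to one decimal; the mapping back to cases is unambiguous).

One published cell is stored in self-consistent form: the warfarin
case 3 R-value points are -10 (its value 0.67 lies below both the range
minimum and the lower outlier fence, and the published total of -40
requires -10), although the source table prints -5 for that cell.
"""

from __future__ import annotations

from .phenotype import CaseFeatures

__all__ = [
    "sportif2_cases",
    "sportif3_subset1_cases",
    "PHENOTYPE_V1_EXPECTED",
    "PHENOTYPE_V2_EXPECTED",
    "SUBSET1_EXPECTED_POINTS",
    "SUBSET1_EXPECTED_TOTALS",
]

DRUG = "ximelagatran"
COMPARATOR = "warfarin"


def sportif2_cases() -> list[CaseFeatures]:
    """The five SPORTIF 2 ximelagatran injury cases (phenotype seed)."""
    rows = [
        ("xim-2.1", 69, 12.72, 0.49),
        ("xim-2.2", 83, 8.68, 0.65),
        ("xim-2.3", 56, 5.93, 0.61),
        ("xim-2.4", 58, 5.75, 0.60),
        ("xim-2.5", 75, 13.85, 0.69),
    ]
    return [
        CaseFeatures(case_id=i, drug=DRUG, latency_days=lat, r_value=r, ast_alt_ratio=ratio, arm="drug")
        for i, lat, r, ratio in rows
    ]


def sportif3_subset1_cases() -> list[CaseFeatures]:
    """The eight SPORTIF 3 subset-1 validation cases (5 drug, 3 comparator)."""
    rows = [
        ("xim-3.1", DRUG, "drug", 43, 3.32, 0.64),
        ("xim-3.2", DRUG, "drug", 46, 6.63, 0.68),
        ("xim-3.3", DRUG, "drug", 92, 7.26, 0.59),
        ("xim-3.4", DRUG, "drug", 427, 9.41, 0.47),
        ("xim-3.5", DRUG, "drug", 45, 0.56, 0.65),
        ("war-3.1", COMPARATOR, "comparator", 43, 2.07, 1.11),
        ("war-3.2", COMPARATOR, "comparator", 187, 2.82, 0.97),
        ("war-3.3", COMPARATOR, "comparator", 266, 0.67, 1.09),
    ]
    return [
        CaseFeatures(case_id=i, drug=d, latency_days=lat, r_value=r, ast_alt_ratio=ratio, arm=a)
        for i, d, a, lat, r, ratio in rows
    ]


#: Published preliminary-phenotype statistics (inclusive dialect).  The
#: latency/ratio lower fences are the fence-formula values (published
#: rounding: 45.3; the ratio cell prints an unreproducible 0.53).
PHENOTYPE_V1_EXPECTED = {
    "latency_days": {
        "median": 69.0, "q25": 58.0, "q75": 75.0, "q15": 57.2, "q85": 78.2,
        "q10": 56.8, "q90": 79.8, "fence_low": 45.25, "fence_high": 100.5,
        "range_min": 56.0, "range_max": 83.0,
    },
    "r_value": {
        "median": 8.68, "q25": 5.93, "q75": 12.72, "q15": 5.858, "q85": 13.172,
        "q10": 5.822, "q90": 13.398, "fence_low": 0.8375, "fence_high": 22.905,
        "range_min": 5.75, "range_max": 13.85,
    },
    "ast_alt_ratio": {
        "median": 0.61, "q25": 0.60, "q75": 0.65, "q15": 0.556, "q85": 0.666,
        "q10": 0.534, "q90": 0.674, "fence_low": 0.5625, "fence_high": 0.725,
        "range_min": 0.49, "range_max": 0.69,
    },
}

#: Published refined-phenotype (version 2) statistics, exclusive dialect,
#: over the pooled ten drug cases.  The published latency median cell
#: ("6.5") and R range maximum ("18.85") are transcription errors; the
#: computed values 63.5 and 13.85 are stored.
PHENOTYPE_V2_EXPECTED = {
    "latency_days": {
        "median": 63.5, "q25": 45.75, "q75": 85.25, "q15": 44.3, "q85": 209.25,
        "q10": 43.2, "q90": 393.5, "fence_low": 16.125, "fence_high": 144.5,
        "range_min": 43.0, "range_max": 427.0,
    },
    "r_value": {
        "median": 6.945, "q25": 5.1425, "q75": 10.2375, "q15": 2.354, "q85": 13.1155,
        "q10": 0.836, "q90": 13.737, "fence_low": 1.32125, "fence_high": 17.88,
        "range_min": 0.56, "range_max": 13.85,
    },
    "ast_alt_ratio": {
        "median": 0.625, "q25": 0.565, "q75": 0.6575, "q15": 0.483, "q85": 0.6835,
        "q10": 0.472, "q90": 0.689, "fence_low": 0.495625, "fence_high": 0.79625,
        "range_min": 0.47, "range_max": 0.69,
    },
}

#: Published per-parameter points for the subset-1 validation scoring
#: (AST/ALT ratio weighted, max 40; others max 20), keyed by case id.
SUBSET1_EXPECTED_POINTS = {
    "xim-3.1": {"latency_days": -10, "r_value": -5, "ast_alt_ratio": 40},
    "xim-3.2": {"latency_days": -5, "r_value": 20, "ast_alt_ratio": 0},
    "xim-3.3": {"latency_days": -5, "r_value": 20, "ast_alt_ratio": 20},
    "xim-3.4": {"latency_days": -10, "r_value": 20, "ast_alt_ratio": -20},
    "xim-3.5": {"latency_days": -10, "r_value": -10, "ast_alt_ratio": 40},
    "war-3.1": {"latency_days": -10, "r_value": -5, "ast_alt_ratio": -20},
    "war-3.2": {"latency_days": -10, "r_value": -5, "ast_alt_ratio": -20},
    "war-3.3": {"latency_days": -10, "r_value": -10, "ast_alt_ratio": -20},
}

#: Published total scores in case order (drug 1-5 then comparator 1-3).
SUBSET1_EXPECTED_TOTALS = (25, 15, 35, -10, 20, -35, -35, -40)
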