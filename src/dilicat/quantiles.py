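"""Quantile estimation dialects and IQR-based outlier fences.

Two interpolation dialects are supported because spreadsheet software
exposes both and published phenotype tables mix them:

``inclusive``
    Linear interpolation at rank ``1 + (n - 1) * q`` (Hyndman & Fan
    type 7; spreadsheet ``PERCENTILE.INC``; numpy ``method="linear"``).
``exclusive``
    Linear interpolation at rank ``(n + 1) * q`` (type 6; spreadsheet
    ``PERCENTILE.EXC``; numpy ``method="weibull"``), clamped to the
    observed data range when the rank falls outside ``[1, n]``.

Outlier fences are asymmetric around the interquartile range: the upper
fence sits 150 % of the IQR width above Q3, the lower fence 75 % of the
IQR width below Q1, reflecting the right skew of latency and R-value
distributions in hepatocellular drug injury.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

__all__ = ["DIALECTS", "percentile", "outlier_fences"]

DIALECTS = ("inclusive", "exclusive")

_NUMPY_METHOD = {"inclusive": "linear", "exclusive": "weibull"}


def percentile(values: Iterable[float], q: float, dialect: str = "inclusive") -> float:
    """Interpolated quantile of ``values`` at fraction ``q``.

    Parameters
    ----------
    values
        Numeric sample (need not be pre-sorted).
    q
        Quantile fraction, strictly inside ``(0, 1)``.
    dialect
        ``"inclusive"`` (type 7) or ``"exclusive"`` (type 6, clamped to
        the data range).

    Returns
    -------
    float
        The interpolated quantile.
    """
    if dialect not in _NUMPY_METHOD:
        raise ValueError(f"unknown quantile dialect {dialect!r}; expected one of {DIALECTS}")
    if not 0.0 < q < 1.0:
        raise ValueError(f"quantile fraction must lie in (0, 1), got {q}")
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot compute a percentile of an empty sample")
    if not np.all(np.isfinite(arr)):
        raise ValueError("percentile input contains non-finite values")
    # numpy clips the interpolation rank to [1, n], which implements the
    # clamped exclusive dialect directly.
    return float(np.quantile(arr, q, method=_NUMPY_METHOD[dialect]))


def outlier_fences(q25: float, q75: float) -> tuple[float, float]:
    """Asymmetric outlier fences from the quartiles.

    ``high = Q3 + 1.5 * IQR`` and ``low = Q1 - 0.75 * IQR`` where
    ``IQR = Q3 - Q1``.  The fences may fall inside the observed range;
    range membership and outlier status are judged independently.
    """
    if q75 < q25:
        raise ValueError(f"q75 ({q75}) must not be below q25 ({q25})")
    iqr = q75 - q25
    return q25 - 0.75 * iqr, q75 + 1.5 * iqr
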