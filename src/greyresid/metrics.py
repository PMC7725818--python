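"""Accuracy measures for forecast evaluation.

Five measures are reported throughout: squared-error sum (SSE), mean
absolute error (MAE), mean squared error (MSE), mean absolute percentage
error (MAPE, in percent) and mean relative error (MRE, the same quantity as
a fraction).  All take absolute values or squares, so all are nonnegative
and ``mape == 100 * mre`` identically.  A signed mean relative error is
available separately for diagnostics (it can cancel positive against
negative deviations and is NOT one of the five measures).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

__all__ = ["ErrorReport", "error_report", "signed_mean_relative_error"]


@dataclass(frozen=True)
class ErrorReport:
    """The five accuracy measures for one actual/predicted pair.

    ``sse`` and ``mse`` are in squared observation units, ``mae`` in
    observation units, ``mape_percent`` in percent and ``mre`` is the
    dimensionless fraction (``mape_percent / 100``).
    """

    sse: float
    mae: float
    mse: float
    mape_percent: float
    mre: float

    def to_dict(self) -> dict:
        return asdict(self)


def _check_pair(actual: Sequence[float], predicted: Sequence[float]):
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.size == 0:
        raise ValueError("empty series")
    if a.size != p.size:
        raise ValueError(f"length mismatch: actual has {a.size}, predicted has {p.size}")
    return a, p


def error_report(actual: Sequence[float], predicted: Sequence[float]) -> ErrorReport:
    """Compute SSE, MAE, MSE, MAPE(%) and MRE over equal-length series.

    The divisor is the number of compared points.  Raises if any actual
    value is zero (the relative measures are undefined there), naming the
    offending 1-based index.
    """
    a, p = _check_pair(actual, predicted)
    if np.any(a == 0):
        bad = int(np.argmax(a == 0)) + 1
        raise ValueError(f"actual value is zero at k={bad}: MAPE/MRE undefined")
    diff = a - p
    sse = float(np.sum(diff**2))
    mae = float(np.mean(np.abs(diff)))
    mse = sse / a.size
    mre = float(np.mean(np.abs(diff / a)))
    return ErrorReport(sse=sse, mae=mae, mse=mse, mape_percent=100.0 * mre, mre=mre)


def signed_mean_relative_error(
    actual: Sequence[float], predicted: Sequence[float]
) -> float:
    """Mean of signed relative deviations (diagnostic; may be negative)."""
    a, p = _check_pair(actual, predicted)
    if np.any(a == 0):
        bad = int(np.argmax(a == 0)) + 1
        raise ValueError(f"actual value is zero at k={bad}")
    return float(np.mean((a - p) / a))
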