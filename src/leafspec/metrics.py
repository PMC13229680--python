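"""Evaluation metrics: coefficient of determination and RMSE."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DataError


def r_squared(y, y_hat) -> float:
    """R^2 = 1 - SS_res / SS_tot, with SS_tot about the mean of ``y`` itself.

    The mean is that of the split being evaluated, so a model predicting
    that split's mean scores exactly 0 on it.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if len(y) < 2 or len(y) != len(y_hat):
        raise DataError("r_squared needs two equal-length vectors of length >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise DataError("label variance is zero; R^2 undefined")
    return 1.0 - float(np.sum((y - y_hat) ** 2)) / ss_tot


def rmse(y, y_hat) -> float:
    """Root mean square error, in label units."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if len(y) == 0 or len(y) != len(y_hat):
        raise DataError("rmse needs two equal-length nonempty vectors")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


@dataclass(frozen=True)
class MetricReport:
    """R^2 and RMSE for one model on one split."""

    r2: float
    rmse: float
    n: int
    split_name: str = ""

    @classmethod
    def evaluate(cls, y, y_hat, split_name: str = "") -> "MetricReport":
        return cls(r_squared(y, y_hat), rmse(y, y_hat), len(np.asarray(y)), split_name)
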