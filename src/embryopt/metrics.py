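"""Model performance statistics: R-squared, MAE, RMSE.

R-squared is the squared Pearson correlation between observed and predicted
series (so it is invariant under affine transforms of either series and lies
in [0, 1]); RMSE and MAE are computed in natural response units.
"""

from __future__ import annotations

import numpy as np

__all__ = ["r_squared", "mae", "rmse"]


def _pair(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(observed, float).ravel()
    yhat = np.asarray(predicted, float).ravel()
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    return y, yhat


def r_squared(observed, predicted) -> float:
    """Squared Pearson correlation; 1.0 means a perfect (affine) fit."""
    y, yhat = _pair(observed, predicted)
    if y.size < 2:
        raise ValueError("r_squared needs at least 2 rows")
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        raise ValueError("correlation undefined for a constant series")
    r = np.corrcoef(y, yhat)[0, 1]
    return float(r * r)


def mae(observed, predicted) -> float:
    """Mean absolute error, in the units of the response."""
    y, yhat = _pair(observed, predicted)
    return float(np.mean(np.abs(y - yhat)))


def rmse(observed, predicted) -> float:
    """Root mean squared error, in the units of the response."""
    y, yhat = _pair(observed, predicted)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))
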