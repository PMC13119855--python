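"""Inverse-distance-weighted interpolation and its leave-one-out CV metrics.

IDW predicts a value at a query location as the weighted mean of
neighboring observations with weights ``d⁻ᵖ``; predictions are exact at
data points and always lie within the data range (weights are positive
and sum to one).

Cross-validation reports RMSE, MAPE and RMSSE.  IDW has no model
variance, so the standardized error uses the distance-weighted standard
deviation of the neighbor values at each left-out point as the local
uncertainty scale; RMSSE ≈ 1 then indicates that this scale is
consistent with the actual prediction errors.  This convention is a
package choice — treat RMSSE comparisons across software as qualitative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = ["CVMetrics", "idw_predict", "loo_crossvalidate", "grid_predict"]

_NODE_TOL = 1e-12


@dataclass(frozen=True)
class CVMetrics:
    """Leave-one-out cross-validation metrics for one variable."""

    rmse: float      # mg·kg⁻¹
    mape: float      # %
    rmsse: float     # dimensionless, ≈1 when the error scale is calibrated
    n: int           # points cross-validated
    n_mape: int      # points entering MAPE (observations > 0)


def _weights(d: np.ndarray, power: float) -> np.ndarray:
    w = d ** (-power)
    return w / w.sum()


def idw_predict(
    points: np.ndarray,
    values: np.ndarray,
    query: np.ndarray,
    power: float = 2.0,
    k: int | None = None,
):
    """IDW prediction at one query point or an array of query points.

    Parameters
    ----------
    points, values
        Data coordinates ``(n, 2)`` and values ``(n,)``.
    query
        A single ``(2,)`` coordinate or ``(q, 2)`` array.
    power
        Distance-decay exponent (> 0).
    k
        Number of nearest neighbors; ``None`` uses all points.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    if points.ndim != 2 or len(points) == 0:
        raise ValueError("need at least one data point")
    if power <= 0:
        raise ValueError("power must be positive")
    query = np.asarray(query, dtype=float)
    single = query.ndim == 1
    q = query[None, :] if single else query

    if k is not None and k < len(points):
        tree = cKDTree(points)
        d, idx = tree.query(q, k=k)
        d = np.atleast_2d(d)
        idx = np.atleast_2d(idx)
        neigh_vals = values[idx]
    else:
        d = np.sqrt(((q[:, None, :] - points[None, :, :]) ** 2).sum(axis=2))
        neigh_vals = np.broadcast_to(values, (len(q), len(values)))

    out = np.empty(len(q))
    for i in range(len(q)):
        di, vi = d[i], neigh_vals[i]
        hit = di < _NODE_TOL
        if hit.any():
            out[i] = vi[hit][0]
        else:
            out[i] = _weights(di, power) @ vi
    return float(out[0]) if single else out


def loo_crossvalidate(
    points: np.ndarray,
    values: np.ndarray,
    power: float = 2.0,
    k: int | None = None,
) -> CVMetrics:
    """Leave-one-out cross-validation: each point predicted from all
    others with the same IDW parameters.

    Observations equal to zero are excluded from MAPE (with a warning);
    points whose neighbor values are constant contribute zero to RMSSE
    when their error is zero and are otherwise excluded.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(points)
    if n < 3:
        raise ValueError("leave-one-out CV needs at least 3 points")

    errors = np.empty(n)
    std_terms = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        pts, vals = points[mask], values[mask]
        d = np.sqrt(((points[i] - pts) ** 2).sum(axis=1))
        if k is not None and k < len(pts):
            order = np.argsort(d)[:k]
            d, vals = d[order], vals[order]
        hit = d < _NODE_TOL
        if hit.any():
            pred = vals[hit][0]
            sigma = 0.0
        else:
            w = _weights(d, power)
            pred = w @ vals
            sigma = np.sqrt(w @ (vals - pred) ** 2)
        err = pred - values[i]
        errors[i] = err
        if sigma > 0:
            std_terms.append((err / sigma) ** 2)
        elif err == 0:
            std_terms.append(0.0)

    rmse = float(np.sqrt(np.mean(errors**2)))
    pos = values > 0
    if not pos.all():
        warnings.warn(
            f"{int((~pos).sum())} zero-valued observations excluded from MAPE",
            stacklevel=2,
        )
    mape = (
        float(np.mean(np.abs(errors[pos]) / values[pos]) * 100.0)
        if pos.any()
        else float("nan")
    )
    rmsse = float(np.sqrt(np.mean(std_terms))) if std_terms else float("nan")
    return CVMetrics(rmse=rmse, mape=mape, rmsse=rmsse, n=n, n_mape=int(pos.sum()))


def grid_predict(
    points: np.ndarray,
    values: np.ndarray,
    bbox: tuple[float, float, float, float],
    shape: tuple[int, int],
    power: float = 2.0,
    k: int | None = None,
) -> pd.DataFrame:
    """Predict on a regular grid; returns a long-form (x, y, value) table.

    ``bbox`` is ``(xmin, ymin, xmax, ymax)`` and must contain every data
    point; ``shape`` is the number of cells ``(nx, ny)``.  Grid nodes are
    cell centers.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    xmin, ymin, xmax, ymax = bbox
    nx, ny = shape
    if nx <= 0 or ny <= 0:
        raise ValueError("grid shape must be positive")
    if (
        points[:, 0].min() < xmin or points[:, 0].max() > xmax
        or points[:, 1].min() < ymin or points[:, 1].max() > ymax
    ):
        raise ValueError("bbox must contain all data points")
    xs = xmin + (np.arange(nx) + 0.5) * (xmax - xmin) / nx
    ys = ymin + (np.arange(ny) + 0.5) * (ymax - ymin) / ny
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    q = np.column_stack([gx.ravel(), gy.ravel()])
    pred = idw_predict(points, values, q, power=power, k=k)
    return pd.DataFrame({"x": q[:, 0], "y": q[:, 1], "value": np.atleast_1d(pred)})
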