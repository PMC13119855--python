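"""Random-forest concentration prediction with the survey's split
protocol and evaluation metrics.

A seeded 70/30 random split, a bagged regression forest (scikit-learn),
and the survey's three accuracy metrics.  Two R² definitions are
reported side by side: the standard coefficient of determination
``1 − SSE/SST`` and the explained-variance ratio
``Σ(Ĉᵢ − C̄)² / Σ(Cᵢ − C̄)²``.  The two agree when predictions are the
least-squares projection of the observations but differ off-projection,
so headline tables should quote the standard form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .core_io import DEPTH_LAYERS, METALS, SampleTable

__all__ = ["EvalMetrics", "split", "train_predict", "evaluate", "default_features"]


@dataclass(frozen=True)
class EvalMetrics:
    mae: float           # mg·kg⁻¹
    rmse: float          # mg·kg⁻¹
    r2_standard: float   # 1 − SSE/SST
    r2_explained: float      # explained-variance ratio


def split(table, fraction: float = 0.7, seed: int = 0):
    """Seeded random partition into train/validation subsets.

    Train size is ``floor(n · fraction)``; the partition is disjoint and
    exhaustive.  Accepts a :class:`SampleTable` or a DataFrame.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    df = table.data if isinstance(table, SampleTable) else table
    n = len(df)
    if n < 10:
        raise ValueError(f"need at least 10 rows to split, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(n * fraction))
    tr_idx, va_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    if isinstance(table, SampleTable):
        return (
            SampleTable(
                data=df.iloc[tr_idx].reset_index(drop=True),
                censored=table.censored.iloc[tr_idx].reset_index(drop=True),
                coordinate_units=table.coordinate_units,
            ),
            SampleTable(
                data=df.iloc[va_idx].reset_index(drop=True),
                censored=table.censored.iloc[va_idx].reset_index(drop=True),
                coordinate_units=table.coordinate_units,
            ),
        )
    return df.iloc[tr_idx], df.iloc[va_idx]


def default_features(target: str) -> list[str]:
    """Coordinates, depth code, pH and the other six metals."""
    return ["x", "y", "depth_code", "pH"] + [m for m in METALS if m != target]


def _design(df: pd.DataFrame, features: list[str]) -> pd.DataFrame:
    out = df.copy()
    if "depth_code" in features and "depth_code" not in out.columns:
        out["depth_code"] = out["depth_layer"].map(
            {l: i for i, l in enumerate(DEPTH_LAYERS)}
        )
    missing = [f for f in features if f not in out.columns]
    if missing:
        raise ValueError(f"features not present: {missing}")
    X = out[features].astype(float)
    return X.fillna(X.median())


def train_predict(
    train,
    validation,
    target: str,
    features: list[str] | None = None,
    n_trees: int = 500,
    seed: int = 0,
) -> np.ndarray:
    """Train a bagged regression forest and predict the validation target.

    Predictions are the mean over trees; fully deterministic for a fixed
    seed.  The target must not appear among the features.
    """
    features = features if features is not None else default_features(target)
    if target in features:
        raise ValueError(f"target {target!r} leaked into the feature list")
    tr = train.data if isinstance(train, SampleTable) else train
    va = validation.data if isinstance(validation, SampleTable) else validation
    model = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
    model.fit(_design(tr, features), tr[target].astype(float))
    return model.predict(_design(va, features))


def evaluate(measured, predicted) -> EvalMetrics:
    """MAE, RMSE and both R² definitions for a prediction vector."""
    c = np.asarray(measured, dtype=float)
    chat = np.asarray(predicted, dtype=float)
    if c.shape != chat.shape or c.ndim != 1:
        raise ValueError("measured and predicted must be 1-D and equal length")
    if len(c) < 2:
        raise ValueError("need at least 2 observations")
    cbar = c.mean()
    sst = ((c - cbar) ** 2).sum()
    if sst == 0:
        raise ValueError("measured values are constant; R² undefined")
    err = chat - c
    return EvalMetrics(
        mae=float(np.abs(err).mean()),
        rmse=float(np.sqrt((err**2).mean())),
        r2_standard=float(1.0 - (err**2).sum() / sst),
        r2_explained=float(((chat - cbar) ** 2).sum() / sst),
    )
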