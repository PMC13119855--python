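"""Uncertainty-weighted positive matrix factorization (PMF) receptor model.

Decomposes a samples × species concentration matrix ``X`` into
non-negative source contributions ``G`` (n × p) and source profiles
``F`` (p × m) by minimizing the uncertainty-scaled objective

    Q = Σᵢ Σⱼ ((xᵢⱼ − Σₖ gᵢₖ fₖⱼ) / uᵢⱼ)²

where ``uᵢⱼ`` is a per-cell measurement uncertainty built from the
method detection limit (MDL) and a relative standard deviation (RSD):

    u = (5/6)·MDL                         if x ≤ MDL
    u = sqrt((x·RSD)² + (0.5·MDL)²)       otherwise

The optimizer runs seeded multiplicative updates for the weighted
objective (monotone; accepted only while Q decreases) followed by
alternating per-row / per-column non-negative least squares, which is
exactly monotone, with multistart over random initializations.  The
reported ``Q_robust`` recomputes Q after inflating the uncertainty of
outlier cells (|scaled residual| > 4) by sqrt(|r|/4), the convention of
the standard receptor-modelling tools.

The bilinear model has an inherent scale indeterminacy (G·D, D⁻¹·F);
fitted factors are normalized so each contribution column has mean 1,
making profile rows directly interpretable as mg·kg⁻¹ at the average
sample, and ordered by decreasing total explained mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .core_io import ReferenceDataError, ReferenceTable

__all__ = [
    "build_uncertainty",
    "q_value",
    "SourceModel",
    "fit",
    "scan_factors",
    "bootstrap",
    "BootstrapResult",
    "contributions_pct",
]

_OUTLIER_CUT = 4.0


def build_uncertainty(
    X: pd.DataFrame | np.ndarray,
    reference: ReferenceTable | None = None,
    rsd: float = 0.2,
    metals: list[str] | None = None,
):
    """Per-cell uncertainty matrix from MDL and RSD (branching at MDL)."""
    ref = reference if reference is not None else ReferenceTable.default()
    if isinstance(X, pd.DataFrame):
        cols = list(X.columns)
        arr = X.to_numpy(dtype=float)
    else:
        if metals is None:
            raise ReferenceDataError("metals list required for array input")
        cols = list(metals)
        arr = np.asarray(X, dtype=float)
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValueError("concentrations must be finite and non-negative")
    mdl = np.array([ref.mdl(m) for m in cols])
    below = arr <= mdl
    u = np.where(
        below,
        (5.0 / 6.0) * mdl,
        np.sqrt((arr * rsd) ** 2 + (0.5 * mdl) ** 2),
    )
    if isinstance(X, pd.DataFrame):
        return pd.DataFrame(u, index=X.index, columns=cols)
    return u


def q_value(X, U, G, F, robust: bool = False) -> float:
    """Evaluate the weighted objective Q at (G, F).

    With ``robust=True``, outlier cells (|scaled residual| > 4) have
    their uncertainty inflated by sqrt(|r|/4) before re-evaluation.
    """
    X, U = np.asarray(X, float), np.asarray(U, float)
    r = (X - G @ F) / U
    if robust:
        a = np.abs(r)
        infl = np.where(a > _OUTLIER_CUT, np.sqrt(a / _OUTLIER_CUT), 1.0)
        r = r / infl
    return float((r**2).sum())


@dataclass
class SourceModel:
    """Fitted PMF solution with diagnostics."""

    G: np.ndarray                 # n × p contributions, ≥ 0, columns mean 1
    F: np.ndarray                 # p × m profiles, ≥ 0, mg·kg⁻¹
    p: int
    Q_true: float
    Q_robust: float
    scaled_residuals: np.ndarray  # n × m
    per_metal_r2: pd.Series
    contributions_pct: pd.DataFrame  # p × m, columns sum to 100
    metals: list[str]
    q_trace: list[float] = field(default_factory=list, repr=False)

    @property
    def q_ratio(self) -> float:
        """Q_robust / Q_true; close to 1 when few outlier cells exist."""
        return self.Q_robust / self.Q_true if self.Q_true > 0 else 1.0


def _mu_phase(X, W, G, F, max_iter, tol, eps=1e-12):
    """Weighted multiplicative updates; stops when Q stops decreasing."""
    trace = [float((W * (X - G @ F) ** 2).sum())]
    for _ in range(max_iter):
        GF = G @ F
        G = G * ((W * X) @ F.T) / ((W * GF) @ F.T + eps)
        GF = G @ F
        F = F * (G.T @ (W * X)) / (G.T @ (W * GF) + eps)
        q = float((W * (X - G @ F) ** 2).sum())
        if q > trace[-1]:
            break
        improved = trace[-1] - q
        trace.append(q)
        if improved < tol * max(q, 1e-300):
            break
    return G, F, trace


def _als_phase(X, U, G, F, max_iter, tol):
    """Alternating weighted NNLS sweeps (exactly monotone)."""
    n, m = X.shape
    trace = [q_value(X, U, G, F)]
    for _ in range(max_iter):
        for i in range(n):
            A = (F / U[i][None, :]).T
            G[i], _ = nnls(A, X[i] / U[i])
        for j in range(m):
            A = G / U[:, j][:, None]
            F[:, j], _ = nnls(A, X[:, j] / U[:, j])
        q = q_value(X, U, G, F)
        improved = trace[-1] - q
        trace.append(q)
        if improved < tol * max(q, 1e-300):
            break
    return G, F, trace


def _normalize(G, F):
    """Fix the scale indeterminacy: contribution columns mean 1, factors
    ordered by decreasing explained mass."""
    d = G.mean(axis=0)
    d[d == 0] = 1.0
    G = G / d
    F = F * d[:, None]
    order = np.argsort(-(F.sum(axis=1)))
    return G[:, order], F[order]


def _diagnose(X, U, G, F, metals, q_trace):
    recon = G @ F
    scaled = (X - recon) / U
    r2 = {}
    for j, m in enumerate(metals):
        obs, pred = X[:, j], recon[:, j]
        denom = ((obs - obs.mean()) ** 2).sum()
        if denom == 0:
            r2[m] = float("nan")
        else:
            num = ((obs - obs.mean()) * (pred - pred.mean())).sum()
            pv = ((pred - pred.mean()) ** 2).sum()
            r2[m] = float(num**2 / (denom * pv)) if pv > 0 else 0.0
    return SourceModel(
        G=G,
        F=F,
        p=G.shape[1],
        Q_true=q_value(X, U, G, F),
        Q_robust=q_value(X, U, G, F, robust=True),
        scaled_residuals=scaled,
        per_metal_r2=pd.Series(r2),
        contributions_pct=contributions_pct(G, F, metals),
        metals=list(metals),
        q_trace=q_trace,
    )


def fit(
    X,
    U,
    p: int,
    n_starts: int = 20,
    seed: int = 0,
    max_mu_iter: int = 1500,
    max_als_iter: int = 40,
    tol: float = 1e-10,
    metals: list[str] | None = None,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> SourceModel:
    """Fit a p-factor PMF model, keeping the best of ``n_starts``
    seeded random initializations (or refining a supplied ``init``)."""
    if isinstance(X, pd.DataFrame):
        metals = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        metals = metals if metals is not None else [f"m{j}" for j in range(Xa.shape[1])]
    Ua = U.to_numpy(dtype=float) if isinstance(U, pd.DataFrame) else np.asarray(U, float)
    if Xa.shape != Ua.shape:
        raise ValueError("X and U must have the same shape")
    if not (np.all(np.isfinite(Xa)) and np.all(np.isfinite(Ua))):
        raise ValueError("X and U must be finite")
    if np.any(Ua <= 0):
        raise ValueError("uncertainties must be positive")
    n, m = Xa.shape
    if p >= min(n, m):
        raise ValueError(f"factor count p={p} must be < min(n, m)={min(n, m)}")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")

    W = 1.0 / Ua**2
    col_scale = np.maximum(Xa.mean(axis=0), 1e-12)
    rng = np.random.default_rng(seed)
    best = None
    starts = [init] if init is not None else [None] * n_starts
    for s in starts:
        if s is None:
            G0 = rng.uniform(0.2, 1.8, size=(n, p))
            F0 = rng.uniform(0.2, 1.8, size=(p, m)) * col_scale[None, :] / p
        else:
            G0, F0 = np.array(s[0], float), np.array(s[1], float)
        G1, F1, tr1 = _mu_phase(Xa, W, G0, F0, max_mu_iter, tol)
        G2, F2, tr2 = _als_phase(Xa, Ua, G1, F1, max_als_iter, tol)
        q = tr2[-1]
        if best is None or q < best[0]:
            best = (q, G2, F2, tr1 + tr2)
    _, G, F, trace = best
    G, F = _normalize(G, F)
    return _diagnose(Xa, Ua, G, F, metals, trace)


def scan_factors(
    X,
    U,
    p_range=range(3, 7),
    n_starts: int = 20,
    seed: int = 0,
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit every factor count in ``p_range`` and tabulate diagnostics:
    Q values, the Q_robust/Q_true ratio, per-metal r² and the fraction
    of scaled residuals inside [−3, 3]."""
    rows = {}
    for k, p in enumerate(p_range):
        model = fit(X, U, p, n_starts=n_starts, seed=seed + 1000 * k, **fit_kwargs)
        row = {
            "q_true": model.Q_true,
            "q_robust": model.Q_robust,
            "q_ratio": model.q_ratio,
            "frac_resid_within_3": float(
                (np.abs(model.scaled_residuals) <= 3).mean()
            ),
            "min_r2": float(model.per_metal_r2.min()),
        }
        row.update({f"r2_{m}": v for m, v in model.per_metal_r2.items()})
        rows[p] = row
    out = pd.DataFrame(rows).T
    out.index.name = "p"
    return out


@dataclass
class BootstrapResult:
    """Row-resampling bootstrap stability report for a fitted model."""

    mapping_rate: pd.Series           # % of iterations each base factor was found
    pct_low: pd.DataFrame             # 5th percentile of contributions_pct
    pct_high: pd.DataFrame            # 95th percentile
    n_boot: int
    boot_pct: np.ndarray = field(repr=False)  # n_boot × p × m (NaN if unmapped)


def bootstrap(
    X,
    U,
    base: SourceModel,
    n_boot: int = 100,
    seed: int = 0,
    max_mu_iter: int = 500,
    max_als_iter: int = 20,
) -> BootstrapResult:
    """Resample samples (rows) with replacement, refit from the base
    solution, and map each bootstrap factor to the base factor with the
    most correlated profile.

    A base factor counts as mapped in an iteration when at least one
    bootstrap factor maps to it uniquely (one-to-one assignment by
    descending correlation).
    """
    Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    Ua = U.to_numpy(dtype=float) if isinstance(U, pd.DataFrame) else np.asarray(U, float)
    rng = np.random.default_rng(seed)
    n = Xa.shape[0]
    p, m = base.F.shape
    mapped = np.zeros(p)
    boot_pct = np.full((n_boot, p, m), np.nan)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        model = fit(
            Xa[idx],
            Ua[idx],
            p,
            metals=base.metals,
            init=(base.G[idx], base.F),
            max_mu_iter=max_mu_iter,
            max_als_iter=max_als_iter,
        )
        corr = np.corrcoef(model.F, base.F)[:p, p:]
        corr = np.nan_to_num(corr, nan=-1.0)
        # greedy one-to-one assignment by descending correlation
        assign = {}
        flat = np.argsort(-corr, axis=None)
        used_b, used_base = set(), set()
        for f in flat:
            bi, ba = divmod(f, p)
            if bi in used_b or ba in used_base:
                continue
            assign[ba] = bi
            used_b.add(bi)
            used_base.add(ba)
        for ba, bi in assign.items():
            if corr[bi, ba] > 0.6:
                mapped[ba] += 1
                boot_pct[b, ba] = model.contributions_pct.to_numpy()[bi]
    rate = pd.Series(100.0 * mapped / n_boot, index=range(p), name="mapping_rate_pct")
    with np.errstate(all="ignore"):
        low = np.nanpercentile(boot_pct, 5, axis=0)
        high = np.nanpercentile(boot_pct, 95, axis=0)
    cols = base.contributions_pct.columns
    return BootstrapResult(
        mapping_rate=rate,
        pct_low=pd.DataFrame(low, columns=cols),
        pct_high=pd.DataFrame(high, columns=cols),
        n_boot=n_boot,
        boot_pct=boot_pct,
    )


def contributions_pct(G, F, metals: list[str] | None = None) -> pd.DataFrame:
    """Share (%) of each metal's total mass attributed to each factor;
    columns sum to 100 (NaN where a metal has zero reconstructed mass)."""
    G, F = np.asarray(G, float), np.asarray(F, float)
    mass = G.sum(axis=0)[:, None] * F  # p × m total mass per factor/metal
    tot = mass.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(tot > 0, 100.0 * mass / tot, np.nan)
    cols = metals if metals is not None else [f"m{j}" for j in range(F.shape[1])]
    return pd.DataFrame(pct, columns=cols)
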