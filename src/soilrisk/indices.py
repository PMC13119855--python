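"""Geo-accumulation index and Hakanson potential ecological risk indices.

Two classical soil-pollution screens:

* the Müller geo-accumulation index,
  ``Igeo = log2(C / (1.5 S))``, where ``C`` is the measured
  concentration and ``S`` the geochemical background — the factor 1.5
  absorbs natural background fluctuation;
* the Hakanson potential ecological risk index,
  ``Ei = Ti · C / S`` per metal (``Ti`` a toxicity response
  coefficient) and the comprehensive index ``RI = Σ Ei``.

RI class thresholds scale with the metal set under study; here the base
threshold is 110 (adjusted for the seven survey metals, ΣTi = 96) and
doubles per class.  All class ladders are left-closed: a boundary value
belongs to the upper class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import ReferenceDataError, ReferenceTable, SampleTable

__all__ = [
    "igeo",
    "igeo_class",
    "ei",
    "ri",
    "ei_class",
    "ri_class",
    "risk_classes",
    "IndexResult",
    "compute_indices",
    "IGEO_LABELS",
    "EI_LABELS",
    "RI_LABELS",
]

IGEO_LABELS = (
    "unpolluted",
    "low",
    "moderate",
    "moderately severe",
    "severe",
    "severely extreme",
    "extreme",
)
IGEO_BOUNDS = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)

EI_LABELS = ("low", "moderate", "considerable", "high", "very high")
EI_BOUNDS = (40.0, 80.0, 160.0, 320.0)

RI_LABELS = ("low", "moderate", "considerable", "high")


def igeo(c, s):
    """Geo-accumulation index ``log2(c / (1.5 s))``.

    Non-positive concentrations are undefined and returned as NaN;
    a non-positive background raises :class:`ReferenceDataError`.
    """
    c = np.asarray(c, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ReferenceDataError("background value must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(c > 0, np.log2(np.where(c > 0, c, np.nan) / (1.5 * s)), np.nan)
    return out if out.ndim else float(out)


def igeo_class(value):
    """Müller pollution class for an Igeo value (left-closed bins)."""
    v = np.asarray(value, dtype=float)
    idx = np.digitize(v, IGEO_BOUNDS, right=False)
    labels = np.array(IGEO_LABELS, dtype=object)[idx]
    return labels if v.ndim else str(labels)


def ei(c, s, t):
    """Per-metal potential ecological risk index ``Ei = t · c / s``."""
    c = np.asarray(c, dtype=float)
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(s <= 0):
        raise ReferenceDataError("background value must be positive")
    if np.any(t <= 0):
        raise ReferenceDataError("toxicity coefficient must be positive")
    out = t * c / s
    return out if out.ndim else float(out)


def ri(eis) -> float | np.ndarray:
    """Comprehensive index: exact sum of per-metal Ei values.

    Accepts a 1-D vector (one sample) or a 2-D samples × metals array /
    DataFrame, in which case the sum runs over metals per sample.
    """
    arr = np.asarray(eis, dtype=float)
    if arr.size == 0:
        raise ValueError("ri requires at least one metal")
    if arr.ndim <= 1:
        return float(arr.sum())
    return arr.sum(axis=1)


def ei_class(value):
    """Hakanson single-metal risk class (left-closed bins at 40/80/160/320)."""
    v = np.asarray(value, dtype=float)
    labels = np.array(EI_LABELS, dtype=object)[np.digitize(v, EI_BOUNDS)]
    return labels if v.ndim else str(labels)


def ri_class(value, ri_base: float = 110.0):
    """RI risk class with doubling thresholds from ``ri_base``."""
    if ri_base <= 0:
        raise ValueError("ri_base must be positive")
    bounds = (ri_base, 2 * ri_base, 4 * ri_base)
    v = np.asarray(value, dtype=float)
    labels = np.array(RI_LABELS, dtype=object)[np.digitize(v, bounds)]
    return labels if v.ndim else str(labels)


def risk_classes(ei_value, ri_value, ri_base: float = 110.0):
    """Class labels for a single-metal Ei and a comprehensive RI."""
    return ei_class(ei_value), ri_class(ri_value, ri_base)


@dataclass
class IndexResult:
    """Per-sample pollution-index tables for one depth layer."""

    igeo: pd.DataFrame            # samples × metals
    igeo_labels: pd.DataFrame
    ei: pd.DataFrame              # samples × metals
    ei_labels: pd.DataFrame
    ri: pd.Series                 # per sample
    ri_labels: pd.Series

    def summary(self) -> pd.DataFrame:
        """Max/min/mean of Ei per metal plus the RI column (survey-style)."""
        s = self.ei.agg(["max", "min", "mean"]).T
        s.loc["RI"] = [self.ri.max(), self.ri.min(), self.ri.mean()]
        return s


def compute_indices(
    samples: SampleTable,
    reference: ReferenceTable | None = None,
    layer: str | None = None,
    ri_base: float = 110.0,
) -> IndexResult:
    """Compute Igeo, Ei and RI (with class labels) for every sample."""
    ref = reference if reference is not None else ReferenceTable.default()
    conc = samples.concentrations(layer)
    metals = list(conc.columns)
    s = np.array([ref.background(m) for m in metals])
    t = np.array([ref.toxicity(m) for m in metals])
    ig = pd.DataFrame(igeo(conc.to_numpy(), s), columns=metals, index=conc.index)
    e = pd.DataFrame(ei(conc.to_numpy(), s, t), columns=metals, index=conc.index)
    total = pd.Series(ri(e), index=conc.index, name="RI")
    return IndexResult(
        igeo=ig,
        igeo_labels=ig.apply(lambda col: igeo_class(col.to_numpy()), axis=0),
        ei=e,
        ei_labels=e.apply(lambda col: ei_class(col.to_numpy()), axis=0),
        ri=total,
        ri_labels=pd.Series(ri_class(total.to_numpy(), ri_base), index=conc.index),
    )
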