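"""Probabilistic multi-pathway human health risk assessment.

Implements the standard USEPA RAGS soil-exposure model.  The average
daily dose (ADD, mg·kg⁻¹·d⁻¹) of a metal at soil concentration ``C``
(mg·kg⁻¹) is, per pathway:

* ingestion:   ``C · IngR · EF · ED / (BW · AT) · 10⁻⁶``
* dermal:      ``C · SA · AF · ABS · EF · ED / (BW · AT) · 10⁻⁶``
* inhalation:  ``C · InhR · EF · ED / (PEF · BW · AT)``

Non-carcinogenic hazard quotients divide the ADD (averaged over the
exposure duration, ``AT_nc = ED·365``) by the pathway reference dose;
the hazard index ``HI = Σ HQ`` flags concern above 1.  Carcinogenic
risk multiplies the lifetime-averaged ADD (``AT_ca``) by the slope
factor; total cancer risk ``TCR = Σ CR`` is screened against the
1 × 10⁻⁶ "notable" and 1 × 10⁻⁴ "unacceptable" thresholds.

Monte Carlo propagation draws concentrations from the empirical sample
distribution and exposure parameters from configurable distributions
(point, normal, lognormal, uniform, triangular; all truncated at zero),
yielding full risk distributions, exceedance probabilities and Spearman
rank sensitivities of each varying input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .core_io import (
    CARCINOGENS,
    METALS,
    PATHWAYS,
    ReferenceDataError,
    ReferenceTable,
    SampleTable,
)

__all__ = [
    "Dist",
    "ExposureScenario",
    "add",
    "hq_hi",
    "cr_tcr",
    "monte_carlo",
    "sensitivity",
    "RiskResult",
    "NOTABLE_RISK",
    "UNACCEPTABLE_RISK",
]

#: TCR screening thresholds: below 1e-6 no significant risk; above 1e-4
#: unacceptable; between them "notable but acceptable".
NOTABLE_RISK = 1e-6
UNACCEPTABLE_RISK = 1e-4


@dataclass(frozen=True)
class Dist:
    """A univariate distribution for an exposure parameter.

    kinds: ``point(value)``, ``normal(mean, sd)`` (truncated at 0),
    ``lognormal(mean, sd)`` (arithmetic moments), ``uniform(low, high)``,
    ``triangular(low, mode, high)``.
    """

    kind: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        expected = {"point": 1, "normal": 2, "lognormal": 2, "uniform": 2,
                    "triangular": 3}
        if self.kind not in expected:
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if len(self.params) != expected[self.kind]:
            raise ValueError(
                f"{self.kind} takes {expected[self.kind]} parameters, "
                f"got {len(self.params)}"
            )

    @property
    def is_point(self) -> bool:
        return self.kind == "point"

    def mean(self) -> float:
        p = self.params
        if self.kind in ("point",):
            return p[0]
        if self.kind in ("normal", "lognormal"):
            return p[0]
        if self.kind == "uniform":
            return (p[0] + p[1]) / 2
        return sum(p) / 3  # triangular

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        p = self.params
        if self.kind == "point":
            return np.full(size, p[0])
        if self.kind == "uniform":
            return rng.uniform(p[0], p[1], size)
        if self.kind == "triangular":
            return rng.triangular(p[0], p[1], p[2], size)
        if self.kind == "normal":
            out = rng.normal(p[0], p[1], size)
            bad = out < 0
            while bad.any():  # truncate at 0 by resampling
                out[bad] = rng.normal(p[0], p[1], int(bad.sum()))
                bad = out < 0
            return out
        # lognormal with arithmetic mean/sd
        mean, sd = p
        s2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - s2 / 2
        return rng.lognormal(mu, np.sqrt(s2), size)


def _d(kind, *params) -> Dist:
    return Dist(kind, tuple(float(v) for v in params))


@dataclass(frozen=True)
class ExposureScenario:
    """A population group plus the distribution of every exposure
    parameter.

    Units: IngR mg·d⁻¹; InhR m³·d⁻¹; EF d·a⁻¹; ED a; BW kg; SA cm²;
    AF mg·cm⁻²·d⁻¹; ABS –; PEF m³·kg⁻¹; AT_nc / AT_ca d.
    """

    population: str
    parameters: dict[str, Dist] = field(default_factory=dict)

    REQUIRED = ("IngR", "InhR", "EF", "ED", "BW", "SA", "AF", "ABS",
                "PEF", "AT_nc", "AT_ca")

    def __post_init__(self) -> None:
        missing = [k for k in self.REQUIRED if k not in self.parameters]
        if missing:
            raise ValueError(f"scenario missing parameters: {missing}")
        if self.parameters["AT_ca"].mean() < self.parameters["AT_nc"].mean():
            raise ValueError("AT_ca must be >= AT_nc")

    # Default parameters follow the Chinese technical-guideline /
    # USEPA-convention values of this literature: body weight lognormal,
    # soil ingestion triangular, the rest point estimates.  All values
    # are editable defaults rather than survey-specific measurements.
    @classmethod
    def child_default(cls) -> "ExposureScenario":
        return cls("child", {
            "IngR": _d("triangular", 100, 200, 300),
            "InhR": _d("point", 7.5),
            "EF": _d("point", 350),
            "ED": _d("point", 6),
            "BW": _d("lognormal", 15.9, 2.9),
            "SA": _d("point", 2800),
            "AF": _d("point", 0.2),
            "ABS": _d("point", 0.001),
            "PEF": _d("point", 1.36e9),
            "AT_nc": _d("point", 6 * 365),
            "AT_ca": _d("point", 70 * 365),
        })

    @classmethod
    def adult_female_default(cls) -> "ExposureScenario":
        return cls("adult_female", {
            "IngR": _d("triangular", 50, 100, 150),
            "InhR": _d("point", 14.5),
            "EF": _d("point", 350),
            "ED": _d("point", 24),
            "BW": _d("lognormal", 57.0, 6.5),
            "SA": _d("point", 5000),
            "AF": _d("point", 0.07),
            "ABS": _d("point", 0.001),
            "PEF": _d("point", 1.36e9),
            "AT_nc": _d("point", 24 * 365),
            "AT_ca": _d("point", 70 * 365),
        })

    @classmethod
    def adult_male_default(cls) -> "ExposureScenario":
        return cls("adult_male", {
            "IngR": _d("triangular", 50, 100, 150),
            "InhR": _d("point", 16.6),
            "EF": _d("point", 350),
            "ED": _d("point", 24),
            "BW": _d("lognormal", 66.2, 7.5),
            "SA": _d("point", 5500),
            "AF": _d("point", 0.07),
            "ABS": _d("point", 0.001),
            "PEF": _d("point", 1.36e9),
            "AT_nc": _d("point", 24 * 365),
            "AT_ca": _d("point", 70 * 365),
        })

    @classmethod
    def default(cls, population: str) -> "ExposureScenario":
        try:
            return {
                "child": cls.child_default,
                "adult_female": cls.adult_female_default,
                "adult_male": cls.adult_male_default,
            }[population]()
        except KeyError:
            raise ValueError(f"unknown population {population!r}") from None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExposureScenario":
        """Load a scenario from YAML: ``population`` plus a mapping of
        parameter name to ``{kind: ..., params: [...]}``."""
        spec = yaml.safe_load(Path(path).read_text())
        params = {
            name: Dist(d["kind"], tuple(float(v) for v in d["params"]))
            for name, d in spec["parameters"].items()
        }
        return cls(spec["population"], params)


def add(pathway: str, c, params: dict, horizon: str = "nc"):
    """Average daily dose for one pathway; vectorized over draws.

    ``params`` maps parameter names to scalars or draw arrays;
    ``horizon`` selects ``AT_nc`` or ``AT_ca``.
    """
    if pathway not in PATHWAYS:
        raise ValueError(f"unknown pathway {pathway!r}")
    if horizon not in ("nc", "ca"):
        raise ValueError(f"unknown horizon {horizon!r}")
    c = np.asarray(c, dtype=float)
    at = np.asarray(params["AT_nc" if horizon == "nc" else "AT_ca"], float)
    bw = np.asarray(params["BW"], float)
    if np.any(bw <= 0) or np.any(at <= 0):
        raise ValueError("BW and AT must be positive")
    ef_ed = np.asarray(params["EF"], float) * np.asarray(params["ED"], float)
    if pathway == "ingestion":
        out = c * np.asarray(params["IngR"], float) * ef_ed / (bw * at) * 1e-6
    elif pathway == "dermal":
        out = (
            c * np.asarray(params["SA"], float) * np.asarray(params["AF"], float)
            * np.asarray(params["ABS"], float) * ef_ed / (bw * at) * 1e-6
        )
    else:
        pef = np.asarray(params["PEF"], float)
        if np.any(pef <= 0):
            raise ValueError("PEF must be positive")
        out = c * np.asarray(params["InhR"], float) * ef_ed / (pef * bw * at)
    return out if out.ndim else float(out)


def hq_hi(adds: dict, reference: ReferenceTable):
    """Hazard quotients per metal (summed over pathways) and their sum HI.

    ``adds`` maps ``(metal, pathway)`` to an ADD value or draw array.
    """
    metals = sorted({m for m, _ in adds}, key=list(METALS).index)
    hq = {}
    for m in metals:
        total = 0.0
        for (mm, pw), dose in adds.items():
            if mm != m:
                continue
            total = total + np.asarray(dose, float) / reference.reference_dose(m, pw)
        hq[m] = total
    hi = sum(hq.values())
    return hq, hi


def cr_tcr(adds: dict, reference: ReferenceTable):
    """Carcinogenic risk per metal (ADD × SF over pathways with an SF)
    and the total TCR.  Requesting a non-carcinogen raises."""
    metals = sorted({m for m, _ in adds}, key=list(METALS).index)
    cr = {}
    for m in metals:
        if m not in CARCINOGENS:
            raise ReferenceDataError(
                f"slope factor requested for non-carcinogen {m!r}"
            )
        total = 0.0
        for (mm, pw), dose in adds.items():
            if mm != m or not reference.has_slope_factor(m, pw):
                continue
            total = total + np.asarray(dose, float) * reference.slope_factor(m, pw)
        cr[m] = total
    tcr = sum(cr.values())
    return cr, tcr


@dataclass
class RiskResult:
    """Monte Carlo risk draws, summaries and stored inputs."""

    population: str
    mode: str
    n_iter: int
    inputs: pd.DataFrame          # per-draw varying inputs (conc + params)
    hq: pd.DataFrame              # draws × metals
    hi: np.ndarray
    cr: pd.DataFrame              # draws × carcinogens
    tcr: np.ndarray
    exceedance: dict[str, float]
    outer_exceedance: pd.DataFrame | None = None  # 2d mode only

    def summary(self) -> pd.DataFrame:
        """Mean and 5th/95th percentiles of HQ, HI, CR, TCR."""
        rows = {}
        for m in self.hq.columns:
            rows[f"HQ_{m}"] = self.hq[m].to_numpy()
        rows["HI"] = self.hi
        for m in self.cr.columns:
            rows[f"CR_{m}"] = self.cr[m].to_numpy()
        rows["TCR"] = self.tcr
        return pd.DataFrame(
            {
                name: {
                    "mean": v.mean(),
                    "p5": np.percentile(v, 5),
                    "p95": np.percentile(v, 95),
                }
                for name, v in rows.items()
            }
        ).T


def _one_batch(conc_pool, scenario, reference, n, rng):
    inputs = {}
    for m in conc_pool:
        pool = conc_pool[m]
        inputs[f"C_{m}"] = pool[rng.integers(0, len(pool), size=n)]
    params = {}
    for name, dist in scenario.parameters.items():
        draws = dist.sample(rng, n)
        params[name] = draws
        if not dist.is_point:
            inputs[name] = draws
    adds_nc, adds_ca = {}, {}
    for m in conc_pool:
        for pw in PATHWAYS:
            adds_nc[(m, pw)] = add(pw, inputs[f"C_{m}"], params, "nc")
        if m in CARCINOGENS:
            for pw in PATHWAYS:
                adds_ca[(m, pw)] = add(pw, inputs[f"C_{m}"], params, "ca")
    hq, hi = hq_hi(adds_nc, reference)
    cr, tcr = cr_tcr(adds_ca, reference)
    return pd.DataFrame(inputs), pd.DataFrame(hq), hi, pd.DataFrame(cr), tcr


def monte_carlo(
    samples: SampleTable,
    scenario: ExposureScenario,
    reference: ReferenceTable | None = None,
    n_iter: int = 10000,
    seed: int = 0,
    mode: str = "1d",
    layer: str = "surface",
    n_outer: int = 100,
    n_inner: int = 1000,
) -> RiskResult:
    """Monte Carlo propagation of concentration and exposure variability.

    ``1d``: every iteration draws one concentration per metal from the
    empirical distribution of the chosen layer plus one value per
    exposure parameter.  ``2d``: an outer loop bootstrap-resamples the
    concentration dataset (propagating sampling uncertainty) and an
    inner loop draws exposure variability; exceedance probabilities are
    then reported with their spread across outer iterations.
    """
    if n_iter < 1000:
        raise ValueError("n_iter must be >= 1000 for reported runs")
    if mode not in ("1d", "2d"):
        raise ValueError(f"unknown mode {mode!r}")
    ref = reference if reference is not None else ReferenceTable.default()
    conc = samples.concentrations(layer)
    if conc.empty:
        raise ValueError(f"no samples in layer {layer!r}")
    pool = {m: conc[m].to_numpy(dtype=float) for m in conc.columns}
    rng = np.random.default_rng(seed)

    if mode == "1d":
        inputs, hq, hi, cr, tcr = _one_batch(pool, scenario, ref, n_iter, rng)
        outer = None
    else:
        parts = []
        rates = []
        for _ in range(n_outer):
            n0 = len(next(iter(pool.values())))
            idx = rng.integers(0, n0, size=n0)
            boot_pool = {m: v[idx] for m, v in pool.items()}
            batch = _one_batch(boot_pool, scenario, ref, n_inner, rng)
            parts.append(batch)
            rates.append(
                {
                    "p_hi_gt_1": float((batch[2] > 1).mean()),
                    "p_tcr_gt_1e6": float((batch[4] > NOTABLE_RISK).mean()),
                    "p_tcr_gt_1e4": float((batch[4] > UNACCEPTABLE_RISK).mean()),
                }
            )
        inputs = pd.concat([b[0] for b in parts], ignore_index=True)
        hq = pd.concat([b[1] for b in parts], ignore_index=True)
        hi = np.concatenate([b[2] for b in parts])
        cr = pd.concat([b[3] for b in parts], ignore_index=True)
        tcr = np.concatenate([b[4] for b in parts])
        outer = pd.DataFrame(rates)

    exceedance = {
        "p_hi_gt_1": float((hi > 1).mean()),
        "p_tcr_gt_1e6": float((tcr > NOTABLE_RISK).mean()),
        "p_tcr_gt_1e4": float((tcr > UNACCEPTABLE_RISK).mean()),
    }
    return RiskResult(
        population=scenario.population,
        mode=mode,
        n_iter=len(hi),
        inputs=inputs,
        hq=hq,
        hi=np.asarray(hi),
        cr=cr,
        tcr=np.asarray(tcr),
        exceedance=exceedance,
        outer_exceedance=outer,
    )


def sensitivity(result: RiskResult, output: str = "HI") -> pd.DataFrame:
    """Spearman rank correlation of every varying input with HI or TCR.

    Returns a table sorted by |ρ| with a contribution share
    ``|ρ|/Σ|ρ|·100``; constant inputs get NaN and are excluded from the
    shares.
    """
    if output == "HI":
        y = result.hi
    elif output == "TCR":
        y = result.tcr
    else:
        raise ValueError("output must be 'HI' or 'TCR'")
    rows = {}
    for col in result.inputs.columns:
        x = result.inputs[col].to_numpy()
        if np.ptp(x) == 0:
            rows[col] = float("nan")
        else:
            rows[col] = float(stats.spearmanr(x, y).statistic)
    rho = pd.Series(rows, name="rho")
    abs_sum = rho.abs().sum(skipna=True)
    share = rho.abs() / abs_sum * 100 if abs_sum > 0 else rho * float("nan")
    out = pd.DataFrame({"rho": rho, "contribution_pct": share})
    return out.sort_values("rho", key=lambda s: s.abs(), ascending=False)
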