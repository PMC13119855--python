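"""Domain containers, reference data and CSV I/O shared by every analysis stage.

The package works on long-form site-sample tables: one row per
(sampling point, depth layer) with planar coordinates, pH and the
concentrations of the seven survey metals (Cd, Pb, Cu, Zn, Ni, Hg, As)
in mg·kg⁻¹.  Values reported below the method detection limit (MDL)
appear in input files as the token ``"ND"``; on read they are replaced
by MDL/2 and flagged as censored so that downstream stages (notably the
PMF uncertainty model) can treat them appropriately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "METALS",
    "DEPTH_LAYERS",
    "PATHWAYS",
    "CARCINOGENS",
    "SHANGHAI_BACKGROUND",
    "TOXICITY_COEFFICIENT",
    "METHOD_DETECTION_LIMIT",
    "SURVEY_SURFACE_STATS",
    "SchemaError",
    "ValidationError",
    "ReferenceDataError",
    "ReferenceTable",
    "SampleTable",
    "read_samples",
    "write_table",
]

#: The seven metals measured in the survey, in reporting order.
METALS: tuple[str, ...] = ("Cd", "Pb", "Cu", "Zn", "Ni", "Hg", "As")

#: Fixed sampling depth layers: 0–0.5 m, 0.5–1.5 m, ≥1.5 m.
DEPTH_LAYERS: tuple[str, ...] = ("surface", "subsurface", "saturated")

#: Human-exposure pathways considered by the health-risk model.
PATHWAYS: tuple[str, ...] = ("ingestion", "dermal", "inhalation")

#: Metals with a cancer slope factor in the default reference table.
CARCINOGENS: tuple[str, ...] = ("Cd", "Pb", "As", "Ni")

#: Soil geochemical background values of Shanghai, mg·kg⁻¹.
SHANGHAI_BACKGROUND: dict[str, float] = {
    "Cd": 0.13, "Pb": 25.5, "Cu": 28.6, "Zn": 86.1,
    "Ni": 31.9, "Hg": 0.10, "As": 9.10,
}

#: Hakanson toxicity response coefficients (dimensionless; sum = 96).
TOXICITY_COEFFICIENT: dict[str, float] = {
    "Cd": 30, "Pb": 5, "Cu": 5, "Zn": 1, "Ni": 5, "Hg": 40, "As": 10,
}

#: Method detection limits of the analytical protocol, mg·kg⁻¹.
METHOD_DETECTION_LIMIT: dict[str, float] = {
    "Cd": 0.03, "Pb": 0.10, "Cu": 1.00, "Zn": 0.50,
    "Ni": 5.00, "Hg": 0.01, "As": 0.002,
}

#: Published surface-layer descriptive statistics (max/min/mean, mg·kg⁻¹)
#: of the Pudong New District redevelopment-site survey.  Used as the
#: worked-example input for the ecological-risk indices.
SURVEY_SURFACE_STATS: pd.DataFrame = pd.DataFrame(
    {
        "max":  [1.27, 174.0, 336.0, 827.0, 130.0, 0.37, 12.6],
        "min":  [0.06, 17.3, 15.0, 29.8, 11.6, 0.03, 5.39],
        "mean": [0.17, 30.8, 43.4, 156.0, 44.7, 0.11, 8.87],
    },
    index=list(METALS),
)

# Default toxicological reference doses, mg·kg⁻¹·d⁻¹.  Oral values follow
# the USEPA IRIS set conventionally used for soil exposure; dermal values
# default to the oral RfD; inhalation values are RfC-derived
# (RfC mg·m⁻³ × 20 m³·d⁻¹ / 70 kg).  These are editable defaults, not
# survey-specific values.
DEFAULT_RFD: dict[str, dict[str, float]] = {
    "ingestion": {
        "Cd": 1.0e-3, "Pb": 3.5e-3, "Cu": 4.0e-2, "Zn": 3.0e-1,
        "Ni": 2.0e-2, "Hg": 3.0e-4, "As": 3.0e-4,
    },
    "dermal": {
        "Cd": 1.0e-3, "Pb": 3.5e-3, "Cu": 4.0e-2, "Zn": 3.0e-1,
        "Ni": 2.0e-2, "Hg": 3.0e-4, "As": 3.0e-4,
    },
    "inhalation": {
        "Cd": 2.9e-6, "Pb": 3.52e-3, "Cu": 4.02e-2, "Zn": 3.0e-1,
        "Ni": 4.0e-6, "Hg": 8.6e-5, "As": 4.3e-6,
    },
}

# Default cancer slope factors, (mg·kg⁻¹·d⁻¹)⁻¹, for the four carcinogens.
# Oral values for As (1.5) and Cd (6.1) are the ones conventionally used
# in this literature; Ni is treated as an inhalation-only carcinogen
# (IARC route-specific evidence).  Editable defaults.
DEFAULT_SF: dict[str, dict[str, float]] = {
    "ingestion": {"Cd": 6.1, "Pb": 8.5e-3, "As": 1.5},
    "inhalation": {"Cd": 6.3, "As": 15.1, "Ni": 0.84},
}


class SchemaError(ValueError):
    """An input table is missing required columns or has a bad header."""


class ValidationError(ValueError):
    """An input table has values violating a domain invariant."""


class ReferenceDataError(ValueError):
    """A reference-table entry is missing or invalid."""


@dataclass(frozen=True)
class ReferenceTable:
    """Per-metal reference data: background, toxicity, MDL, RfD and SF.

    Parameters
    ----------
    values
        DataFrame indexed by metal with columns ``background`` (Si,
        mg·kg⁻¹), ``toxicity`` (Ti, dimensionless) and ``mdl`` (mg·kg⁻¹).
    rfd
        Reference doses per pathway, ``{pathway: {metal: mg·kg⁻¹·d⁻¹}}``.
    sf
        Cancer slope factors per pathway for carcinogens.
    """

    values: pd.DataFrame
    rfd: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    sf: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"background", "toxicity", "mdl"}
        missing = required - set(self.values.columns)
        if missing:
            raise SchemaError(f"reference table missing columns: {sorted(missing)}")
        for col in required:
            bad = self.values.index[~(self.values[col] > 0)]
            if len(bad):
                raise ReferenceDataError(
                    f"non-positive {col} for metals: {list(bad)}"
                )

    @classmethod
    def default(cls) -> "ReferenceTable":
        """The shipped reference table (Shanghai backgrounds, Hakanson Ti,
        survey MDLs, default RfD/SF)."""
        values = pd.DataFrame(
            {
                "background": SHANGHAI_BACKGROUND,
                "toxicity": TOXICITY_COEFFICIENT,
                "mdl": METHOD_DETECTION_LIMIT,
            }
        ).loc[list(METALS)]
        return cls(values=values, rfd=DEFAULT_RFD, sf=DEFAULT_SF)

    @property
    def metals(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    def background(self, metal: str) -> float:
        return self._get("background", metal)

    def toxicity(self, metal: str) -> float:
        return self._get("toxicity", metal)

    def mdl(self, metal: str) -> float:
        return self._get("mdl", metal)

    def _get(self, col: str, metal: str) -> float:
        if metal not in self.values.index:
            raise ReferenceDataError(f"no reference data for metal {metal!r}")
        return float(self.values.at[metal, col])

    def reference_dose(self, metal: str, pathway: str) -> float:
        try:
            return float(self.rfd[pathway][metal])
        except KeyError:
            raise ReferenceDataError(
                f"missing RfD for metal {metal!r}, pathway {pathway!r}"
            ) from None

    def slope_factor(self, metal: str, pathway: str) -> float:
        if metal not in CARCINOGENS:
            raise ReferenceDataError(
                f"slope factor requested for non-carcinogen {metal!r}"
            )
        try:
            return float(self.sf[pathway][metal])
        except KeyError:
            raise ReferenceDataError(
                f"missing SF for metal {metal!r}, pathway {pathway!r}"
            ) from None

    def has_slope_factor(self, metal: str, pathway: str) -> bool:
        return metal in self.sf.get(pathway, {})


REQUIRED_COLUMNS = ("sample_id", "x", "y", "depth_layer")


@dataclass
class SampleTable:
    """Long-form site samples: one row per (sampling point, depth layer).

    ``data`` holds columns ``sample_id, x, y, depth_layer, pH`` plus one
    concentration column per metal (mg·kg⁻¹).  ``censored`` is a boolean
    frame (same index, metal columns) flagging below-MDL entries whose
    concentration was substituted with MDL/2.
    """

    data: pd.DataFrame
    censored: pd.DataFrame | None = None
    coordinate_units: str = "m"
    metals: tuple[str, ...] = METALS

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        missing += [m for m in self.metals if m not in self.data.columns]
        if missing:
            raise SchemaError(f"sample table missing columns: {missing}")
        if "pH" not in self.data.columns:
            self.data = self.data.assign(pH=np.nan)
        bad_layer = set(self.data["depth_layer"]) - set(DEPTH_LAYERS)
        if bad_layer:
            raise ValidationError(f"unknown depth layers: {sorted(bad_layer)}")
        conc = self.data[list(self.metals)].to_numpy(dtype=float)
        neg = np.argwhere(conc < 0)
        if len(neg):
            i, j = neg[0]
            raise ValidationError(
                f"negative concentration of {self.metals[j]} in row "
                f"{self.data['sample_id'].iloc[i]!r}"
            )
        dup = self.data.duplicated(subset=["sample_id", "depth_layer"])
        if dup.any():
            raise ValidationError(
                "duplicate (sample_id, depth_layer) pairs: "
                f"{self.data.loc[dup, 'sample_id'].tolist()[:5]}"
            )
        if self.censored is None:
            self.censored = pd.DataFrame(
                False, index=self.data.index, columns=list(self.metals)
            )
        if self.coordinate_units not in ("m", "deg"):
            raise ValidationError(
                f"coordinate_units must be 'm' or 'deg', got {self.coordinate_units!r}"
            )
        if self.coordinate_units == "deg":
            warnings.warn(
                "coordinates are in degrees; IDW distances will be in degree units",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.data)

    def layer(self, name: str) -> "SampleTable":
        """Subset to one depth layer (keeps censoring flags aligned)."""
        if name not in DEPTH_LAYERS:
            raise ValidationError(f"unknown depth layer {name!r}")
        mask = self.data["depth_layer"] == name
        return SampleTable(
            data=self.data.loc[mask].reset_index(drop=True),
            censored=self.censored.loc[mask].reset_index(drop=True),
            coordinate_units=self.coordinate_units,
            metals=self.metals,
        )

    def concentrations(self, layer: str | None = None) -> pd.DataFrame:
        """Metal concentration matrix (rows = samples, columns = metals)."""
        t = self if layer is None else self.layer(layer)
        return t.data[list(t.metals)].astype(float)

    def coordinates(self, layer: str | None = None) -> np.ndarray:
        t = self if layer is None else self.layer(layer)
        return t.data[["x", "y"]].to_numpy(dtype=float)


def read_samples(
    path: str | Path,
    reference: ReferenceTable | None = None,
    coordinate_units: str = "m",
) -> SampleTable:
    """Read a site-sample CSV, substituting ``"ND"`` cells with MDL/2.

    Below-detection cells are flagged in the returned table's
    ``censored`` frame so the PMF stage can apply the below-MDL
    uncertainty branch while index/RF/MC stages use the MDL/2 value.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ref = reference if reference is not None else ReferenceTable.default()
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    for col in REQUIRED_COLUMNS + METALS:
        if col not in raw.columns:
            raise SchemaError(f"input CSV missing column {col!r}")
    data = raw.copy()
    censored = pd.DataFrame(False, index=raw.index, columns=list(METALS))
    for m in METALS:
        nd = raw[m].str.strip().str.upper() == "ND"
        censored[m] = nd
        vals = pd.to_numeric(raw[m].where(~nd), errors="raise")
        data[m] = vals.where(~nd, ref.mdl(m) / 2.0)
    for col in ("x", "y"):
        data[col] = pd.to_numeric(data[col], errors="raise")
    if "pH" in data.columns:
        data["pH"] = pd.to_numeric(data["pH"], errors="coerce")
    return SampleTable(
        data=data.reset_index(drop=True),
        censored=censored.reset_index(drop=True),
        coordinate_units=coordinate_units,
    )


def write_table(table: SampleTable | pd.DataFrame, path: str | Path) -> None:
    """Write a result table (or a :class:`SampleTable`) to CSV.

    Writing uses full float precision so ``read(write(t))`` round-trips
    exactly; censored cells of a :class:`SampleTable` are re-emitted as
    ``"ND"``.
    """
    path = Path(path)
    if isinstance(table, SampleTable):
        out = table.data.copy()
        for m in table.metals:
            col = out[m].astype(object)
            col[table.censored[m].to_numpy()] = "ND"
            out[m] = col
    else:
        out = table
    if len(out) == 0:
        raise ValueError("refusing to write an empty table")
    out.to_csv(path, index=isinstance(out.index, pd.MultiIndex) or out.index.name is not None)
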