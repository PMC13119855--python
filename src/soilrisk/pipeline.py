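"""End-to-end orchestration: generate → describe → indices → IDW → PMF →
RF → health risk, driven by one YAML config and one seed.

Each stage draws its randomness from a named substream derived from the
config seed, so stages are independently reproducible and the whole run
is deterministic: the same config and seed yield byte-identical output
CSVs.  A manifest records per-stage outputs and timings.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import idw, indices, pmf, rf, risk
from .core_io import DEPTH_LAYERS, METALS, ReferenceTable, SampleTable, write_table
from .synthetic import GeneratorSpec, generate

__all__ = ["RunConfig", "RunManifest", "StageError", "describe", "run_all"]

_STAGES = ("generate", "describe", "indices", "idw", "pmf", "rf", "risk")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Pipeline settings; every field has a reportable default."""

    seed: int = 0
    n_points: int = 252
    noise_cv: float = 0.05
    # PMF
    pmf_factors: int = 4
    pmf_scan: tuple[int, int] = (3, 6)
    pmf_n_starts: int = 20
    pmf_bootstrap: int = 100
    pmf_rsd: float = 0.2
    # IDW
    idw_power: float = 2.0
    idw_neighbors: int | None = None
    idw_grid: tuple[int, int] = (50, 50)
    # RF
    rf_fraction: float = 0.7
    rf_trees: int = 500
    rf_targets: tuple[str, ...] = ("Cd",)
    # Monte Carlo
    mc_iterations: int = 10000
    mc_mode: str = "1d"
    mc_populations: tuple[str, ...] = ("child", "adult_female", "adult_male")
    # stage toggles for quick runs
    run_scan: bool = False
    run_bootstrap: bool = False
    outdir: str = "run_output"

    def __post_init__(self) -> None:
        if not 0 < self.rf_fraction < 1:
            raise ValueError("rf_fraction must be in (0, 1)")
        if self.mc_iterations < 1000:
            raise ValueError("mc_iterations must be >= 1000 for reported runs")
        for pop in self.mc_populations:
            if pop not in ("child", "adult_female", "adult_male"):
                raise ValueError(f"unknown population {pop!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("pmf_scan", "idw_grid", "rf_targets", "mc_populations"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        """Named substream: independent, reproducible per-stage seed."""
        idx = _STAGES.index(stage)
        return int(
            np.random.SeedSequence([self.seed, idx]).generate_state(1)[0] % 2**31
        )


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: dict[str, dict] = field(default_factory=dict)

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def describe(samples: SampleTable) -> pd.DataFrame:
    """Per metal × layer descriptive statistics: max, min, mean, sample
    SD and CV (%).  Layers with fewer than 2 samples are omitted with a
    warning column note."""
    rows = []
    for layer in DEPTH_LAYERS:
        sub = samples.data[samples.data["depth_layer"] == layer]
        if len(sub) < 2:
            continue
        for m in samples.metals:
            v = sub[m].astype(float)
            mean = v.mean()
            sd = v.std(ddof=1)  # sample SD
            rows.append(
                {
                    "metal": m,
                    "layer": layer,
                    "max": v.max(),
                    "min": v.min(),
                    "mean": mean,
                    "sd": sd,
                    "cv_pct": sd / mean * 100 if mean != 0 else float("nan"),
                }
            )
    if not rows:
        raise ValueError("need at least 2 samples in some layer")
    return pd.DataFrame(rows)


def _stage(manifest: RunManifest, name: str):
    class _Ctx:
        def __init__(self):
            self.t0 = None
            self.outputs: list[str] = []

        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            manifest.stages[name] = {
                "outputs": self.outputs,
                "seconds": round(time.perf_counter() - self.t0, 3),
            }
            return False

    return _Ctx()


def run_all(
    config: RunConfig | str | Path,
    reference: ReferenceTable | None = None,
    quiet: bool = True,
) -> RunManifest:
    """Execute every stage in dependency order under one seed.

    Writes all result CSVs plus ``manifest.json`` under
    ``config.outdir`` and returns the manifest.
    """
    cfg = config if isinstance(config, RunConfig) else RunConfig.from_yaml(config)
    ref = reference if reference is not None else ReferenceTable.default()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(asdict(cfg), sort_keys=True, default=str)
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        seed=cfg.seed,
        version=_package_version(),
    )

    def log(msg):
        if not quiet:
            print(msg)

    with _stage(manifest, "generate") as st:
        spec = GeneratorSpec(
            n_points=cfg.n_points, noise_cv=cfg.noise_cv, seed=cfg.stage_seed("generate")
        )
        table, truth = generate(spec, ref)
        write_table(table, out / "samples.csv")
        truth["G_true"].to_csv(out / "truth_G.csv", index=False)
        truth["F_true"].to_csv(out / "truth_F.csv")
        st.outputs += ["samples.csv", "truth_G.csv", "truth_F.csv"]
        log(f"generate: {len(table)} records ({cfg.n_points} points × 3 layers)")

    with _stage(manifest, "describe") as st:
        stats = describe(table)
        stats.to_csv(out / "descriptive_stats.csv", index=False)
        st.outputs.append("descriptive_stats.csv")

    with _stage(manifest, "indices") as st:
        res = indices.compute_indices(table, ref, layer="surface")
        frame = res.ei.copy()
        frame.columns = [f"Ei_{m}" for m in res.ei.columns]
        for m in res.igeo.columns:
            frame[f"Igeo_{m}"] = res.igeo[m]
        frame["RI"] = res.ri
        frame["RI_class"] = res.ri_labels
        frame.insert(0, "sample_id", table.layer("surface").data["sample_id"].values)
        frame.to_csv(out / "indices_surface.csv", index=False)
        st.outputs.append("indices_surface.csv")
        log(f"indices: mean RI {res.ri.mean():.1f}")

    with _stage(manifest, "idw") as st:
        surf = table.layer("surface")
        xy = surf.coordinates()
        cv_rows = {}
        for m in surf.metals:
            cv_rows[m] = asdict(
                idw.loo_crossvalidate(
                    xy, surf.data[m].to_numpy(float),
                    power=cfg.idw_power, k=cfg.idw_neighbors,
                )
            )
        pd.DataFrame(cv_rows).T.to_csv(out / "idw_cv.csv")
        bbox = (xy[:, 0].min(), xy[:, 1].min(), xy[:, 0].max(), xy[:, 1].max())
        grid = idw.grid_predict(
            xy, surf.data[surf.metals[0]].to_numpy(float), bbox, cfg.idw_grid,
            power=cfg.idw_power, k=cfg.idw_neighbors,
        )
        grid.to_csv(out / f"idw_surface_{surf.metals[0]}.csv", index=False)
        st.outputs += ["idw_cv.csv", f"idw_surface_{surf.metals[0]}.csv"]

    with _stage(manifest, "pmf") as st:
        X = table.concentrations("surface")
        U = pmf.build_uncertainty(X, ref, rsd=cfg.pmf_rsd)
        model = pmf.fit(
            X, U, cfg.pmf_factors, n_starts=cfg.pmf_n_starts,
            seed=cfg.stage_seed("pmf"),
        )
        pd.DataFrame(model.G, columns=[f"F{k+1}" for k in range(model.p)]).to_csv(
            out / "pmf_G.csv", index=False
        )
        pd.DataFrame(model.F, columns=model.metals).to_csv(out / "pmf_F.csv", index=False)
        model.contributions_pct.to_csv(out / "pmf_contributions_pct.csv", index=False)
        diag = {
            "q_true": model.Q_true, "q_robust": model.Q_robust,
            "q_ratio": model.q_ratio,
        }
        diag.update({f"r2_{m}": v for m, v in model.per_metal_r2.items()})
        pd.DataFrame([diag]).to_csv(out / "pmf_diagnostics.csv", index=False)
        st.outputs += ["pmf_G.csv", "pmf_F.csv", "pmf_contributions_pct.csv",
                       "pmf_diagnostics.csv"]
        if cfg.run_scan:
            scan = pmf.scan_factors(
                X, U, range(cfg.pmf_scan[0], cfg.pmf_scan[1] + 1),
                n_starts=cfg.pmf_n_starts, seed=cfg.stage_seed("pmf"),
            )
            scan.to_csv(out / "pmf_scan.csv")
            st.outputs.append("pmf_scan.csv")
        if cfg.run_bootstrap:
            boot = pmf.bootstrap(
                X, U, model, n_boot=cfg.pmf_bootstrap, seed=cfg.stage_seed("pmf") + 1
            )
            boot.mapping_rate.to_frame().to_csv(out / "pmf_bootstrap.csv")
            st.outputs.append("pmf_bootstrap.csv")
        log(f"pmf: Q_true {model.Q_true:.1f}, min r2 {model.per_metal_r2.min():.3f}")

    with _stage(manifest, "rf") as st:
        train, valid = rf.split(table, cfg.rf_fraction, seed=cfg.stage_seed("rf"))
        metrics = {}
        for m in cfg.rf_targets:
            pred = rf.train_predict(
                train, valid, m, n_trees=cfg.rf_trees, seed=cfg.stage_seed("rf")
            )
            metrics[m] = asdict(rf.evaluate(valid.data[m].to_numpy(float), pred))
        pd.DataFrame(metrics).T.to_csv(out / "rf_metrics.csv")
        st.outputs.append("rf_metrics.csv")

    with _stage(manifest, "risk") as st:
        rows = {}
        for pop in cfg.mc_populations:
            scenario = risk.ExposureScenario.default(pop)
            res = risk.monte_carlo(
                table, scenario, ref, n_iter=cfg.mc_iterations,
                seed=cfg.stage_seed("risk"), mode=cfg.mc_mode,
            )
            res.summary().to_csv(out / f"risk_summary_{pop}.csv")
            risk.sensitivity(res, "HI").to_csv(out / f"risk_sensitivity_{pop}.csv")
            rows[pop] = res.exceedance
            st.outputs += [f"risk_summary_{pop}.csv", f"risk_sensitivity_{pop}.csv"]
        pd.DataFrame(rows).T.to_csv(out / "risk_exceedance.csv")
        st.outputs.append("risk_exceedance.csv")

    manifest.save(out / "manifest.json")
    return manifest


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("soilrisk")
    except PackageNotFoundError:
        return "unknown"
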