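# soilrisk

Source apportionment and risk assessment for soil heavy-metal site
surveys: pollution indices, uncertainty-weighted PMF receptor
modelling, IDW spatial interpolation, random-forest concentration
prediction and probabilistic (Monte Carlo) human health risk — the
analysis chain used for contaminated-site investigations such as the
redevelopment-site survey of Pudong New District, Shanghai (252
sampling points × 3 depth layers, seven metals: Cd, Pb, Cu, Zn, Ni,
Hg, As).

It is written for environmental scientists and site assessors who want
the whole chain reproducible from one seed, and ships a synthetic
survey generator with a known 4-source mixing structure so every stage
can be validated against ground truth.

## Methods at a glance

* **Geo-accumulation index** — `Igeo = log₂(Cᵢ / 1.5·Sᵢ)` with the
  Müller class ladder; `Sᵢ` are the Shanghai soil backgrounds.
* **Potential ecological risk** — Hakanson `Eᵢ = Tᵢ·Cᵢ/Sᵢ` and
  `RI = Σ Eᵢ` (ΣTᵢ = 96 for this metal set; RI classes double from a
  base threshold of 110).
* **PMF** — non-negative bilinear model `X ≈ G·F` minimising
  `Q = ΣΣ((xᵢⱼ − Σₖ gᵢₖfₖⱼ)/uᵢⱼ)²` with per-cell uncertainties
  `u = (5/6)·MDL` below the detection limit and
  `u = √((x·RSD)² + (0.5·MDL)²)` above it; multiplicative updates plus
  alternating weighted NNLS, multistart, factor-scan, bootstrap
  stability and per-metal contribution percentages.
* **IDW** — distance-decay interpolation (`w ∝ d⁻ᵖ`) with leave-one-out
  RMSE / MAPE / RMSSE cross-validation.
* **Random forest** — seeded 70/30 split, bagged trees, MAE/RMSE and
  two R² conventions (standard and explained-variance ratio).
* **Health risk** — USEPA RAGS average daily doses over ingestion,
  dermal and inhalation pathways; `HI = Σ ADD/RfD`,
  `TCR = Σ ADD·SF`; 1-D or 2-D Monte Carlo with empirical
  concentration draws, exceedance probabilities against the 10⁻⁶/10⁻⁴
  thresholds and Spearman rank sensitivities.

## Worked example

```python
from soilrisk.synthetic import GeneratorSpec, generate
from soilrisk.indices import compute_indices
from soilrisk import pmf, risk

table, truth = generate(GeneratorSpec(seed=7, noise_cv=0.05))

idx = compute_indices(table, layer="surface")
print(round(idx.ri.mean(), 2))          # 122.24  -> "moderate" RI class

X = table.concentrations("surface")
U = pmf.build_uncertainty(X)
model = pmf.fit(X, U, p=4, n_starts=20, seed=1)
print(round(model.Q_true, 1), round(model.per_metal_r2.min(), 3))
# 39.9 0.998
print(model.contributions_pct.round(1)["As"].tolist())
# [7.6, 10.4, 14.3, 67.7]   -> the As column is dominated by one factor

res = risk.monte_carlo(table, risk.ExposureScenario.default("child"),
                       n_iter=10000, seed=1)
print(res.exceedance)
# {'p_hi_gt_1': 0.0524, 'p_tcr_gt_1e6': 1.0, 'p_tcr_gt_1e4': 0.0}
```

Reading: the synthetic survey sits in the "moderate" ecological-risk
band (RI between 110 and 220); the four-factor PMF reconstructs every
metal with r² ≥ 0.998 and attributes ~68 % of arsenic to the
natural-background-like factor; for children the hazard index exceeds
1 in ~5 % of draws while total cancer risk always sits in the
"notable but acceptable" 10⁻⁶–10⁻⁴ band.

The same chain runs from the shell:

```sh
soilrisk run --config examples/demo.yaml
```

writing sample tables, index tables, IDW surfaces and CV metrics, PMF
matrices and diagnostics, RF metrics, risk summaries and a
`manifest.json` under `demo_run/`.

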