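# Methods

This note documents the models implemented in `soilrisk`, the defaults
they ship with, and the reasoning behind the choices that were
genuinely open. Nothing here reports an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Pollution indices

The geo-accumulation index `Igeo = log₂(C / 1.5·S)` compares a measured
concentration `C` against 1.5× the geochemical background `S`; the
factor 1.5 absorbs natural background fluctuation. Classes follow the
Müller ladder (unpolluted below 0, then unit-width classes up to
"extreme" at ≥ 5). The Hakanson indices are `Eᵢ = Tᵢ·Cᵢ/Sᵢ` per metal
and `RI = Σᵢ Eᵢ`, with the toxicity coefficients
Cd 30, Pb 5, Cu 5, Zn 1, Ni 5, Hg 40, As 10 (sum 96) and the Shanghai
backgrounds as `S`. Because the RI class ladder depends on the metal
set under study, the base threshold is 110 with doubling classes
(110/220/440); the per-metal `Eᵢ` ladder uses the standard Hakanson
cut points 40/80/160/320. All ladders are left-closed: a value on a
boundary belongs to the upper class. A concentration of zero makes
`Igeo` undefined; it is reported as missing rather than −∞.

## Synthetic survey generator

The generator emulates a multi-source contaminated redevelopment site:
252 sampling points × 3 depth layers by default, with concentrations
from a non-negative bilinear model `X = G·F` (4 sources) times
multiplicative noise. Source contributions are mean-one log-normals
modulated by a smooth spatial field built from 25 seeded Gaussian
bumps (correlation length 900 m on a 4 × 4 km domain); the field gives
IDW something real to interpolate. Anthropogenic contributions
attenuate with depth (1 / 0.72 / 0.50 for surface / subsurface /
saturated); the natural source does not. Draws below the method
detection limit are replaced by MDL/2 and flagged as censored.

Defaults were chosen once, analytically, so that expected surface
concentrations sit near the survey's reported means, the natural
source carries ≈ 80 % of expected As, and surface coefficients of
variation land in the survey's reported pattern (Cd/Cu/Ni high, As
≈ 20 %). Sample-size and dispersion parameters are frozen; they are
conditions of the emulated study, not tuning knobs.

One structural choice deserves emphasis. A "natural background" source
that loads every metal at a sizeable fraction of its background value
makes the 4-factor model **rotationally non-identifiable**: for any
constant `c`, replacing `g_anthro ← g_anthro + c·g_nat` and
`f_nat ← f_nat − c·f_anthro` leaves `X` (and hence the PMF objective)
exactly unchanged until a non-negativity constraint binds. No solver
can recover a ground truth that sits in the interior of that flat
manifold. The default profiles are therefore *near-separable*: the
natural source keeps As near background (7.2 vs 9.1 mg·kg⁻¹) but loads
the anthropogenic signature metals only lightly, which pins the
factorization close to its vertex and makes profile recovery a
well-posed test. This mirrors how fitted natural factors look in real
receptor-model studies, where the natural share of
anthropogenically-dominated metals is small.

With the default profiles and the survey's detection limits, no
generated value falls below an MDL (the emulated survey's own reported
minima all exceed the MDLs), so the censoring path is exercised by
dedicated tests with constructed trace-level inputs rather than by the
defaults.

What the generator does *not* emulate: real geostatistical covariance
(the bump field is a convenience, not a fitted variogram), pH–metal
dependence, analytical bias, spatially clustered sampling designs, or
metal speciation. Passing recovery tests on this generator shows the
machinery is correct under the assumed mixing structure; it does not
certify performance on field data whose structure differs.

## PMF solver

The solver minimises `Q = ΣΣ((x − Σ g f)/u)²` under `G, F ≥ 0`. Cell
uncertainties follow the standard receptor-modelling formula:
`u = (5/6)·MDL` for values at or below the MDL, else
`u = √((x·RSD)² + (0.5·MDL)²)` with RSD defaulting to 0.2. MDLs
default to Cd 0.03, Pb 0.10, Cu 1.00, Zn 0.50, Ni 5.00, Hg 0.01,
As 0.002 mg·kg⁻¹.

Optimisation runs in two phases per start: weighted multiplicative
updates (cheap, vectorised; an update is accepted only while Q
decreases) followed by alternating per-row/per-column non-negative
least squares (each sweep solves its subproblem exactly, so this phase
is strictly monotone). Twenty seeded random starts by default; the
best Q wins. Convergence tolerance 1e-10 relative; the Q trace is
retained and tested for monotonicity. The scale indeterminacy
(`G·D, D⁻¹·F`) is fixed by normalising contribution columns to mean 1
and ordering factors by explained mass, which makes profile rows
interpretable as mg·kg⁻¹ at the average sample.

`Q_robust` re-evaluates Q after inflating the uncertainty of cells
with |scaled residual| > 4 by √(|r|/4). The factor scan (3–6 by
default) reports Q ratios, per-metal r² (squared correlation of
observed vs reconstructed columns) and the fraction of scaled
residuals within ±3. The bootstrap resamples samples with replacement,
refits warm-started from the base solution, and maps bootstrap factors
to base factors one-to-one by profile correlation (mapped when
r > 0.6); it reports per-factor mapping rates and 5–95 % intervals of
the contribution percentages.

Contribution percentages attribute metal `j` mass
`Σᵢ gᵢₖ fₖⱼ / Σₖ′ Σᵢ gᵢₖ′ fₖ′ⱼ × 100`; columns sum to 100. Because of
the rotational flat directions described above, contribution shares on
low-noise data are determined only up to the point where
non-negativity binds — on the default fixture a truth-initialised
solution and the multistart optimum have *identical* Q yet As-shares
differing by ~13 points. Recovery tests therefore assert dominance
structure, profile cosine similarity and an ambiguity-bounded share
tolerance rather than exact share equality. Species weighting
("strong/weak") and rotation tools (Fpeak, DISP) are out of scope;
factor naming (traffic/combustion/industry/natural) is a reporting
label supplied by the user, never inferred.

## IDW interpolation

Weights are `d⁻ᵖ` (default power 2, all neighbours; both
configurable) normalised to sum to one, which makes every prediction a
convex combination of data values — exact at nodes (distance
< 1e-12), bounded by the data range, and converging to
nearest-neighbour as the power grows. Leave-one-out cross-validation
reports RMSE, MAPE (over strictly positive observations; zeros are
excluded with a warning) and RMSSE. IDW has no model variance, so the
standardisation scale for RMSSE is defined here as the
distance-weighted standard deviation of the neighbour values at the
left-out point; RMSSE ≈ 1 then means that local neighbourhood spread
is a faithful error scale. This convention is package-specific —
comparisons with RMSSE values from other software should be treated as
qualitative only.

## Random forest

A seeded permutation 70/30 split (train size ⌊n·f⌋), scikit-learn
`RandomForestRegressor` with 500 trees and default depth, and a
default feature set of coordinates, depth code, pH and the six other
metal concentrations (the target is never a feature; leakage raises).
Both R² conventions are reported because the explained-variance ratio
`Σ(Ĉ−C̄)²/Σ(C−C̄)²` equals the standard `1 − SSE/SST` only when
predictions are the least-squares projection; off-projection they
diverge, so headline numbers should quote the standard form.

## Health risk model

Average daily doses use the standard USEPA RAGS soil equations (stated
in the module docstring) with `AT_nc = ED·365` for non-carcinogens and
`AT_ca = 70·365` d for carcinogens. Default exposure parameters follow
the Chinese site-assessment guideline conventions: child
IngR triangular(100, 200, 300) mg·d⁻¹, BW lognormal(15.9, 2.9) kg,
InhR 7.5 m³·d⁻¹, EF 350 d·a⁻¹, ED 6 a, SA 2800 cm²,
AF 0.2 mg·cm⁻²·d⁻¹, ABS 0.001, PEF 1.36 × 10⁹ m³·kg⁻¹ (adults
analogous; every parameter is overridable via YAML).

The toxicity defaults are editable conventions, not survey values:
oral RfDs from the USEPA set (Cu 0.04, As 3e-4, …); dermal RfDs equal
to oral; inhalation RfDs derived from reference concentrations
(RfC × 20 m³ / 70 kg), which gives Ni 4.0e-6 and As 4.3e-6
mg·kg⁻¹·d⁻¹. Slope factors: oral As 1.5, Cd 6.1, Pb 8.5e-3; Ni is
treated as an inhalation-only carcinogen (0.84), the toxicologically
standard position — an oral Ni slope factor would make total cancer
risk Ni-dominated, contradicting both route-specific evidence and the
observed pattern in surveys of this kind. Under these defaults the
hazard-index decomposition orders ingestion > inhalation > dermal,
and total cancer risk is dominated by As, then Cd, then Pb, with Ni
negligible.

Monte Carlo: 1-D mode draws, per iteration, one concentration per
metal from the empirical distribution of the chosen layer (surface by
default — the layer humans contact) and one value per exposure
parameter; distributions are truncated at zero (normal by resampling).
2-D mode adds an outer bootstrap over the concentration dataset
(default 100 × 1000) so sampling uncertainty and exposure variability
are propagated separately; 1-D is the default reporting mode.
Exceedance probabilities are draw fractions against HI > 1,
TCR > 10⁻⁶ and TCR > 10⁻⁴. Sensitivities are Spearman rank
correlations between each varying input and HI or TCR, with
contribution shares |ρ|/Σ|ρ|; parameters appearing only in
denominators (body weight) are provably negative.

## Pipeline

`run_all` executes generate → describe → indices → IDW → PMF → RF →
risk. Each stage seeds its own named substream
(`SeedSequence([seed, stage_index])`), so runs are byte-identical
under a fixed config and stages can be reproduced in isolation. Any
stage failure aborts with an error naming the stage. Reported problem
sizes in the shipped demo (252 points, 20 PMF starts, 100 bootstrap
iterations, 10⁴ Monte Carlo draws) are the package's reference
configuration; the quick-run config used in the test suite scales
these down (60 points, 3 starts, 10³ draws) without changing any
method.

## Known limitations

* PMF rotational ambiguity is inherent; the solver reports one vertex
  of the feasible set and the bootstrap quantifies stability, but no
  Fpeak-style rotation exploration is provided.
* RMSSE for IDW is a package convention (see above).
* The exposure and toxicity defaults are literature conventions;
  site-specific assessments should override them.
* Metal interactions (synergy/antagonism) and multi-pathway coupling
  beyond dose addition are not modelled.
* Coordinates are treated as planar; degree inputs are accepted with a
  warning but distances are then in degree units.
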