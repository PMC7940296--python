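# Methods

This note documents the models inside `traitforest`, the choices behind
their default parameters, what the synthetic generators do and do not
emulate, and the numerical conventions. Units are stated with every
parameter; all defaults live in `GapModelParams`, `ClimateParams`,
`TraitBounds`, `HerbivorySettings` and `SoilWaterParams` and can be
overridden from the TOML configuration.

## 1. The trait continuum

Every established individual draws SLA ~ U(60, 250) cm²/g and
WSG ~ U(0.35, 0.85), independently. Dependent traits follow fitted
power-law trade-off curves, `log y = α + β log SLA (+ ε)`:

| dependent trait | local: value at SLA=100, slope | global: value at SLA=100, slope |
|---|---|---|
| leaf C:N (mass ratio) | 22, −0.55 | 14, −0.35 |
| leaf C:P (mass ratio) | 350, −0.45 | 220, −0.28 |
| leaf longevity (yr) | 1.20, −0.90 | 1.00, −0.70 |

Both packaged curve sets are **synthetic stand-ins with documented
parameters** — no real trait-database values are bundled. They are chosen
so that (i) the local set follows ordinary leaf-economics magnitudes
(C:N ≈ 29 at SLA 60 down to ≈ 13 at SLA 250; leaf lifespan ≈ 1.9 yr down
to ≈ 0.5 yr), and (ii) the global set is biased toward nitrogen-rich
leaves with shallower slopes, a visible mis-parameterisation standing in
for the difference between a global database fit and local plot data.
Users fit their own curves from CSV trait tables
(`fit_curves_from_table`); fits are OLS on the log–log scale with the
residual sd taken df-corrected (n−2). By default individuals scatter
lognormally around the curve with that residual sd (configurable
`stochastic` flag, on), representing within-key-trait variation between
individuals; dependent traits are floored at 1e−6 against degenerate
curves.

## 2. Climate forcing and soil water

The generator produces stationary annual series per site. Mean annual
temperature is `19 °C − 5.5 K/km · (elev − 1000 m)` plus N(0, 0.4 °C)
interannual noise; a scenario ΔT shifts every value exactly. Precipitation
is lognormal (CV 0.15) around `2000 mm + 800 mm/km`, rescaled by (1 + ΔP).
Shortwave radiation sits near 15 MJ m⁻² d⁻¹. Nitrogen and phosphorus input
(deposition + weathering, treated as one flux) decline with elevation:
25 − 9/km kg N ha⁻¹ yr⁻¹ and 2.0 − 0.75/km kg P ha⁻¹ yr⁻¹. None of these
numbers are measurements; they are plausible magnitudes for a wet tropical
montane gradient, and the N/P gradients are the lever that makes the upper
site nutrient-poor.

Soil water is a single-layer bucket (depth 1000 mm; volumetric wilting
point 0.15, field capacity 0.35, saturation 0.45): transpiration supply
falls linearly from the demand at field capacity to zero at wilting;
water above field capacity drains (≤ 500 mm/step), above saturation runs
off. The balance `Δstorage = P − ET − drainage − runoff` closes to machine
precision by construction, and the state provably stays inside
[wilting, saturation]. The bucket is stepped 12 times per simulation year
against the previous year's transpiration demand (demand = GPP / WUE with
WUE 3 g C per kg H₂O); the annual water scalar f_W is the mean relative
availability. On this wet gradient f_W ≈ 1 — the bucket exists so that dry
scenarios (ΔP ≪ 0) can bite, not because the default sites are
water-limited.

## 3. The gap model

Annual time step; 0.1-ha patches simulated independently (a 1-ha site =
10 patches; seeds are spawned per patch, so patch i is unaffected by
patch j's existence).

**Light.** The canopy is horizontally uniform and layered by height:
individuals are stacked tallest-first and each absorbs the Beer–Lambert
increment (k = 0.5) of its own LAI beneath the cumulative LAI of everything
taller. Absorbed fractions sum to 1 − e^(−k·LAI) ≤ 1. Leaf area per
individual is `0.2 · SLA · leaf C` (the 0.2 bundles cm²/g → m²/kg and a
dry-mass:carbon ratio of 2).

**Production.** GPP = ε(N_area) · APAR · f_T · f_W · min(f_N, f_P), a
light-use-efficiency form: ε = 2.6 g C/MJ · N_area/(N_area + 1 g/m²), with
leaf N per area derived from SLA and leaf C:N; f_T is a Gaussian response
centred at 21 °C with width 12 °C. Maintenance respiration is proportional
to tissue N (12 kg C per kg N per yr at 15 °C, Q10 = 2; root N at 0.6× leaf
N per C, wood N 0.002); growth respiration takes 25% of the positive
balance. NPP may be negative.

**Nutrients.** Plant-available N and P pools (kg/ha) receive
deposition/weathering input and litter mineralisation, lose 10%/yr to
leaching, and are drawn down by uptake proportional to realised growth and
tissue stoichiometry. The limitation scalars are Michaelis–Menten in the
pool with half-saturations scaled by the *individual's* N (or P) demand
relative to a reference (n_half 100 kg N/ha at C:N 25; p_half 10 kg P/ha):
nutrient-hungry (high-SLA, low-C:N) individuals saturate later. This
per-individual demand scaling is what lets nutrient scarcity select
against nitrogen-expensive leaves; Liebig's minimum of f_N and f_P then
multiplies GPP. The elemental books are deliberately approximate (uptake
is capped by the pools after growth is realised; resorption is ignored) —
only carbon closes exactly.

**Allocation and allometry.** Positive NPP splits 0.25/0.55/0.20 into
leaf/wood/fine roots; negative NPP depletes root, then leaf, then wood.
Leaves and fine roots turn over at 1/longevity (fine-root lifespan is tied
to leaf lifespan — the fast–slow coupling of the leaf economics spectrum).
Stem volume is `wood C / (500 · WSG)` m³, so the same carbon increment
buys exactly 1/WSG times more volume in light wood; height = 22·V^0.25
(capped at 40 m), crown area = 0.5·h^1.2 m². Leaf area above an allometric
crown capacity (4 m² leaf per m² crown) is shed to litter; without this cap
a single tree can monopolise the flat canopy and stand structure collapses
to a handful of giants.

**Mortality.** Annual death probability = background + stress, clipped to
[0, 1]. Background = 0.012 · exp(−2.5 · (WSG − 0.6)) — the growth–survival
trade-off, light wood dies more. Stress = 0.15/(1 + greff/0.03) with
growth efficiency greff = realised NPP per m² leaf — suppressed and
carbon-starved trees die quickly. Dead trees' pools go to litter.

**Establishment.** Poisson(rate · area), rate 80 saplings ha⁻¹ yr⁻¹,
saplings start with 0.05/0.10/0.05 kg C (leaf/wood/root). Three modes:
`diversity` (uniform key-trait draws + local curves), `fixed_global`
(draws + global curves) and `low_diversity` (every sapling gets the
midpoint key traits with deterministic dependent traits — the fixed-PFT
benchmark, zero trait variance by construction). Initialisation is bare
ground; there is no separate spin-up protocol, which is why reported
values average a late window.

**Carbon closure.** Per patch-year, exactly:
`Δ(plant C + litter C) = NPP + establishment C − heterotrophic respiration
− herbivore respiration − herbivore retention`. Realised NPP is floored at
−(total pools) — a tree cannot respire carbon it does not hold — with the
shortfall logged as carbon stress, so the identity holds to 1e−9 relative
even under fuzzed parameters. Litter decays at 0.20/yr (Q10 = 2, capped at
0.6/yr), releasing heterotrophic respiration and mineralising litter N and
P.

**Herbivory.** The herbivore community is a flux transformer, not a state:
realised rate = 0.06 · exp(−0.04 · (MAT − 13.5 °C)) of each individual's
leaf mass per year (negative temperature sensitivity — the observed
direction along such gradients; magnitude configurable, and the default
rate is a placeholder to be calibrated against leaf-area-loss data), with
an optional SLA-palatability modifier defaulting to 0 (no SLA association
by default). Of the consumed carbon, 40% is assimilated; 60% of that is
respired away and the rest is retained in herbivore biomass (exported);
the unassimilated 60% returns to litter as frass. Setting the base rate to
0 makes the simulator bit-identical to a build without the compartment.

## 4. Community summaries and the census cutoff

CWM(trait) = Σwᵢtᵢ/Σwᵢ with abundance weights (each tree = 1) by default
and leaf-mass weights as an option. Summaries census trees ≥ 5 m height
(configurable), mirroring field plot censuses with diameter cutoffs; the
simulator's persistent bank of suppressed saplings — all of which carry
fresh uniform draws — would otherwise swamp any abundance-weighted signal
of sorting. LAI and all carbon fluxes integrate every individual
regardless of the cutoff.

## 5. The three-site experiment and its reference values

Defaults: sites at 1000/2000/3000 m, 1 ha each, 700 years with the final
200 averaged (the test suite and acceptance script run the reduced 200/100
configuration, which reaches the same qualitative state in a fraction of
the time; `--full-scale` gives 10-ha sites / 100 patches). Forcing is
generated once per site and shared across the three modes; every run is
fully determined by the experiment seed and writes a manifest (version,
seeds, config hash).

The per-site reference NPP values (10, 8, 2 Mg C ha⁻¹ yr⁻¹ at 1000, 2000,
3000 m) are **synthetic stand-ins**: rounded values with the observed
qualitative property that productivity declines steeply toward the top of
tropical montane gradients, set near the local-trait-mode output of the
shipped calibration — they exist so the mode comparison has a yardstick,
and they are meant to be replaced by the user's own plot estimates
(`[reference_npp]` in the TOML).

The shipped calibration was chosen so that the package's headline
qualitative pattern emerges and is seed-robust: the low-diversity mode
underestimates NPP most at 3000 m, and local trade-off curves beat the
global set on summed absolute NPP error. The mechanism, not the numbers,
is the claim: at the cold, nutrient-poor top of the gradient a sorted
community of low-SLA, long-lived-leaf, low-N-demand trees outperforms both
a fixed mid-trait community and one whose dependent traits come from
mis-specified global curves.

## 6. The response–effect statistical layer

Path models over observed variables only, for any recursive DAG.
Variables are z-scored before fitting, so reported coefficients are
standardized. For a recursive system with uncorrelated errors the ML
estimates given the sample covariance S (n−1 divisor) are per-equation
least squares computed from S; the implied covariance is
Σ = (I−B)⁻¹Ψ(I−B)⁻ᵀ, and the fit statistic uses the (n−1)-multiplier
convention, χ² = (n−1)(ln|Σ| + tr(SΣ⁻¹) − ln|S| − p), with df = p(p+1)/2
minus free parameters (software conventions differ here; this one is
stated so results are comparable). A just-identified model reports
χ² = 0, df = 0 exactly. Standard errors are the df-corrected per-equation
least-squares ones. Mediation effects follow Wright's path tracing:
direct = the x→y coefficient, indirect = (x→m)(m→y), total = their sum,
which equals the marginal standardized regression slope of y on x.

The chi-square survival function is the regularized upper incomplete
gamma Q(df/2, x/2) — exp(−x/2) exactly at df = 2. The difference test
requires the restricted edge set to be a subset of the general one on the
same data; Δχ² and Δdf are the differences and p = Q(Δdf/2, Δχ²/2).
Arbitrary nested specifications are accepted (the shipped default drops
the single direct path, Δdf = 1); no latent variables, no missing-data
handling, no robust corrections.

Calibration checks in the test suite: on synthetic standardized mediation
data (truth 0.5/0.5/0.0, n = 200) the mean absolute bias of every path
stays below 0.02 over 500 replicates, and the difference test's empirical
type-I error sits inside 0.05 ± 0.01 over 2000 null simulations. The
saturated fit reproduces per-equation OLS to 1e−8, and both fits agree
with an independent brute-force numerical ML fitter (test suite only) to
1e−4 in coefficients and 1e−3 in χ².

## 7. What the synthetic generators do and do not emulate

The fixture generators mimic the *structure* of a field campaign — trait
tables of 52 species × 8 replicates with species-level curve scatter plus
replicate measurement noise, station-like forcing series, plot-level
mediation datasets with known standardized paths — but none of its
content: no real species, sites, or measured values appear anywhere.
Passing tests therefore demonstrate internal consistency (conservation,
calibration, recovery of known generating parameters, emergence of
sorting) and not predictive skill on real forests. Real-data features the
generators deliberately lack include temporal autocorrelation and seasonal
structure in climate, spatially explicit crowns and gaps, species
identities and phylogenetic structure, measurement error in NPP, and any
coupling between herbivore pressure and herbivore dynamics.

## 8. Known limitations

Annual time step with a flat, horizontally uniform canopy; fixed
allocation fractions; no seed dispersal, disturbance, or pasture/grass
layer; nutrient books approximate by design; height strictly allometric in
stem volume (so the exact 1/WSG advantage applies to volume growth, and to
height only through the concave allometry); the temperature optimum is
global rather than a trait, so all thermal adaptation must come from the
traits that are in the continuum. The statistical layer handles observed
variables only. Problem sizes in the shipped tests (1-ha sites, 200-year
runs, 2-patch sorting studies) are the package's desk-scale defaults;
larger configurations are a flag away and scale linearly.
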