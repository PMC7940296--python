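# Annotated run configuration for the three-site diversity-mode experiment.
# Every section is optional; omitted sections fall back to the shipped
# defaults (the calibration documented in docs/methods.md).

# Sites along the elevation gradient. patch_area_m2 divides area_ha into
# independently simulated patches (1 ha / 1000 m2 -> 10 patches).
[[sites]]
site_id = "site_1000m"
elevation = 1000.0
area_ha = 1.0

[[sites]]
site_id = "site_2000m"
elevation = 2000.0
area_ha = 1.0

[[sites]]
site_id = "site_3000m"
elevation = 3000.0
area_ha = 1.0

[experiment]
# low_diversity: every sapling carries the midpoint key traits (fixed-PFT style)
# global_tradeoffs: uniform key-trait draws, dependent traits from the global curve set
# local_tradeoffs: uniform key-trait draws, dependent traits from the local curve set
modes = ["low_diversity", "global_tradeoffs", "local_tradeoffs"]
years = 200            # headline design: 700
average_window = 100   # headline design: 200 (the final years averaged)
seed = 1               # explicit; no wall-clock seeding

# Climate baseline at the 1000 m reference elevation and its lapse/gradients.
[climate]
mat_1000 = 19.0        # degC
lapse_k_per_km = 5.5
precip_1000 = 2000.0   # mm/yr
precip_per_km = 800.0
n_in_1000 = 25.0       # kg N/ha/yr deposition + weathering
n_in_per_km = -9.0
p_in_1000 = 2.0        # kg P/ha/yr
p_in_per_km = -0.75

# Climate-change scenario deltas (applied to every site).
[scenario]
delta_t_c = 0.0        # additive warming, degC
delta_p_frac = 0.0     # fractional precipitation change (-0.5 = half)

# Uniform sampling bounds for the key traits.
[bounds]
sla_min = 60.0         # cm2/g
sla_max = 250.0
wsg_min = 0.35         # dimensionless
wsg_max = 0.85

# Herbivore energy-transformation settings.
[herbivory]
base_rate = 0.06              # fraction of leaf mass removed per yr at T_ref
temp_sensitivity = -0.04      # per degC (negative: less herbivory when warm)
assimilation_fraction = 0.4
respiration_fraction = 0.6
palatability_slope = 0.0      # no SLA dependence by default

# Trade-off curve sets: log(dependent) = intercept + slope * log(key).
# Omit to use the packaged synthetic defaults. provenance must match the set.
[tradeoffs.local.leaf_cn]
key_name = "sla"
intercept = 5.6240       # ln(22) + 0.55 ln(100)
slope = -0.55
residual_sd = 0.12
provenance = "local"

[tradeoffs.local.leaf_cp]
key_name = "sla"
intercept = 7.9305
slope = -0.45
residual_sd = 0.15
provenance = "local"

[tradeoffs.local.leaf_longevity]
key_name = "sla"
intercept = 4.3268
slope = -0.9
residual_sd = 0.15
provenance = "local"

# Per-site reference NPP (Mg C/ha/yr) the simulations are compared against.
# These are synthetic stand-ins shipped with the package; replace with your
# own plot estimates.
[reference_npp]
1000 = 10.0
2000 = 8.0
3000 = 2.0
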