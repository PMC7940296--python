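"""Individual-based patch dynamics with a trait continuum.

A deliberately simplified forest gap model: trees live on small (0.1 ha)
patches, compete for light in a flat, horizontally uniform canopy
(Beer–Lambert extinction, taller individuals shade shorter ones), grow by a
light-use-efficiency production scheme limited by temperature, soil water and
the more limiting of nitrogen and phosphorus (Liebig), allocate carbon by
fixed fractions, and die by a wood-density-dependent background hazard plus a
growth-efficiency stress hazard. Community trait composition is not imposed:
it emerges by ecological sorting of individuals whose key traits were drawn
at random at establishment.

Carbon is conserved exactly: per patch-year,

    d(plant C + litter C) = NPP + establishment C
                            - heterotrophic respiration
                            - herbivore respiration - herbivore retention,

where the right-hand side fluxes are the realised ones (a tree cannot respire
carbon it does not hold; the shortfall is recorded as carbon stress).
Nitrogen and phosphorus books are intentionally approximate — they exist to
produce nutrient limitation, not to close elemental budgets.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .forcing import ClimateForcing, SitePlan, SoilWaterParams, SoilWaterState, step_soil_water
from .herbivory import HerbivorySettings, apply_herbivory, realized_rate
from .traits import (
    DEPENDENT_TRAITS,
    TraitBounds,
    TradeoffCurve,
    TraitSet,
    default_curves,
    derive_dependent_traits,
    draw_key_traits,
)

__all__ = [
    "GapModelParams",
    "Individual",
    "Patch",
    "CommunityState",
    "SiteRun",
    "stem_volume",
    "tree_height",
    "crown_area",
    "leaf_area",
    "partition_light",
    "establish",
    "annual_production",
    "allocate_and_grow",
    "death_probability",
    "mortality",
    "step_patch",
    "run_site",
    "community_summary",
]

Mode = Literal["diversity", "low_diversity", "fixed_global"]
MODES = ("diversity", "low_diversity", "fixed_global")


@dataclass(frozen=True)
class GapModelParams:
    """Tunable constants of the gap model (annual time step, SI-ish units).

    The defaults are the shipped calibration: chosen so that a wet tropical
    montane gradient (19 °C / 2000 mm at 1000 m down to 8 °C at 3000 m,
    declining N and P input) reproduces the qualitative diversity-mode
    pattern — trait sorting toward high SLA in warm, nutrient-rich sites and
    low SLA in cold, nutrient-poor ones, with a fixed-average-trait community
    underperforming most at the top of the gradient.
    """

    # geometry / stoichiometry
    carbon_density_wood: float = 500.0   # kg C per m³ at WSG 1 (0.5 kgC/kg dry * 1000 kg/m³)
    sla_area_per_c: float = 0.2          # m² leaf per kg C per unit SLA(cm²/g)
    height_allom_a: float = 22.0         # h = a * V^b, capped
    height_allom_b: float = 0.25
    height_max: float = 40.0             # m
    crown_allom_a: float = 0.5           # crown area = a * h^b, m²
    crown_allom_b: float = 1.2
    crown_lai_max: float = 4.0           # max leaf area per m² crown
    census_min_height_m: float = 5.0     # census cutoff for community summaries
    stem_form_factor: float = 0.4        # V = form * basal area * height
    root_nmass_frac: float = 0.6         # root N per C relative to leaf
    wood_nmass: float = 0.002            # kg N per kg C
    wood_pmass: float = 0.0002           # kg P per kg C

    # light & production
    k_ext: float = 0.5                   # Beer-Lambert extinction
    par_fraction: float = 0.5            # PAR share of shortwave radiation
    eps_max: float = 2.6                 # g C per MJ APAR at N saturation
    eps_half_narea: float = 1.0          # g N m⁻² half-saturation of LUE
    t_opt: float = 21.0                  # °C
    t_width: float = 12.0                # °C
    q10_resp: float = 2.0
    resp_ref_t: float = 15.0             # °C
    maint_resp_per_n: float = 12.0       # kg C per kg tissue N per yr at ref T
    growth_resp_frac: float = 0.25
    wue_g_per_kg: float = 3.0            # g C fixed per kg H₂O transpired

    # allocation
    alloc_leaf: float = 0.25
    alloc_wood: float = 0.55
    alloc_root: float = 0.20

    # demography
    establishment_rate: float = 80.0     # saplings ha⁻¹ yr⁻¹
    sapling_leaf_c: float = 0.05         # kg C
    sapling_wood_c: float = 0.10
    sapling_root_c: float = 0.05
    mort_background: float = 0.012      # at WSG = wsg_ref
    mort_wsg_slope: float = 2.5          # hazard ∝ exp(-slope·(wsg - ref))
    wsg_ref: float = 0.6
    mort_stress_max: float = 0.15
    greff_half: float = 0.03             # kg C m⁻² leaf yr⁻¹

    # soil / nutrients
    litter_decay_ref: float = 0.20       # yr⁻¹ at ref T
    litter_decay_max: float = 0.6
    q10_soil: float = 2.0
    n_half: float = 100.0                # kg N ha⁻¹ half-saturation of f_N
    p_half: float = 10.0                 # kg P ha⁻¹
    nmass_ref: float = 0.04              # leaf N per C reference (CN 25)
    pmass_ref: float = 1.0 / 350.0
    nutrient_leach: float = 0.10         # yr⁻¹
    init_avail_n: float = 15.0           # kg ha⁻¹
    init_avail_p: float = 1.5
    pet_per_degc: float = 60.0           # mm yr⁻¹ per °C (Thornthwaite-flavoured)

    def __post_init__(self) -> None:
        s = self.alloc_leaf + self.alloc_wood + self.alloc_root
        if abs(s - 1.0) > 1e-12:
            raise ValueError("allocation fractions must sum to 1")


# ---------------------------------------------------------------------------
# Allometry helpers (vectorised)
# ---------------------------------------------------------------------------


def stem_volume(c_wood, wsg, params: GapModelParams):
    """Stem volume (m³) from the wood carbon pool and wood-specific gravity."""
    return np.asarray(c_wood, float) / (params.carbon_density_wood * np.asarray(wsg, float))


def tree_height(c_wood, wsg, params: GapModelParams):
    v = stem_volume(c_wood, wsg, params)
    return np.minimum(params.height_allom_a * v**params.height_allom_b, params.height_max)


def crown_area(height, params: GapModelParams):
    return params.crown_allom_a * np.asarray(height, float) ** params.crown_allom_b


def leaf_area(c_leaf, sla, params: GapModelParams):
    """Leaf area (m²) = leaf C · SLA with unit conversion (dry mass ≈ 2 C)."""
    return params.sla_area_per_c * np.asarray(c_leaf, float) * np.asarray(sla, float)


# ---------------------------------------------------------------------------
# State containers
# ---------------------------------------------------------------------------


@dataclass
class Individual:
    """One tree, for inspection and single-tree tests (the patch stores arrays)."""

    traits: TraitSet
    c_leaf: float
    c_wood: float
    c_root: float
    age: float = 0.0
    alive: bool = True

    def height(self, params: GapModelParams) -> float:
        return float(tree_height(self.c_wood, self.traits.wsg, params))

    def leaf_area(self, params: GapModelParams) -> float:
        return float(leaf_area(self.c_leaf, self.traits.sla, params))


class Patch:
    """A 0.1-ha (default) community: parallel arrays over living individuals."""

    TRAIT_COLS = ("sla", "wsg", "leaf_cn", "leaf_cp", "leaf_longevity")
    POOL_COLS = ("c_leaf", "c_wood", "c_root")

    def __init__(
        self,
        area_m2: float = 1000.0,
        params: GapModelParams | None = None,
        soil_params: SoilWaterParams | None = None,
    ) -> None:
        self.area_m2 = float(area_m2)
        self.params = params or GapModelParams()
        sp = soil_params or SoilWaterParams()
        self.soil = SoilWaterState(swc=sp.field_capacity, params=sp)
        for col in self.TRAIT_COLS + self.POOL_COLS + ("age",):
            setattr(self, col, np.empty(0, dtype=float))
        self.avail_n = self.params.init_avail_n   # kg ha⁻¹
        self.avail_p = self.params.init_avail_p
        self.litter_c = 0.0                       # kg C per patch
        self.litter_n = 0.0                       # kg per ha
        self.litter_p = 0.0
        self.carbon_stress = 0.0                  # cumulative unrespirable deficit
        self.last_et_demand_mm = 0.0

    # -- bookkeeping ------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.sla)

    @property
    def ha_factor(self) -> float:
        """Multiplier converting per-patch amounts to per-hectare."""
        return 10_000.0 / self.area_m2

    @property
    def plant_c(self) -> float:
        return float(self.c_leaf.sum() + self.c_wood.sum() + self.c_root.sum())

    @property
    def total_c(self) -> float:
        return self.plant_c + self.litter_c

    def leaf_areas(self) -> np.ndarray:
        return leaf_area(self.c_leaf, self.sla, self.params)

    def heights(self) -> np.ndarray:
        return tree_height(self.c_wood, self.wsg, self.params)

    @property
    def lai(self) -> float:
        return float(self.leaf_areas().sum() / self.area_m2)

    def add(self, traits: TraitSet, c_leaf, c_wood, c_root) -> None:
        n = np.size(np.asarray(traits.sla))
        for col in self.TRAIT_COLS:
            v = np.broadcast_to(np.asarray(getattr(traits, col), float), (n,))
            setattr(self, col, np.concatenate([getattr(self, col), v]))
        for col, v in zip(self.POOL_COLS, (c_leaf, c_wood, c_root)):
            v = np.broadcast_to(np.asarray(v, float), (n,))
            setattr(self, col, np.concatenate([getattr(self, col), v]))
        self.age = np.concatenate([self.age, np.zeros(n)])

    def keep(self, mask: np.ndarray) -> None:
        for col in self.TRAIT_COLS + self.POOL_COLS + ("age",):
            setattr(self, col, getattr(self, col)[mask])

    def individual(self, i: int) -> Individual:
        return Individual(
            traits=TraitSet(
                sla=float(self.sla[i]),
                wsg=float(self.wsg[i]),
                leaf_cn=float(self.leaf_cn[i]),
                leaf_cp=float(self.leaf_cp[i]),
                leaf_longevity=float(self.leaf_longevity[i]),
            ),
            c_leaf=float(self.c_leaf[i]),
            c_wood=float(self.c_wood[i]),
            c_root=float(self.c_root[i]),
            age=float(self.age[i]),
        )


@dataclass
class CommunityState:
    """Per site-year (or patch-year) community summary."""

    npp_kg_m2: float = 0.0
    npp_mg_ha: float = 0.0
    nppa_mg_ha: float = 0.0
    gpp_kg_m2: float = 0.0
    lai: float = 0.0
    basal_area_m2_ha: float = 0.0
    stem_count_ha: float = 0.0
    cwm_sla: float = float("nan")
    cwm_wsg: float = float("nan")
    sla_variance: float = float("nan")
    cwm_missing: bool = True


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------


def partition_light(heights, leaf_areas, area_m2: float, k_ext: float):
    """Absorbed-PAR fraction per individual in a flat layered canopy.

    Individuals are stacked by height (tallest first, stable ties); each
    absorbs the Beer–Lambert increment of its own LAI below the cumulative
    LAI of everything taller. The fractions sum to ``1 − exp(−k·LAI)`` ≤ 1,
    so total absorbed light never exceeds incident light.
    """
    heights = np.asarray(heights, float)
    leaf_areas = np.asarray(leaf_areas, float)
    n = len(heights)
    if n == 0:
        return np.empty(0)
    order = np.argsort(-heights, kind="stable")
    lai_i = leaf_areas[order] / area_m2
    cum_above = np.concatenate([[0.0], np.cumsum(lai_i)[:-1]])
    frac_sorted = np.exp(-k_ext * cum_above) - np.exp(-k_ext * (cum_above + lai_i))
    frac = np.empty(n)
    frac[order] = frac_sorted
    return frac


def establish(
    patch: Patch,
    rate: float,
    mode: Mode,
    bounds: TraitBounds,
    curves_local: dict[str, TradeoffCurve],
    curves_global: dict[str, TradeoffCurve] | None = None,
    rng: np.random.Generator | int = 0,
    stochastic: bool = True,
) -> float:
    """Add a Poisson number of saplings; returns the carbon they import (kg C).

    ``diversity``: uniform key-trait draws + local curves (stochastic scatter
    honours the flag). ``low_diversity``: every sapling gets the midpoint key
    traits and deterministic dependent traits — zero trait variance, the
    conventional fixed-PFT behaviour. ``fixed_global``: uniform draws but the
    global curve set fills the dependent traits.
    """
    if mode not in MODES:
        raise ValueError(f"unknown establishment mode {mode!r}")
    if rate < 0:
        raise ValueError("establishment rate must be >= 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    p = patch.params
    n = int(rng.poisson(rate * patch.area_m2 / 10_000.0))
    if n == 0:
        return 0.0
    if mode == "low_diversity":
        sla = np.full(n, bounds.sla_mid)
        wsg = np.full(n, bounds.wsg_mid)
        traits = derive_dependent_traits(sla, wsg, curves_local, stochastic=False, rng_seed=rng)
    else:
        keys = draw_key_traits(bounds, n, rng)
        curves = curves_local if mode == "diversity" else (curves_global or default_curves("global"))
        traits = derive_dependent_traits(
            keys[:, 0], keys[:, 1], curves, stochastic=stochastic, rng_seed=rng
        )
    patch.add(traits, p.sapling_leaf_c, p.sapling_wood_c, p.sapling_root_c)
    return n * (p.sapling_leaf_c + p.sapling_wood_c + p.sapling_root_c)


def annual_production(
    c_leaf,
    c_wood,
    c_root,
    sla,
    leaf_cn,
    apar_mj,
    tair_c: float,
    f_water: float,
    f_n,
    f_p,
    params: GapModelParams,
):
    """Per-individual GPP, NPP and transpiration demand for one year.

    ``gpp = ε(N_area) · APAR · f_T · f_W · min(f_N, f_P)`` with light-use
    efficiency ε saturating in leaf N per area (derived from SLA and leaf
    C:N). NPP subtracts maintenance respiration (proportional to tissue N
    with a Q10 temperature response) and a fixed growth-respiration fraction
    of the positive balance; it may be negative. Transpiration demand (mm
    over the patch) follows from a fixed water-use efficiency.

    All inputs vectorise over individuals. Returns ``(gpp, npp, et_demand)``
    in kg C, kg C and mm·m² (divide by patch area for mm).
    """
    c_leaf = np.asarray(c_leaf, float)
    sla_a = np.asarray(sla, float)
    nmass = 1.0 / np.asarray(leaf_cn, float)            # kg N per kg leaf C
    narea = 1000.0 * nmass / (params.sla_area_per_c * sla_a)  # g N per m² leaf
    eps = params.eps_max * narea / (narea + params.eps_half_narea)  # g C / MJ

    f_t = np.exp(-0.5 * ((tair_c - params.t_opt) / params.t_width) ** 2)
    f_np = np.minimum(np.asarray(f_n, float), np.asarray(f_p, float))
    gpp = eps / 1000.0 * np.asarray(apar_mj, float) * f_t * f_water * f_np

    tissue_n = (
        c_leaf * nmass
        + np.asarray(c_root, float) * nmass * params.root_nmass_frac
        + np.asarray(c_wood, float) * params.wood_nmass
    )
    rm = params.maint_resp_per_n * tissue_n * params.q10_resp ** ((tair_c - params.resp_ref_t) / 10.0)
    balance = gpp - rm
    npp = np.where(balance > 0, balance * (1.0 - params.growth_resp_frac), balance)

    et_demand = gpp * 1000.0 / params.wue_g_per_kg      # kg H₂O = mm·m²
    return gpp, npp, et_demand


def allocate_and_grow(
    c_leaf,
    c_wood,
    c_root,
    sla,
    wsg,
    leaf_longevity,
    npp,
    params: GapModelParams,
):
    """Turnover and growth for one year (vectorised).

    Leaf and fine-root pools turn over at ``1/longevity`` into litter (fine
    roots share the leaf lifespan — the leaf-economics coupling). Positive
    NPP is split leaf/wood/root by fixed fractions; negative NPP depletes
    root, then leaf, then wood. A deficit larger than the pools cannot be
    respired: realised NPP is floored at −(total pools) and the shortfall
    reported as carbon stress so that the patch carbon budget stays exact.
    After growth, leaf area above the allometric crown capacity
    (``crown_lai_max`` per m² of crown) is shed to litter — no single tree
    can hold the whole canopy.

    Returns a dict with new pools, litter carbon, realised npp, growth per
    compartment and the stress total.
    """
    c_leaf = np.asarray(c_leaf, float).copy()
    c_wood = np.asarray(c_wood, float).copy()
    c_root = np.asarray(c_root, float).copy()
    npp = np.asarray(npp, float)
    turnover_rate = 1.0 / np.asarray(leaf_longevity, float)

    leaf_fall = np.minimum(c_leaf * turnover_rate, c_leaf)
    root_fall = np.minimum(c_root * turnover_rate, c_root)
    c_leaf -= leaf_fall
    c_root -= root_fall

    pos = np.maximum(npp, 0.0)
    g_leaf = pos * params.alloc_leaf
    g_wood = pos * params.alloc_wood
    g_root = pos * params.alloc_root

    deficit = np.maximum(-npp, 0.0)
    total_pool = c_leaf + c_wood + c_root
    stress = np.maximum(deficit - total_pool, 0.0)
    deficit = np.minimum(deficit, total_pool)
    realized_npp = np.where(npp > 0, npp, -(deficit))
    # deplete root, then leaf, then wood
    take_root = np.minimum(deficit, c_root)
    deficit_left = deficit - take_root
    take_leaf = np.minimum(deficit_left, c_leaf)
    deficit_left = deficit_left - take_leaf
    take_wood = np.minimum(deficit_left, c_wood)

    c_leaf = c_leaf + g_leaf - take_leaf
    c_wood = c_wood + g_wood - take_wood
    c_root = c_root + g_root - take_root

    # crown capacity: shed leaf carbon whose area exceeds what the crown holds
    heights = tree_height(c_wood, wsg, params)
    la_max = params.crown_lai_max * crown_area(heights, params)
    c_leaf_max = la_max / (params.sla_area_per_c * np.asarray(sla, float))
    shed = np.maximum(c_leaf - c_leaf_max, 0.0)
    c_leaf -= shed
    leaf_fall = leaf_fall + shed

    return {
        "c_leaf": c_leaf,
        "c_wood": c_wood,
        "c_root": c_root,
        "leaf_fall": leaf_fall,
        "root_fall": root_fall,
        "realized_npp": realized_npp,
        "g_leaf": g_leaf,
        "g_wood": g_wood,
        "g_root": g_root,
        "carbon_stress": float(stress.sum()),
    }


def death_probability(greff, wsg, params: GapModelParams):
    """Annual death probability: WSG-dependent background + growth-efficiency stress.

    Background hazard decreases with wood-specific gravity (the
    growth–survival trade-off); the stress term decreases with growth
    efficiency (realised NPP per unit leaf area). Clipped to [0, 1].
    """
    greff = np.asarray(greff, float)
    wsg = np.asarray(wsg, float)
    background = params.mort_background * np.exp(-params.mort_wsg_slope * (wsg - params.wsg_ref))
    stress = params.mort_stress_max / (1.0 + np.maximum(greff, 0.0) / params.greff_half)
    stress = np.where(greff < 0, params.mort_stress_max, stress)
    return np.clip(background + stress, 0.0, 1.0)


def mortality(greff, wsg, rng: np.random.Generator | int, params: GapModelParams):
    """Sample survival; returns a boolean array (True = survives)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    p_death = death_probability(greff, wsg, params)
    return rng.uniform(size=np.shape(p_death)) >= p_death


# ---------------------------------------------------------------------------
# The annual patch loop
# ---------------------------------------------------------------------------


def step_patch(
    patch: Patch,
    climate_year: dict,
    herb_settings: HerbivorySettings,
    mode: Mode,
    bounds: TraitBounds,
    curves_local: dict[str, TradeoffCurve],
    curves_global: dict[str, TradeoffCurve] | None,
    rng: np.random.Generator,
    establishment_rate: float | None = None,
    stochastic_traits: bool = True,
) -> dict:
    """Advance one patch one year; returns the annual flux/state record.

    Order: soil water → light partitioning → production → herbivory →
    allocation/turnover → mortality → establishment → litter decay and
    nutrient mineralisation. ``climate_year`` needs keys tair_c, precip_mm,
    rad_mj_m2_d, n_in_kg_ha_yr, p_in_kg_ha_yr.
    """
    p = patch.params
    tair = float(climate_year["tair_c"])
    precip = float(climate_year["precip_mm"])
    rad = float(climate_year["rad_mj_m2_d"])

    c_before = patch.total_c

    # soil water: 12 equal monthly steps against last year's transpiration demand
    pet = p.pet_per_degc * max(tair, 0.0)
    et_demand_mm = min(patch.last_et_demand_mm, pet)
    f_w_acc, aet_mm = 0.0, 0.0
    for _ in range(12):
        f_w_acc += patch.soil.availability
        patch.soil, aet, _, _ = step_soil_water(patch.soil, precip / 12.0, et_demand_mm / 12.0)
        aet_mm += aet
    f_water = f_w_acc / 12.0

    n_ind = patch.n_individuals
    record: dict[str, float] = {}

    if n_ind > 0:
        la = patch.leaf_areas()
        frac = partition_light(patch.heights(), la, patch.area_m2, p.k_ext)
        par_annual = rad * 365.0 * p.par_fraction          # MJ m⁻² yr⁻¹
        apar = par_annual * frac * patch.area_m2           # MJ per individual

        nmass = 1.0 / patch.leaf_cn
        pmass = 1.0 / patch.leaf_cp
        f_n = patch.avail_n / (patch.avail_n + p.n_half * nmass / p.nmass_ref)
        f_p = patch.avail_p / (patch.avail_p + p.p_half * pmass / p.pmass_ref)

        gpp, npp, et_dem = annual_production(
            patch.c_leaf, patch.c_wood, patch.c_root,
            patch.sla, patch.leaf_cn,
            apar, tair, f_water, f_n, f_p, p,
        )
        patch.last_et_demand_mm = float(et_dem.sum() / patch.area_m2)

        # herbivory on the post-production leaf pool
        rate = realized_rate(herb_settings, tair, patch.sla)
        consumed_i = np.asarray(rate) * patch.c_leaf
        new_leaf, herb = apply_herbivory(patch.c_leaf, rate, herb_settings)
        frass_share = 1.0 - herb_settings.assimilation_fraction
        frass_n = float((consumed_i * nmass).sum()) * frass_share * patch.ha_factor
        frass_p = float((consumed_i * pmass).sum()) * frass_share * patch.ha_factor
        patch.c_leaf = np.asarray(new_leaf, float)
        patch.litter_c += herb.frass_to_litter
        patch.litter_n += frass_n
        patch.litter_p += frass_p

        grown = allocate_and_grow(
            patch.c_leaf, patch.c_wood, patch.c_root,
            patch.sla, patch.wsg, patch.leaf_longevity, npp, p,
        )
        litterfall_c = float(grown["leaf_fall"].sum() + grown["root_fall"].sum())
        litterfall_n = float(
            ((grown["leaf_fall"] + grown["root_fall"] * p.root_nmass_frac) * nmass).sum()
        ) * patch.ha_factor
        litterfall_p = float(
            ((grown["leaf_fall"] + grown["root_fall"] * p.root_nmass_frac) * pmass).sum()
        ) * patch.ha_factor
        patch.litter_c += litterfall_c
        patch.litter_n += litterfall_n
        patch.litter_p += litterfall_p
        patch.carbon_stress += grown["carbon_stress"]

        # nutrient uptake follows realised growth, capped by the pools
        demand_n = float(
            (grown["g_leaf"] * nmass + grown["g_root"] * nmass * p.root_nmass_frac).sum()
            + grown["g_wood"].sum() * p.wood_nmass
        ) * patch.ha_factor
        demand_p = float(
            (grown["g_leaf"] * pmass + grown["g_root"] * pmass * p.root_nmass_frac).sum()
            + grown["g_wood"].sum() * p.wood_pmass
        ) * patch.ha_factor
        patch.avail_n -= min(demand_n, patch.avail_n)
        patch.avail_p -= min(demand_p, patch.avail_p)

        patch.c_leaf = grown["c_leaf"]
        patch.c_wood = grown["c_wood"]
        patch.c_root = grown["c_root"]
        realized_npp = grown["realized_npp"]

        # mortality on realised growth efficiency
        la_now = np.maximum(patch.leaf_areas(), 1e-6)
        greff = realized_npp / la_now
        survives = mortality(greff, patch.wsg, rng, p)
        dead = ~survives
        mort_c = float(
            patch.c_leaf[dead].sum() + patch.c_wood[dead].sum() + patch.c_root[dead].sum()
        )
        mort_n = float(
            (patch.c_leaf[dead] * nmass[dead]).sum()
            + (patch.c_root[dead] * nmass[dead] * p.root_nmass_frac).sum()
            + patch.c_wood[dead].sum() * p.wood_nmass
        ) * patch.ha_factor
        mort_p = float(
            (patch.c_leaf[dead] * pmass[dead]).sum()
            + (patch.c_root[dead] * pmass[dead] * p.root_nmass_frac).sum()
            + patch.c_wood[dead].sum() * p.wood_pmass
        ) * patch.ha_factor
        patch.litter_c += mort_c
        patch.litter_n += mort_n
        patch.litter_p += mort_p
        patch.keep(survives)
        patch.age += 1.0

        record.update(
            gpp=float(gpp.sum()),
            npp=float(realized_npp.sum()),
            nppa=float((np.maximum(realized_npp, 0.0) * (p.alloc_leaf + p.alloc_wood)).sum()),
            litterfall=litterfall_c,
            mortality_c=mort_c,
            herb_consumed=herb.consumed,
            herb_respired=herb.respired,
            herb_frass=herb.frass_to_litter,
            herb_retained=herb.herbivore_retained,
            f_water=f_water,
            f_n=float(np.mean(f_n)),
            f_p=float(np.mean(f_p)),
        )
    else:
        patch.last_et_demand_mm = 0.0
        record.update(
            gpp=0.0, npp=0.0, nppa=0.0, litterfall=0.0, mortality_c=0.0,
            herb_consumed=0.0, herb_respired=0.0, herb_frass=0.0, herb_retained=0.0,
            f_water=f_water, f_n=1.0, f_p=1.0,
        )

    # establishment
    rate = p.establishment_rate if establishment_rate is None else establishment_rate
    est_c = establish(
        patch, rate, mode, bounds, curves_local, curves_global, rng, stochastic_traits
    )

    # litter decay and nutrient mineralisation, then external input and leaching
    decay_frac = min(
        p.litter_decay_ref * p.q10_soil ** ((tair - p.resp_ref_t) / 10.0), p.litter_decay_max
    )
    rh = decay_frac * patch.litter_c
    patch.litter_c -= rh
    mineral_n = decay_frac * patch.litter_n
    mineral_p = decay_frac * patch.litter_p
    patch.litter_n -= mineral_n
    patch.litter_p -= mineral_p
    patch.avail_n = (patch.avail_n + mineral_n + float(climate_year["n_in_kg_ha_yr"])) * (
        1.0 - p.nutrient_leach
    )
    patch.avail_p = (patch.avail_p + mineral_p + float(climate_year["p_in_kg_ha_yr"])) * (
        1.0 - p.nutrient_leach
    )

    record.update(est_c=est_c, rh=rh, plant_c=patch.plant_c, litter_c=patch.litter_c)

    # exact per-year carbon identity (see module docstring)
    delta_c = patch.total_c - c_before
    expected = record["npp"] + est_c - rh - record["herb_respired"] - record["herb_retained"]
    gross = abs(record["gpp"]) + abs(rh) + abs(est_c) + 1e-12
    record["c_balance_residual"] = (delta_c - expected) / gross

    summary = community_summary(patch)
    record.update(
        lai=summary.lai,
        stems_ha=summary.stem_count_ha,
        basal_area_m2_ha=summary.basal_area_m2_ha,
        cwm_sla=summary.cwm_sla,
        cwm_wsg=summary.cwm_wsg,
        sla_variance=summary.sla_variance,
        swc=patch.soil.swc,
        aet_mm=aet_mm,
        avail_n=patch.avail_n,
        avail_p=patch.avail_p,
    )
    return record


def community_summary(
    patch: Patch,
    weighting: str = "abundance",
    min_height_m: float | None = None,
) -> CommunityState:
    """Community-weighted means and stand structure for one patch.

    ``weighting``: ``abundance`` (every censused individual weighs 1, the
    default) or ``leaf_mass`` (weights = leaf carbon). Following field
    practice, the census covers trees at or above ``min_height_m`` (default:
    the parameter set's ``census_min_height_m``); when no tree qualifies,
    all individuals are used. LAI integrates everything regardless. An empty
    community reports zero LAI/stems and NaN community-weighted means
    flagged missing.
    """
    if weighting not in ("abundance", "leaf_mass"):
        raise ValueError("weighting must be 'abundance' or 'leaf_mass'")
    n = patch.n_individuals
    if n == 0:
        return CommunityState()
    p = patch.params
    cutoff = p.census_min_height_m if min_height_m is None else min_height_m
    heights = patch.heights()
    census = heights >= cutoff
    if not census.any():
        census = np.ones(n, dtype=bool)
    w = np.ones(int(census.sum())) if weighting == "abundance" else patch.c_leaf[census]
    if w.sum() <= 0:
        w = np.ones(int(census.sum()))
    wsum = w.sum()
    sla_c = patch.sla[census]
    cwm_sla = float((w * sla_c).sum() / wsum)
    cwm_wsg = float((w * patch.wsg[census]).sum() / wsum)
    var_sla = float((w * (sla_c - cwm_sla) ** 2).sum() / wsum)
    vol = stem_volume(patch.c_wood[census], patch.wsg[census], p)
    ba = vol / (p.stem_form_factor * np.maximum(heights[census], 1e-3))
    return CommunityState(
        lai=patch.lai,
        stem_count_ha=int(census.sum()) * patch.ha_factor,
        basal_area_m2_ha=float(ba.sum()) * patch.ha_factor,
        cwm_sla=cwm_sla,
        cwm_wsg=cwm_wsg,
        sla_variance=var_sla,
        cwm_missing=False,
    )


# ---------------------------------------------------------------------------
# Site runs
# ---------------------------------------------------------------------------


@dataclass
class SiteRun:
    """Result of one site × mode simulation."""

    site: SitePlan
    mode: str
    annual: pd.DataFrame          # one row per patch-year
    window_means: pd.Series       # means over patches and the final window
    years: int
    average_window: int


def run_site(
    site: SitePlan,
    forcing: ClimateForcing,
    mode: Mode,
    years: int = 700,
    average_window: int = 200,
    rng_seed: int = 0,
    params: GapModelParams | None = None,
    bounds: TraitBounds | None = None,
    curves_local: dict[str, TradeoffCurve] | None = None,
    curves_global: dict[str, TradeoffCurve] | None = None,
    herb_settings: HerbivorySettings | None = None,
    stochastic_traits: bool = True,
) -> SiteRun:
    """Run every patch of a site independently and average the final window.

    Patches are seeded from independent spawns of ``rng_seed``, so patch i's
    trajectory does not depend on whether patch j exists. Reported window
    means are taken over all patches and the last ``average_window`` years
    (the community-composition statistics ignore empty-patch years).
    """
    if average_window > years:
        raise ValueError("average_window must be <= years")
    if forcing.years < years:
        raise ValueError("forcing series shorter than the simulation")
    params = params or GapModelParams()
    bounds = bounds or TraitBounds()
    curves_local = curves_local or default_curves("local")
    curves_global = curves_global or default_curves("global")
    herb_settings = herb_settings or HerbivorySettings()

    seeds = np.random.SeedSequence(rng_seed).spawn(site.n_patches)
    rows = []
    for ipatch, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        patch = Patch(area_m2=site.patch_area_m2, params=params)
        for year in range(years):
            climate_year = {
                "tair_c": forcing.tair_c[year],
                "precip_mm": forcing.precip_mm[year],
                "rad_mj_m2_d": forcing.rad_mj_m2_d[year],
                "n_in_kg_ha_yr": forcing.n_in_kg_ha_yr[year],
                "p_in_kg_ha_yr": forcing.p_in_kg_ha_yr[year],
            }
            rec = step_patch(
                patch, climate_year, herb_settings, mode,
                bounds, curves_local, curves_global, rng,
                stochastic_traits=stochastic_traits,
            )
            rec.update(site=site.site_id, patch=ipatch, year=year + 1)
            rows.append(rec)
    annual = pd.DataFrame(rows)
    area_m2 = site.patch_area_m2
    annual["npp_kg_m2"] = annual["npp"] / area_m2
    annual["npp_mg_ha"] = annual["npp_kg_m2"] * 10.0
    annual["nppa_mg_ha"] = annual["nppa"] / area_m2 * 10.0
    annual["gpp_kg_m2"] = annual["gpp"] / area_m2

    window = annual[annual["year"] > years - average_window]
    mean_cols = [
        "npp_kg_m2", "npp_mg_ha", "nppa_mg_ha", "gpp_kg_m2", "lai", "stems_ha",
        "basal_area_m2_ha", "cwm_sla", "cwm_wsg", "sla_variance",
        "herb_consumed", "herb_respired", "f_water", "f_n", "f_p",
    ]
    window_means = window[mean_cols].mean()
    window_means["npp_sd_across_patches"] = (
        window.groupby("patch")["npp_mg_ha"].mean().std(ddof=1) if site.n_patches > 1 else 0.0
    )
    window_means["max_abs_c_residual"] = annual["c_balance_residual"].abs().max()
    return SiteRun(
        site=site,
        mode=mode,
        annual=annual,
        window_means=window_means,
        years=years,
        average_window=average_window,
    )
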