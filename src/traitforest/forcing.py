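"""Synthetic site forcing along an elevation gradient, and a soil-water bucket.

Emulates the hydro-climate stations of a tropical montane gradient
(1000–3000 m a.s.l.): mean annual temperature falls with elevation at a
configurable lapse rate, precipitation rises, radiation changes weakly, and
atmospheric nutrient input (deposition + weathering) declines. Climate-change
scenarios are expressed as a temperature delta (°C, additive) and a
precipitation delta (fractional, multiplicative).

The full catchment hydrology of the source framework is replaced here by a
single-layer soil-water bucket — the minimum structure that lets soil water
limit growth while closing a water balance exactly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SitePlan",
    "ClimateParams",
    "ClimateForcing",
    "SoilWaterParams",
    "SoilWaterState",
    "generate_forcing",
    "step_soil_water",
]

logger = logging.getLogger(__name__)

FORCING_COLUMNS = ("year", "tair_c", "precip_mm", "rad_mj_m2_d", "n_in_kg_ha_yr", "p_in_kg_ha_yr")


@dataclass(frozen=True)
class SitePlan:
    """One simulated site: a 1-ha-scale plot at a given elevation."""

    site_id: str
    elevation: float  # m a.s.l.
    area_ha: float = 1.0
    patch_area_m2: float = 1000.0

    def __post_init__(self) -> None:
        if not (500.0 <= self.elevation <= 4000.0):
            raise ValueError("elevation must lie in [500, 4000] m a.s.l.")
        if self.area_ha <= 0:
            raise ValueError("area_ha must be > 0")
        if self.n_patches < 1:
            raise ValueError("site must contain at least one patch")

    @property
    def n_patches(self) -> int:
        return max(1, round(self.area_ha * 10_000.0 / self.patch_area_m2))


@dataclass(frozen=True)
class ClimateParams:
    """Baseline climate at the 1000 m reference elevation and its gradients.

    Values are generator choices for a wet tropical montane gradient, all
    configurable: MAT 19 °C at 1000 m with a 5.5 K/km lapse; precipitation
    ~2000 mm/yr rising ~800 mm per km; shortwave radiation ~15 MJ m⁻² d⁻¹;
    N and P input (deposition + weathering) declining with elevation.
    """

    mat_1000: float = 19.0          # °C at the reference elevation
    lapse_k_per_km: float = 5.5
    temp_sd: float = 0.4            # interannual Gaussian sd, °C
    precip_1000: float = 2000.0     # mm/yr
    precip_per_km: float = 800.0    # mm/yr per km of elevation
    precip_cv: float = 0.15         # lognormal interannual CV
    rad_1000: float = 15.0          # MJ m⁻² d⁻¹
    rad_per_km: float = 0.5
    rad_sd: float = 0.4
    n_in_1000: float = 25.0         # kg N ha⁻¹ yr⁻¹
    n_in_per_km: float = -9.0
    p_in_1000: float = 2.0          # kg P ha⁻¹ yr⁻¹
    p_in_per_km: float = -0.75
    ref_elevation: float = 1000.0


@dataclass
class ClimateForcing:
    """Annual driver series for one site (arrays of equal length ``years``)."""

    site_id: str
    tair_c: np.ndarray
    precip_mm: np.ndarray
    rad_mj_m2_d: np.ndarray
    n_in_kg_ha_yr: np.ndarray
    p_in_kg_ha_yr: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.tair_c)
        for name in ("precip_mm", "rad_mj_m2_d", "n_in_kg_ha_yr", "p_in_kg_ha_yr"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise ValueError("all forcing series must have equal length")
            if np.any(arr < 0):
                raise ValueError(f"{name} must be non-negative")

    @property
    def years(self) -> int:
        return len(self.tair_c)

    @property
    def mat(self) -> float:
        """Long-run mean annual temperature, °C."""
        return float(np.mean(self.tair_c))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": np.arange(1, self.years + 1),
                "tair_c": self.tair_c,
                "precip_mm": self.precip_mm,
                "rad_mj_m2_d": self.rad_mj_m2_d,
                "n_in_kg_ha_yr": self.n_in_kg_ha_yr,
                "p_in_kg_ha_yr": self.p_in_kg_ha_yr,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, site_id: str = "csv") -> "ClimateForcing":
        df = pd.read_csv(path, comment="#")
        missing = [c for c in FORCING_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"forcing CSV missing column(s) {missing}")
        return cls(
            site_id=site_id,
            tair_c=df["tair_c"].to_numpy(float),
            precip_mm=df["precip_mm"].to_numpy(float),
            rad_mj_m2_d=df["rad_mj_m2_d"].to_numpy(float),
            n_in_kg_ha_yr=df["n_in_kg_ha_yr"].to_numpy(float),
            p_in_kg_ha_yr=df["p_in_kg_ha_yr"].to_numpy(float),
        )


def generate_forcing(
    site: SitePlan,
    years: int,
    params: ClimateParams | None = None,
    scenario: tuple[float, float] = (0.0, 0.0),
    rng_seed: int | np.random.Generator = 0,
) -> ClimateForcing:
    """Generate stationary annual forcing for a site.

    ``scenario = (dT, dP)``: dT (°C) shifts every temperature value exactly;
    dP (fraction) rescales the precipitation mean multiplicatively by
    ``1 + dP``. Deterministic under a fixed seed.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    p = params or ClimateParams()
    d_t, d_p = scenario
    if 1.0 + d_p < 0:
        raise ValueError("precipitation scenario would be negative")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    km = (site.elevation - p.ref_elevation) / 1000.0

    mat = p.mat_1000 - p.lapse_k_per_km * km + d_t
    tair = mat + rng.normal(0.0, p.temp_sd, size=years)

    precip_mean = max(p.precip_1000 + p.precip_per_km * km, 0.0) * (1.0 + d_p)
    if precip_mean > 0:
        sigma = np.sqrt(np.log(1.0 + p.precip_cv**2))
        mu = np.log(precip_mean) - 0.5 * sigma**2
        precip = rng.lognormal(mu, sigma, size=years)
    else:
        precip = np.zeros(years)

    rad = np.maximum(p.rad_1000 + p.rad_per_km * km + rng.normal(0.0, p.rad_sd, size=years), 0.1)
    n_in = np.full(years, max(p.n_in_1000 + p.n_in_per_km * km, 0.0))
    p_in = np.full(years, max(p.p_in_1000 + p.p_in_per_km * km, 0.0))

    return ClimateForcing(
        site_id=site.site_id,
        tair_c=tair,
        precip_mm=precip,
        rad_mj_m2_d=rad,
        n_in_kg_ha_yr=n_in,
        p_in_kg_ha_yr=p_in,
    )


# ---------------------------------------------------------------------------
# Single-layer soil-water bucket
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SoilWaterParams:
    """Bucket geometry: volumetric thresholds over a fixed rooting depth."""

    depth_mm: float = 1000.0
    wilting_point: float = 0.15       # m³/m³
    field_capacity: float = 0.35
    saturation: float = 0.45
    max_drainage_mm: float = 500.0    # per step

    def __post_init__(self) -> None:
        if not (0.0 <= self.wilting_point <= self.field_capacity <= self.saturation):
            raise ValueError("require 0 <= wilting <= field capacity <= saturation")
        if self.depth_mm <= 0 or self.max_drainage_mm < 0:
            raise ValueError("depth_mm > 0 and max_drainage_mm >= 0 required")


@dataclass(frozen=True)
class SoilWaterState:
    """Volumetric soil water content plus its bucket parameters."""

    swc: float
    params: SoilWaterParams = field(default_factory=SoilWaterParams)

    def __post_init__(self) -> None:
        if not (self.params.wilting_point - 1e-12 <= self.swc <= self.params.saturation + 1e-12):
            raise ValueError("swc must lie within [wilting point, saturation]")

    @property
    def storage_mm(self) -> float:
        return self.swc * self.params.depth_mm

    @property
    def availability(self) -> float:
        """Relative plant-available water in [0, 1] (wilting → 0, field capacity → 1)."""
        p = self.params
        span = p.field_capacity - p.wilting_point
        if span <= 0:
            return 0.0
        return float(np.clip((self.swc - p.wilting_point) / span, 0.0, 1.0))


def step_soil_water(
    state: SoilWaterState,
    precip_mm: float,
    et_demand_mm: float,
) -> tuple[SoilWaterState, float, float, float]:
    """Advance the bucket one step; returns (state, actual ET, drainage, runoff).

    Transpiration supply falls linearly from the demand at field capacity to
    zero at the wilting point; water above field capacity drains (up to the
    drainage capacity) and anything above saturation runs off. The balance
    ``Δstorage = precip − ET − drainage − runoff`` closes to machine precision
    by construction. Negative inputs are clipped to zero with a logged warning.
    """
    if precip_mm < 0 or et_demand_mm < 0:
        logger.warning(
            "negative forcing clipped to zero (precip=%s, et_demand=%s)", precip_mm, et_demand_mm
        )
        precip_mm = max(precip_mm, 0.0)
        et_demand_mm = max(et_demand_mm, 0.0)
    p = state.params

    supply_scalar = state.availability
    available_mm = max(state.storage_mm - p.wilting_point * p.depth_mm, 0.0)
    actual_et = min(et_demand_mm * supply_scalar, available_mm + precip_mm)

    storage = state.storage_mm + precip_mm - actual_et

    fc_mm = p.field_capacity * p.depth_mm
    sat_mm = p.saturation * p.depth_mm
    drainage = 0.0
    runoff = 0.0
    if storage > fc_mm:
        drainage = min(storage - fc_mm, p.max_drainage_mm)
        storage -= drainage
    if storage > sat_mm:
        runoff = storage - sat_mm
        storage = sat_mm

    new_state = SoilWaterState(swc=storage / p.depth_mm, params=p)
    return new_state, actual_et, drainage, runoff
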