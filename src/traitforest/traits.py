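"""Trait continuum: uniform key-trait draws and trade-off-derived dependent traits.

Instead of discrete plant functional types, every established individual gets a
random pair of key traits — specific leaf area (SLA, cm²/g) and wood-specific
gravity (WSG, dimensionless) — drawn independently and uniformly from configured
bounds. Dependent traits (leaf C:N, leaf C:P, leaf longevity) are then filled in
through fitted trade-off curves, power laws in the leaf-economics-spectrum
convention: linear on log–log axes, optionally with a lognormal residual scatter
representing within-key-trait variation between individuals.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEPENDENT_TRAITS",
    "TraitBounds",
    "TradeoffCurve",
    "TraitSet",
    "draw_key_traits",
    "fit_tradeoff_curve",
    "derive_dependent_traits",
    "default_curves",
    "read_trait_table",
    "fit_curves_from_table",
]

#: Dependent traits every curve set must cover.
DEPENDENT_TRAITS = ("leaf_cn", "leaf_cp", "leaf_longevity")

#: Column names required of a delimited trait table.
TRAIT_TABLE_COLUMNS = ("species_id", "sla_cm2_g", "wsg", "leaf_cn", "leaf_cp")


class ConfigurationError(ValueError):
    """Raised when bounds, curves or tables violate their invariants."""


@dataclass(frozen=True)
class TraitBounds:
    """Uniform sampling bounds for the two key traits.

    SLA in cm²/g; WSG dimensionless (oven-dry mass over green volume,
    relative to water). Bounds must be strictly positive and ordered.
    """

    sla_min: float = 60.0
    sla_max: float = 250.0
    wsg_min: float = 0.35
    wsg_max: float = 0.85

    def __post_init__(self) -> None:
        for lo, hi, name in (
            (self.sla_min, self.sla_max, "sla"),
            (self.wsg_min, self.wsg_max, "wsg"),
        ):
            if lo <= 0 or hi <= 0:
                raise ConfigurationError(f"{name} bounds must be strictly positive")
            if lo > hi:
                raise ConfigurationError(f"{name}_min > {name}_max ({lo} > {hi})")

    @property
    def sla_mid(self) -> float:
        return 0.5 * (self.sla_min + self.sla_max)

    @property
    def wsg_mid(self) -> float:
        return 0.5 * (self.wsg_min + self.wsg_max)


@dataclass(frozen=True)
class TradeoffCurve:
    """A fitted key-trait → dependent-trait power law.

    ``log(dependent) = intercept + slope * log(key) + N(0, residual_sd)``

    ``residual_sd`` is the df-corrected (n−2) root mean squared residual on
    the natural-log scale; ``provenance`` records whether the curve came from
    a local trait table or a global (TRY-like) database stand-in.
    """

    dependent_name: str
    key_name: str
    intercept: float
    slope: float
    residual_sd: float = 0.0
    provenance: str = "local"

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ConfigurationError("residual_sd must be >= 0")
        if self.provenance not in ("local", "global"):
            raise ConfigurationError(
                f"provenance must be 'local' or 'global', got {self.provenance!r}"
            )

    def predict(self, key, *, stochastic: bool = False, rng: np.random.Generator | None = None):
        """Evaluate the curve at ``key`` (scalar or array).

        In stochastic mode a log-scale Gaussian deviate with sd
        ``residual_sd`` is added per element before exponentiating.
        """
        key = np.asarray(key, dtype=float)
        if np.any(key <= 0):
            raise ValueError(f"{self.key_name} must be strictly positive")
        log_mu = self.intercept + self.slope * np.log(key)
        if stochastic and self.residual_sd > 0:
            if rng is None:
                raise ValueError("stochastic prediction requires an rng")
            log_mu = log_mu + rng.normal(0.0, self.residual_sd, size=np.shape(key))
        out = np.exp(log_mu)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class TraitSet:
    """One individual's full trait vector (or a vector of individuals).

    Fields may be scalars or equally shaped numpy arrays; all values are
    strictly positive, with SLA and WSG inside the configured bounds.
    """

    sla: float | np.ndarray
    wsg: float | np.ndarray
    leaf_cn: float | np.ndarray
    leaf_cp: float | np.ndarray
    leaf_longevity: float | np.ndarray

    def validate(self, bounds: TraitBounds | None = None) -> "TraitSet":
        for name in ("sla", "wsg", "leaf_cn", "leaf_cp", "leaf_longevity"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"trait {name} must be strictly positive")
        if bounds is not None:
            sla = np.asarray(self.sla)
            wsg = np.asarray(self.wsg)
            if np.any(sla < bounds.sla_min) or np.any(sla > bounds.sla_max):
                raise ValueError("sla outside configured bounds")
            if np.any(wsg < bounds.wsg_min) or np.any(wsg > bounds.wsg_max):
                raise ValueError("wsg outside configured bounds")
        return self


def draw_key_traits(
    bounds: TraitBounds,
    n: int,
    rng_seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw ``n`` independent uniform (SLA, WSG) pairs.

    Returns an ``(n, 2)`` array, column 0 SLA, column 1 WSG. SLA and WSG are
    sampled i.i.d. and independently of each other; a degenerate interval
    (min == max) yields constant values.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    out = np.empty((n, 2), dtype=float)
    out[:, 0] = rng.uniform(bounds.sla_min, bounds.sla_max, size=n)
    out[:, 1] = rng.uniform(bounds.wsg_min, bounds.wsg_max, size=n)
    return out


def fit_tradeoff_curve(
    pairs: Sequence[tuple[float, float]] | np.ndarray,
    dependent_name: str,
    key_name: str = "sla",
    provenance: str = "local",
) -> TradeoffCurve:
    """Ordinary least squares of log(dependent) on log(key).

    Requires at least 3 strictly positive pairs; ``residual_sd`` is the
    df-corrected (n − 2) root mean squared log-scale residual.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (key, dependent) tuples")
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 pairs to fit a trade-off curve")
    if np.any(arr <= 0):
        raise ValueError("all key and dependent values must be strictly positive")
    x = np.log(arr[:, 0])
    y = np.log(arr[:, 1])
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n = len(y)
    residual_sd = float(np.sqrt(np.sum(resid**2) / (n - 2)))
    # exact collinearity can leave a tiny negative-rounding artefact
    if residual_sd < 1e-12:
        residual_sd = 0.0
    return TradeoffCurve(
        dependent_name=dependent_name,
        key_name=key_name,
        intercept=float(beta[0]),
        slope=float(beta[1]),
        residual_sd=residual_sd,
        provenance=provenance,
    )


def derive_dependent_traits(
    sla,
    wsg,
    curves: Mapping[str, TradeoffCurve],
    stochastic: bool = True,
    rng_seed: int | np.random.Generator = 0,
    floor: float = 1e-6,
) -> TraitSet:
    """Fill in dependent traits from the key traits through the curve set.

    ``curves`` must provide one :class:`TradeoffCurve` per name in
    :data:`DEPENDENT_TRAITS` (all keyed on SLA by default). Deterministic
    mode evaluates the mean curve; stochastic mode scatters each individual
    lognormally around it with the curve's residual sd. Results are clipped
    below at ``floor`` to guard degenerate curves.
    """
    missing = [t for t in DEPENDENT_TRAITS if t not in curves]
    if missing:
        raise ConfigurationError(f"missing trade-off curve(s) for {missing}")
    sla_a = np.asarray(sla, dtype=float)
    wsg_a = np.asarray(wsg, dtype=float)
    if np.any(sla_a <= 0) or np.any(wsg_a <= 0):
        raise ValueError("sla and wsg must be strictly positive")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    values: dict[str, np.ndarray] = {}
    for name in DEPENDENT_TRAITS:
        curve = curves[name]
        key = sla_a if curve.key_name == "sla" else wsg_a
        pred = np.asarray(curve.predict(key, stochastic=stochastic, rng=rng))
        values[name] = np.maximum(pred, floor)
    scalar = sla_a.ndim == 0

    def _maybe_scalar(v):
        return float(v) if scalar else v

    return TraitSet(
        sla=_maybe_scalar(sla_a),
        wsg=_maybe_scalar(wsg_a),
        leaf_cn=_maybe_scalar(values["leaf_cn"]),
        leaf_cp=_maybe_scalar(values["leaf_cp"]),
        leaf_longevity=_maybe_scalar(values["leaf_longevity"]),
    )


# ---------------------------------------------------------------------------
# Packaged default curve sets
# ---------------------------------------------------------------------------
# Synthetic stand-ins with documented parameters (no real TRY data are
# bundled). The "local" set is steeper: leaf nitrogen and phosphorus fall
# faster with SLA than in the shallower "global" set, and leaf lifespan is
# more strongly coupled to SLA — the structural difference the three-site
# experiment exercises.

_DEFAULT_CURVE_PARAMS = {
    # name: (provenance -> (value at SLA=100 cm²/g, log-log slope, residual sd))
    "leaf_cn": {"local": (22.0, -0.55, 0.12), "global": (14.0, -0.35, 0.18)},
    "leaf_cp": {"local": (350.0, -0.45, 0.15), "global": (220.0, -0.28, 0.20)},
    "leaf_longevity": {"local": (1.20, -0.90, 0.15), "global": (1.00, -0.70, 0.20)},
}


def default_curves(provenance: str = "local") -> dict[str, TradeoffCurve]:
    """Packaged synthetic trade-off curve set (``local`` or ``global``).

    Each curve is parameterised by its value at SLA = 100 cm²/g and its
    log–log slope; the intercept follows as ``log(v100) − slope·log(100)``.
    """
    if provenance not in ("local", "global"):
        raise ConfigurationError("provenance must be 'local' or 'global'")
    curves = {}
    for name, by_prov in _DEFAULT_CURVE_PARAMS.items():
        v100, slope, rsd = by_prov[provenance]
        intercept = math.log(v100) - slope * math.log(100.0)
        curves[name] = TradeoffCurve(
            dependent_name=name,
            key_name="sla",
            intercept=intercept,
            slope=slope,
            residual_sd=rsd,
            provenance=provenance,
        )
    return curves


def read_trait_table(path) -> pd.DataFrame:
    """Read a delimited trait table (CSV, UTF-8, mandatory header).

    Columns: species_id, sla_cm2_g, wsg, leaf_cn, leaf_cp. Lines starting
    with ``#`` are treated as comments (fixture generators embed their
    generating parameters that way).
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TRAIT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"trait table missing column(s) {missing}")
    return df


def fit_curves_from_table(
    df: pd.DataFrame,
    provenance: str = "local",
    longevity_fallback: TradeoffCurve | None = None,
) -> dict[str, TradeoffCurve]:
    """Fit SLA→C:N and SLA→C:P curves from a trait table.

    Leaf longevity is rarely in local tables; it defaults to the packaged
    global curve unless ``longevity_fallback`` overrides it or the table
    carries a ``leaf_longevity`` column.
    """
    curves: dict[str, TradeoffCurve] = {}
    for dep in ("leaf_cn", "leaf_cp"):
        pairs = df[["sla_cm2_g", dep]].to_numpy(dtype=float)
        curves[dep] = fit_tradeoff_curve(pairs, dep, "sla", provenance)
    if "leaf_longevity" in df.columns:
        pairs = df[["sla_cm2_g", "leaf_longevity"]].to_numpy(dtype=float)
        curves["leaf_longevity"] = fit_tradeoff_curve(pairs, "leaf_longevity", "sla", provenance)
    elif longevity_fallback is not None:
        curves["leaf_longevity"] = longevity_fallback
    else:
        curves["leaf_longevity"] = default_curves("global")["leaf_longevity"]
    return curves
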