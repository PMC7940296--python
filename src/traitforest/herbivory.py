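"""Herbivory as an energy/carbon transformation through a herbivore compartment.

The herbivore community is not a dynamic state variable; it is a flux
transformer with two elements: (1) leaf input to herbivores, removing a
fraction of each individual's leaf mass per year, and (2) respiration losses
of the assimilated leaf carbon through herbivore metabolism. Unassimilated
carbon returns to the litter as frass; assimilated-but-unrespired carbon is
retained in herbivore biomass and exported from the patch (eaten, emigrated —
not recycled).

The realised removal rate responds negatively to mean annual temperature by
default (the empirically observed direction along the gradient) and is, by
default, independent of SLA (no palatability–SLA association was observed).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HerbivorySettings", "HerbivoryFluxes", "realized_rate", "apply_herbivory"]


@dataclass(frozen=True)
class HerbivorySettings:
    """Herbivore energy-transformation parameters.

    ``base_rate``: fraction of leaf mass removed per year at the reference
    temperature. ``temp_sensitivity``: per-°C log-linear modifier (negative
    default). ``assimilation_fraction`` / ``respiration_fraction``: Wiegert-
    Petersen-style transformation efficiencies (assimilated share of consumed
    C; respired share of assimilated C). ``palatability_slope``: optional
    log-linear SLA modifier around 100 cm²/g, default 0.
    """

    base_rate: float = 0.06
    temp_sensitivity: float = -0.04   # per °C
    reference_temp: float = 13.5      # °C, mid-gradient
    assimilation_fraction: float = 0.4
    respiration_fraction: float = 0.6
    palatability_slope: float = 0.0

    def __post_init__(self) -> None:
        for name in ("base_rate", "assimilation_fraction", "respiration_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class HerbivoryFluxes:
    """Per patch-year carbon fluxes through the herbivore compartment (kg C).

    Identities: consumed = assimilated + frass_to_litter;
    respired + herbivore_retained = assimilated.
    """

    consumed: float = 0.0
    assimilated: float = 0.0
    respired: float = 0.0
    frass_to_litter: float = 0.0
    herbivore_retained: float = 0.0

    def __add__(self, other: "HerbivoryFluxes") -> "HerbivoryFluxes":
        return HerbivoryFluxes(
            self.consumed + other.consumed,
            self.assimilated + other.assimilated,
            self.respired + other.respired,
            self.frass_to_litter + other.frass_to_litter,
            self.herbivore_retained + other.herbivore_retained,
        )


def realized_rate(settings: HerbivorySettings, mat, sla=100.0):
    """Realised annual leaf-removal fraction at a given MAT and SLA.

    ``rate = base · exp(temp_sensitivity · (MAT − T_ref)) · (SLA/100)^palatability``,
    clipped to [0, 1]. Vectorises over ``mat`` and/or ``sla``.
    """
    mat = np.asarray(mat, dtype=float)
    sla = np.asarray(sla, dtype=float)
    rate = settings.base_rate * np.exp(settings.temp_sensitivity * (mat - settings.reference_temp))
    if settings.palatability_slope != 0.0:
        rate = rate * (sla / 100.0) ** settings.palatability_slope
    else:
        rate = rate * np.ones_like(sla)
    out = np.clip(rate, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def apply_herbivory(leaf_c, rate, settings: HerbivorySettings):
    """Remove leaf carbon at ``rate`` and route it through the compartment.

    ``leaf_c`` (kg C) and ``rate`` may be scalars or arrays over individuals;
    the returned fluxes are patch totals. Returns ``(new_leaf_c, fluxes)``.
    """
    leaf_c = np.asarray(leaf_c, dtype=float)
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0) or np.any(rate > 1):
        raise ValueError("rate must lie in [0, 1]")
    consumed = rate * leaf_c
    new_leaf = leaf_c - consumed
    total_consumed = float(np.sum(consumed))
    assimilated = settings.assimilation_fraction * total_consumed
    respired = settings.respiration_fraction * assimilated
    frass = total_consumed - assimilated
    retained = assimilated - respired
    fluxes = HerbivoryFluxes(
        consumed=total_consumed,
        assimilated=assimilated,
        respired=respired,
        frass_to_litter=frass,
        herbivore_retained=retained,
    )
    if new_leaf.ndim == 0:
        return float(new_leaf), fluxes
    return new_leaf, fluxes
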