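"""Synthetic fixture generators standing in for the field-sampling layer.

Everything here is generated data with documented parameters, emulating the
structure of the field campaign (52 tree species with 8 replicate trait
measurements per species, hydro-climate station forcing, plot-level REF
datasets) — never real observations. Generating parameters are embedded as
``#``-comment headers in the CSVs the generators write.
"""
from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .forcing import ClimateParams, SitePlan, generate_forcing
from .traits import TraitBounds, default_curves, derive_dependent_traits, draw_key_traits

__all__ = [
    "TraitTableParams",
    "RefDatasetParams",
    "make_trait_table",
    "make_forcing_table",
    "make_ref_dataset",
    "make_fixtures",
]


@dataclass(frozen=True)
class TraitTableParams:
    """Generator truth for a local-like or global-like trait table.

    Species-mean SLA values are uniform over the bounds; dependent traits
    follow the named curve set's power laws; replicates scatter lognormally
    around the species means with sd ``replicate_sd`` (log scale).
    """

    n_species: int = 52
    n_replicates: int = 8
    provenance: str = "local"
    replicate_sd: float = 0.08
    bounds: TraitBounds = TraitBounds()


def make_trait_table(params: TraitTableParams | None = None, seed: int = 0) -> pd.DataFrame:
    """Species × replicate trait table (columns of :func:`traits.read_trait_table`)."""
    p = params or TraitTableParams()
    rng = np.random.default_rng(seed)
    curves = default_curves(p.provenance)
    keys = draw_key_traits(p.bounds, p.n_species, rng)
    rows = []
    for s in range(p.n_species):
        sla_s, wsg_s = keys[s]
        base = derive_dependent_traits(sla_s, wsg_s, curves, stochastic=True, rng_seed=rng)
        for _ in range(p.n_replicates):
            noise = np.exp(rng.normal(0.0, p.replicate_sd, size=4))
            rows.append(
                {
                    "species_id": f"sp{s + 1:03d}",
                    "sla_cm2_g": sla_s * noise[0],
                    "wsg": min(wsg_s * np.exp(rng.normal(0.0, p.replicate_sd / 2)), 1.4),
                    "leaf_cn": base.leaf_cn * noise[1],
                    "leaf_cp": base.leaf_cp * noise[2],
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RefDatasetParams:
    """Standardized mediation truth for REF calibration datasets.

    Data follow x → m → y with standardized path coefficients ``a`` (x→m),
    ``b`` (m→y) and ``c`` (the direct x→y path; 0 under full mediation).
    """

    n: int = 200
    a: float = 0.5
    b: float = 0.5
    c: float = 0.0


def make_ref_dataset(params: RefDatasetParams | None = None, seed: int = 0) -> pd.DataFrame:
    """One mediation dataset with unit-variance variables and known paths."""
    p = params or RefDatasetParams()
    rng = np.random.default_rng(seed)
    x = rng.normal(size=p.n)
    m = p.a * x + rng.normal(size=p.n) * np.sqrt(max(1.0 - p.a**2, 1e-12))
    var_y = 1.0 - (p.b**2 + p.c**2 + 2 * p.a * p.b * p.c)
    y = p.b * m + p.c * x + rng.normal(size=p.n) * np.sqrt(max(var_y, 1e-12))
    return pd.DataFrame({"unit_id": np.arange(1, p.n + 1), "mat_c": x, "trait": m, "response": y})


def make_forcing_table(
    elevation: float = 2000.0, years: int = 100, seed: int = 0
) -> pd.DataFrame:
    site = SitePlan(f"fixture_{int(elevation)}m", elevation)
    forcing = generate_forcing(site, years, ClimateParams(), rng_seed=seed)
    return forcing.to_frame()


def _write_with_header(df: pd.DataFrame, path: Path, header_lines: list[str]) -> None:
    buf = io.StringIO()
    for line in header_lines:
        buf.write(f"# {line}\n")
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue())


def make_fixtures(kind: str, outdir, seed: int = 0, **kwargs) -> list[Path]:
    """Write fixture CSVs; returns the created paths.

    ``kind``: ``trait_table`` (writes local-like and global-like tables),
    ``forcing`` (one station series) or ``ref_dataset`` (one mediation CSV).
    Generating parameters are embedded as comment headers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    if kind == "trait_table":
        for i, provenance in enumerate(("local", "global")):
            params = TraitTableParams(provenance=provenance, **kwargs)
            df = make_trait_table(params, seed=seed + i)
            path = outdir / f"trait_table_{provenance}.csv"
            curves = default_curves(provenance)
            header = [
                f"synthetic {provenance}-like trait table (fixture, not field data)",
                f"n_species={params.n_species} n_replicates={params.n_replicates} "
                f"replicate_sd={params.replicate_sd} seed={seed + i}",
            ] + [
                f"true curve {name}: intercept={c.intercept:.6f} slope={c.slope:.4f} "
                f"residual_sd={c.residual_sd}"
                for name, c in curves.items()
            ]
            _write_with_header(df, path, header)
            created.append(path)
    elif kind == "forcing":
        elevation = kwargs.pop("elevation", 2000.0)
        years = kwargs.pop("years", 100)
        df = make_forcing_table(elevation, years, seed)
        path = outdir / f"forcing_{int(elevation)}m.csv"
        _write_with_header(
            df, path, [f"synthetic station forcing (fixture): elevation={elevation} seed={seed}"]
        )
        created.append(path)
    elif kind == "ref_dataset":
        params = RefDatasetParams(**kwargs)
        df = make_ref_dataset(params, seed)
        path = outdir / "ref_dataset.csv"
        _write_with_header(
            df,
            path,
            [
                "synthetic mediation dataset (fixture)",
                f"truth: a={params.a} b={params.b} c={params.c} n={params.n} seed={seed}",
            ],
        )
        created.append(path)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return created
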