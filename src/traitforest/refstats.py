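"""Response–effect framework statistics: CWM, path models, chi-square tests.

Implements, from first principles, the statistical layer that links an
abiotic driver (mean annual temperature), a community trait (CWM of specific
leaf area) and an ecosystem response (aboveground biomass production, or
herbivory): normal-theory maximum-likelihood path models over observed
variables, direct/indirect (mediation) effect decomposition, and the
chi-square difference test between nested models.

Model and conventions
---------------------
For a recursive DAG over p observed variables with uncorrelated errors, the
ML estimates given the sample covariance S are the per-equation least-squares
solutions computed from S. The model-implied covariance is
``Σ = (I − B)⁻¹ Ψ (I − B)⁻ᵀ`` with B the path matrix and Ψ holding the free
exogenous (co)variances plus the diagonal error variances. The fit statistic
is ``χ² = (n − 1) · F_ML`` with
``F_ML = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p`` (the (n − 1) multiplier convention;
S uses the n − 1 divisor throughout). Degrees of freedom are the number of
non-redundant sample moments, p(p+1)/2, minus the number of free parameters.
Variables are z-scored before fitting, so all coefficients are standardized.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "MEDIATION_SATURATED",
    "MEDIATION_PARTIAL",
    "PathModelFit",
    "Chi2DiffResult",
    "cwm",
    "fit_path_model",
    "mediation_effects",
    "chi2_sf",
    "chi2_difference_test",
]

#: The three-variable saturated mediation topology X → M → Y plus X → Y.
MEDIATION_SATURATED = (("x", "m"), ("m", "y"), ("x", "y"))
#: Partial mediation: the direct X → Y path omitted.
MEDIATION_PARTIAL = (("x", "m"), ("m", "y"))


def cwm(weights, traits) -> float:
    """Community-weighted mean: Σ wᵢ tᵢ / Σ wᵢ.

    Weights must be non-negative with a positive sum (species or individual
    abundances); vectors must have equal length.
    """
    w = np.asarray(weights, dtype=float)
    t = np.asarray(traits, dtype=float)
    if w.shape != t.shape:
        raise ValueError("weights and traits must have equal length")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must not all be zero")
    return float((w * t).sum() / total)


@dataclass
class PathModelFit:
    """A fitted recursive path model.

    ``coefficients`` maps each directed edge to its standardized estimate;
    ``standard_errors`` are the per-equation least-squares SEs. ``chi_square``
    is the (n−1)·F_ML discrepancy against the saturated covariance; a
    just-identified (saturated) model has chi_square = 0 and df = 0.
    """

    variables: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    coefficients: dict[tuple[str, str], float]
    standard_errors: dict[tuple[str, str], float]
    error_variances: dict[str, float]
    r_squared: dict[str, float]
    sample_cov: np.ndarray
    implied_cov: np.ndarray
    chi_square: float
    df: int
    n: int
    loglik_deficit: float  # F_ML, the per-observation ML discrepancy

    def coefficient(self, src: str, dst: str) -> float:
        return self.coefficients.get((src, dst), 0.0)


@dataclass(frozen=True)
class Chi2DiffResult:
    """Chi-square difference (likelihood-ratio) test between nested models."""

    delta_chi2: float
    delta_df: int
    p_value: float


def _topological_order(variables: Sequence[str], edges: Sequence[tuple[str, str]]) -> list[str]:
    parents: dict[str, set[str]] = {v: set() for v in variables}
    for src, dst in edges:
        parents[dst].add(src)
    order: list[str] = []
    remaining = set(variables)
    while remaining:
        free = sorted(v for v in remaining if not (parents[v] & remaining))
        if not free:
            raise ValueError("edge set is not a DAG (cycle detected)")
        order.extend(free)
        remaining -= set(free)
    return order


def fit_path_model(
    data: pd.DataFrame | Mapping[str, np.ndarray],
    edges: Sequence[tuple[str, str]] = MEDIATION_SATURATED,
    variables: Sequence[str] | None = None,
    standardize: bool = True,
) -> PathModelFit:
    """Fit a recursive path model by normal-theory maximum likelihood.

    ``data`` holds one column per variable; ``edges`` is any recursive DAG
    over the variable names (errors uncorrelated, exogenous covariances
    free). Returns the standardized fit; raises on singular covariance.
    """
    df = pd.DataFrame(data)
    if variables is None:
        in_edges = {v for e in edges for v in e}
        variables = [c for c in df.columns if c in in_edges] or list(df.columns)
    df = df[list(variables)].dropna()
    n = len(df)
    if n < 10:
        raise ValueError("need at least 10 complete observations")
    X = df.to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant variable: covariance is singular")
        X = (X - X.mean(axis=0)) / sd
    p = X.shape[1]
    S = np.cov(X, rowvar=False, ddof=1)
    sign, logdet_s = np.linalg.slogdet(S)
    if sign <= 0 or not np.isfinite(logdet_s):
        raise ValueError("sample covariance is singular; cannot fit")

    edges = tuple((str(a), str(b)) for a, b in edges)
    for src, dst in edges:
        if src not in variables or dst not in variables:
            raise ValueError(f"edge ({src}, {dst}) references unknown variable")
    _topological_order(variables, edges)  # raises on cycles

    idx = {v: i for i, v in enumerate(variables)}
    parents: dict[str, list[str]] = {v: [] for v in variables}
    for src, dst in edges:
        parents[dst].append(src)
    endogenous = [v for v in variables if parents[v]]
    exogenous = [v for v in variables if not parents[v]]

    B = np.zeros((p, p))
    psi = np.zeros((p, p))
    coefficients: dict[tuple[str, str], float] = {}
    standard_errors: dict[tuple[str, str], float] = {}
    error_variances: dict[str, float] = {}
    r_squared: dict[str, float] = {}

    # free exogenous (co)variance block
    ex_idx = [idx[v] for v in exogenous]
    psi[np.ix_(ex_idx, ex_idx)] = S[np.ix_(ex_idx, ex_idx)]

    for v in endogenous:
        pv = parents[v]
        pi = [idx[u] for u in pv]
        yi = idx[v]
        Spp = S[np.ix_(pi, pi)]
        Spy = S[pi, yi]
        beta = np.linalg.solve(Spp, Spy)
        resid_var = float(S[yi, yi] - beta @ Spy)  # ML error variance (S convention)
        error_variances[v] = resid_var
        r_squared[v] = 1.0 - resid_var / float(S[yi, yi])
        psi[yi, yi] = resid_var
        # df-corrected least-squares standard errors
        sigma2 = resid_var * (n - 1) / max(n - 1 - len(pv), 1)
        cov_beta = sigma2 * np.linalg.inv(Spp) / (n - 1)
        for j, u in enumerate(pv):
            B[yi, idx[u]] = beta[j]
            coefficients[(u, v)] = float(beta[j])
            standard_errors[(u, v)] = float(np.sqrt(cov_beta[j, j]))

    eye = np.eye(p)
    inv_imb = np.linalg.inv(eye - B)
    implied = inv_imb @ psi @ inv_imb.T

    sign_i, logdet_i = np.linalg.slogdet(implied)
    if sign_i <= 0:
        raise ValueError("model-implied covariance is singular")
    f_ml = float(logdet_i + np.trace(S @ np.linalg.inv(implied)) - logdet_s - p)
    f_ml = max(f_ml, 0.0)
    chi_square = (n - 1) * f_ml
    n_free = len(edges) + len(endogenous) + len(exogenous) * (len(exogenous) + 1) // 2
    df_model = p * (p + 1) // 2 - n_free
    if df_model < 0:
        raise ValueError("model has more free parameters than sample moments")
    if df_model == 0:
        chi_square = 0.0  # just-identified: discrepancy is numerical noise

    return PathModelFit(
        variables=tuple(variables),
        edges=edges,
        coefficients=coefficients,
        standard_errors=standard_errors,
        error_variances=error_variances,
        r_squared=r_squared,
        sample_cov=S,
        implied_cov=implied,
        chi_square=float(chi_square),
        df=df_model,
        n=n,
        loglik_deficit=f_ml,
    )


def mediation_effects(
    fit: PathModelFit,
    x: str = "x",
    m: str = "m",
    y: str = "y",
) -> tuple[float, float, float]:
    """Direct, indirect and total effect of ``x`` on ``y`` through ``m``.

    direct = the x→y coefficient (0 if the path is absent); indirect = the
    product (x→m)·(m→y); total = direct + indirect (Wright's path tracing).
    """
    for v in (x, m, y):
        if v not in fit.variables:
            raise ValueError(f"variable {v!r} not in the fitted model")
    direct = fit.coefficient(x, y)
    indirect = fit.coefficient(x, m) * fit.coefficient(m, y)
    return direct, indirect, direct + indirect


def chi2_sf(x: float, df: int) -> float:
    """Upper-tail probability of the chi-square distribution.

    Computed as the regularized upper incomplete gamma Q(df/2, x/2); for
    df = 2 this reduces exactly to exp(−x/2).
    """
    if x < 0:
        raise ValueError("x must be >= 0")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(special.gammaincc(df / 2.0, x / 2.0))


def chi2_difference_test(restricted: PathModelFit, saturated: PathModelFit) -> Chi2DiffResult:
    """Likelihood-ratio comparison of nested path models on the same data.

    The restricted model's edges must be a subset of the more general
    model's; Δχ² = χ²_restricted − χ²_general, Δdf likewise, with the
    p-value from the chi-square upper tail (p = 1 when Δdf = 0).
    """
    if restricted.n != saturated.n or restricted.variables != saturated.variables:
        raise ValueError("models must be fitted to the same data and variables")
    if not set(restricted.edges) <= set(saturated.edges):
        raise ValueError("models are not nested (restricted edges must be a subset)")
    delta_chi2 = restricted.chi_square - saturated.chi_square
    if delta_chi2 < -1e-8:
        raise ValueError("negative chi-square difference: models are not nested as fitted")
    delta_chi2 = max(delta_chi2, 0.0)
    delta_df = restricted.df - saturated.df
    if delta_df < 0:
        raise ValueError("restricted model must have more degrees of freedom")
    p_value = 1.0 if delta_df == 0 else chi2_sf(delta_chi2, delta_df)
    return Chi2DiffResult(delta_chi2=delta_chi2, delta_df=delta_df, p_value=p_value)
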