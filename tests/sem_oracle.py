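"""Independent SEM oracle for the test suite.

A brute-force normal-theory ML fitter: it parameterises every free path
coefficient, error variance and exogenous (co)variance explicitly and
minimises the Wishart discrepancy F_ML = ln|Σ(θ)| + tr(S Σ(θ)⁻¹) − ln|S| − p
numerically with scipy. It shares no code path with the package's
closed-form per-equation fitter, so agreement between the two is a real
cross-check, not a tautology.
"""
import numpy as np
import pandas as pd
from scipy import optimize


def fit_sem_numeric(data: pd.DataFrame, edges, variables=None):
    """Return (coefficients dict, chi_square, df) by numerical ML."""
    if variables is None:
        variables = list(data.columns)
    X = data[variables].to_numpy(float)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    n, p = X.shape
    S = np.cov(X, rowvar=False, ddof=1)
    _, logdet_s = np.linalg.slogdet(S)

    idx = {v: i for i, v in enumerate(variables)}
    edges = [(str(a), str(b)) for a, b in edges]
    endo = sorted({b for _, b in edges}, key=variables.index)
    exo = [v for v in variables if v not in endo]
    exo_pairs = [(i, j) for ii, i in enumerate(exo) for j in exo[ii:]]

    n_par = len(edges) + len(endo) + len(exo_pairs)

    def unpack(theta):
        B = np.zeros((p, p))
        psi = np.zeros((p, p))
        k = 0
        for src, dst in edges:
            B[idx[dst], idx[src]] = theta[k]
            k += 1
        for v in endo:
            psi[idx[v], idx[v]] = np.exp(theta[k])  # log-parameterised variance
            k += 1
        for i, j in exo_pairs:
            if i == j:
                psi[idx[i], idx[i]] = np.exp(theta[k])
            else:
                psi[idx[i], idx[j]] = psi[idx[j], idx[i]] = theta[k]
            k += 1
        return B, psi

    def f_ml(theta):
        B, psi = unpack(theta)
        try:
            inv_imb = np.linalg.inv(np.eye(p) - B)
        except np.linalg.LinAlgError:
            return 1e6
        sigma = inv_imb @ psi @ inv_imb.T
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return 1e6
        return logdet + float(np.trace(S @ np.linalg.inv(sigma))) - logdet_s - p

    theta0 = np.concatenate([np.full(len(edges), 0.1), np.zeros(len(endo) + len(exo_pairs))])
    res = optimize.minimize(f_ml, theta0, method="Nelder-Mead",
                            options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12})
    res = optimize.minimize(f_ml, res.x, method="Nelder-Mead",
                            options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12})
    coeffs = {e: float(v) for e, v in zip(edges, res.x[: len(edges)])}
    chi2 = (n - 1) * max(res.fun, 0.0)
    n_moments = p * (p + 1) // 2
    return coeffs, chi2, n_moments - n_par
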