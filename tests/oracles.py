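"""Independent oracles used by the test suite.

Everything here is coded straight-line from the model definitions,
deliberately bypassing the package's structural/vectorized machinery, so
agreement between the two paths is informative.
"""

import math

import numpy as np
from scipy import optimize, stats


def straight_line_peak(agonist, drug_conc, time_h, p):
    """Independent scalar evaluator of the peak-current prediction.

    ``p`` is a plain dict with keys min0, max0, pec50_0, nh_a, nt and,
    when drug_conc > 0, pic50, nh_d, pa2, ns, ng.
    """
    max_t = max(p["max0"] * (1.0 + p["nt"] * time_h), 0.0)
    if drug_conc > 0:
        ic50 = 10.0 ** (-p["pic50"])
        max_t = max_t / (1.0 + (drug_conc / ic50) ** p["nh_d"])
        pec50 = p["pec50_0"] - p["ng"] * math.log10(
            1.0 + (drug_conc * 10.0 ** p["pa2"]) ** p["ns"]
        )
    else:
        pec50 = p["pec50_0"]
    if agonist == 0:
        return p["min0"]
    ec50 = 10.0 ** (-pec50)
    frac = agonist ** p["nh_a"] / (
        agonist ** p["nh_a"] + ec50 ** p["nh_a"]
    )
    return p["min0"] + (max_t - p["min0"]) * frac


def els_sum(y, pred, variances, eta=None, omega=None):
    """Straight-line penalized extended-least-squares summation."""
    total = sum(
        (yi - pi) ** 2 / vi + math.log(vi)
        for yi, pi, vi in zip(y, pred, variances)
    )
    if eta is not None:
        omega = np.asarray(omega, dtype=float)
        eta = np.asarray(eta, dtype=float)
        total += float(eta @ np.linalg.inv(omega) @ eta)
        total += float(np.linalg.slogdet(omega)[1])
    return total


def linear_gaussian_m2ll(y, mean, sigma2, omega2):
    """Exact -2 log-likelihood (constants dropped) for y = mean + eta + e.

    One additive random intercept shared by all observations with
    variance ``omega2`` and iid residual variance ``sigma2``; the
    n*ln(2*pi) constant is excluded to match the package's ``ofv``
    convention.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    cov = sigma2 * np.eye(n) + omega2 * np.ones((n, n))
    m2ll = -2.0 * stats.multivariate_normal(
        mean=np.full(n, mean), cov=cov
    ).logpdf(y)
    return float(m2ll - n * math.log(2.0 * math.pi))


def gls_standard_errors(X, sigma2, omega2):
    """Closed-form GLS covariance for a linear mixed model fixed effect.

    y = X beta + 1 eta + e with known variances; returns SEs of beta.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    cov = sigma2 * np.eye(n) + omega2 * np.ones((n, n))
    beta_cov = np.linalg.inv(X.T @ np.linalg.solve(cov, X))
    return np.sqrt(np.diag(beta_cov))


def agq_marginal(g_scalar, n_nodes=64, bracket=(-8.0, 8.0)):
    """Adaptive Gauss-Hermite value of the one-eta marginal objective.

    ``g_scalar(eta)`` is the inner objective; returns the quadrature
    analogue of the Laplace contribution (same constant convention: the
    eta-prior normalization is part of g, and no n*ln(2*pi) data
    constant is added), i.e.  -2 ln [ (2*pi)^(-1/2) * Int exp(-g/2) ].
    """
    res = optimize.minimize_scalar(
        g_scalar, bounds=bracket, method="bounded",
        options={"xatol": 1e-12},
    )
    ehat = res.x
    h = 1e-5
    hess_half = 0.5 * (
        g_scalar(ehat + h) + g_scalar(ehat - h) - 2.0 * g_scalar(ehat)
    ) / h**2
    s = 1.0 / math.sqrt(hess_half)
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    g0 = g_scalar(ehat)
    vals = [
        math.exp(-0.5 * (g_scalar(ehat + s * math.sqrt(2.0) * xi) - g0)
                 + xi * xi) * wi
        for xi, wi in zip(x, w)
    ]
    integral = s * math.sqrt(2.0) * sum(vals)
    return float(g0 - 2.0 * math.log(integral) + math.log(2.0 * math.pi))


def agq_marginal_2d(g_scalar2, n_nodes=24, start=(0.0, 0.0)):
    """Tensor-product AGQ for a two-eta marginal objective."""
    res = optimize.minimize(lambda e: g_scalar2(e[0], e[1]),
                            np.array(start), method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12,
                                     "maxiter": 4000})
    ehat = res.x
    h = 1e-4
    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            ei = np.zeros(2); ei[i] = h
            ej = np.zeros(2); ej[j] = h
            H[i, j] = (
                g_scalar2(*(ehat + ei + ej))
                - g_scalar2(*(ehat + ei - ej))
                - g_scalar2(*(ehat - ei + ej))
                + g_scalar2(*(ehat - ei - ej))
            ) / (8.0 * h * h)  # Hessian of g/2
    w_, V = np.linalg.eigh(H)
    S = V @ np.diag(1.0 / np.sqrt(w_))
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    g0 = g_scalar2(*ehat)
    total = 0.0
    for xi, wi in zip(x, w):
        for xj, wj in zip(x, w):
            z = math.sqrt(2.0) * (S @ np.array([xi, xj]))
            total += wi * wj * math.exp(
                -0.5 * (g_scalar2(*(ehat + z)) - g0) + xi * xi + xj * xj
            )
    integral = 2.0 * abs(np.linalg.det(S)) * total
    return float(g0 - 2.0 * math.log(integral)
                 + 2.0 * math.log(2.0 * math.pi))
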