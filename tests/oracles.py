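"""Independent reference implementations used only to check the package.

Each oracle deliberately takes a different computational route from the
implementation it validates (recurrences vs direct log-factorials,
explicit sorts vs step-up vectorization, profiled generalized least
squares vs statsmodels REML, numeric partial-likelihood maximization vs
the packaged Cox fit).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize, minimize_scalar


def hwe_exact_recurrence(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE p-value via the heterozygote-count recurrence.

    Builds the conditional distribution of the heterozygote count given
    allele counts from the ratio of successive probabilities, then sums
    all outcomes no more probable than the observed one.
    """
    n = n_AA + n_Aa + n_aa
    n_rare = min(2 * n_aa + n_Aa, 2 * n_AA + n_Aa)
    if n_rare == 0:
        return 1.0
    mid = n_rare % 2
    hets = list(range(mid, n_rare + 1, 2))
    probs = {mid: 1.0}
    # P(h+2)/P(h) = 4 * n_hom_rare(h) * n_hom_common(h) / ((h+2)(h+1))
    for h in hets[:-1]:
        hom_rare = (n_rare - h) // 2
        hom_common = n - h - hom_rare
        probs[h + 2] = probs[h] * 4.0 * hom_rare * hom_common / ((h + 2.0) * (h + 1.0))
    total = sum(probs.values())
    p_obs = probs[n_Aa] / total
    return min(1.0, sum(v / total for v in probs.values() if v / total <= p_obs * (1 + 1e-12)))


def bh_fdr_sort(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values via the explicit sorted definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        val = m * p[order[rank - 1]] / rank
        running = min(running, val)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def reml_random_intercept(y, X, groups):
    """Profiled-REML fit of a random-intercept model by generalized least
    squares over the variance ratio.

    Returns (beta, sigma2_batch, sigma2_resid).
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    groups = np.asarray(groups)
    n, p = X.shape
    labels = np.unique(groups)
    Z = (groups[:, None] == labels[None, :]).astype(float)

    def neg_reml(log_lam):
        lam = np.exp(log_lam)
        V = np.eye(n) + lam * Z @ Z.T
        Vi = np.linalg.inv(V)
        XtVi = X.T @ Vi
        A = XtVi @ X
        beta = np.linalg.solve(A, XtVi @ y)
        r = y - X @ beta
        quad = r @ Vi @ r
        sigma2 = quad / (n - p)
        _, ld_V = np.linalg.slogdet(V)
        _, ld_A = np.linalg.slogdet(A)
        # restricted log-likelihood up to constants
        ll = -0.5 * (ld_V + ld_A + (n - p) * np.log(sigma2))
        return -ll

    res = minimize_scalar(neg_reml, bounds=(-12.0, 8.0), method="bounded",
                          options={"xatol": 1e-12})
    lam = np.exp(res.x)
    V = np.eye(n) + lam * Z @ Z.T
    Vi = np.linalg.inv(V)
    A = X.T @ Vi @ X
    beta = np.linalg.solve(A, X.T @ Vi @ y)
    r = y - X @ beta
    sigma2 = (r @ Vi @ r) / (n - p)
    return beta, lam * sigma2, sigma2


def cox_breslow_loglik(beta, times, events, X):
    """Breslow partial log-likelihood (allows ties)."""
    beta = np.atleast_1d(beta)
    eta = X @ beta
    ll = 0.0
    for t in np.unique(times[events == 1]):
        d = (times == t) & (events == 1)
        risk = times >= t
        ll += eta[d].sum() - d.sum() * np.log(np.exp(eta[risk]).sum())
    return ll


def cox_breslow_mle(times, events, X):
    """Maximize the Breslow partial likelihood numerically."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(times):
        X = X.T
    p = X.shape[1]
    res = minimize(
        lambda b: -cox_breslow_loglik(b, times, events, X),
        np.zeros(p),
        method="BFGS",
        options={"gtol": 1e-10, "maxiter": 500},
    )
    return res.x


def ols_beta(y, X):
    """Plain normal-equation least squares (exact linear-algebra route)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    return np.linalg.solve(X.T @ X, X.T @ y)


def omitted_variable_bias_pct(y, x_kept, x_omitted, Z):
    """Analytic percentage change of x_kept's coefficient when x_omitted
    is added, from exact least-squares fits with controls Z.

    Returns |100 * (b1 - b2) / b1| where b1 omits and b2 includes the
    extra regressor.
    """
    Z = np.asarray(Z, float)
    X1 = np.column_stack([x_kept, Z])
    X2 = np.column_stack([x_kept, x_omitted, Z])
    b1 = ols_beta(y, X1)[0]
    b2 = ols_beta(y, X2)[0]
    return abs(100.0 * (b1 - b2) / b1)
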