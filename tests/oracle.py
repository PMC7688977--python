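"""Independent centralized Breslow-ties Cox oracle.

Deliberately written as a different algorithm from the package: the partial
log-likelihood, score and Hessian are assembled by brute-force boolean-mask
sums over the risk set at each distinct event time, and the maximum is found
by scipy's quasi-Newton optimizer rather than the package's aggregated
Newton-Raphson. Used only to check the federated estimator.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def _event_times(T, E):
    return np.unique(np.asarray(T)[np.asarray(E) == 1])


def breslow_negloglik(beta, T, E, X):
    T, E, X = np.asarray(T, float), np.asarray(E, int), np.asarray(X, float)
    beta = np.asarray(beta, float)
    eta = X @ beta
    ll = 0.0
    for t in _event_times(T, E):
        events = (T == t) & (E == 1)
        at_risk = T >= t
        d = events.sum()
        ll += eta[events].sum() - d * np.log(np.exp(eta[at_risk]).sum())
    return -ll


def breslow_score(beta, T, E, X):
    T, E, X = np.asarray(T, float), np.asarray(E, int), np.asarray(X, float)
    beta = np.asarray(beta, float)
    w = np.exp(X @ beta)
    U = np.zeros(X.shape[1])
    for t in _event_times(T, E):
        events = (T == t) & (E == 1)
        at_risk = T >= t
        d = events.sum()
        s0 = w[at_risk].sum()
        s1 = (w[at_risk, None] * X[at_risk]).sum(axis=0)
        U += X[events].sum(axis=0) - d * s1 / s0
    return -U


def breslow_hessian(beta, T, E, X):
    T, E, X = np.asarray(T, float), np.asarray(E, int), np.asarray(X, float)
    beta = np.asarray(beta, float)
    w = np.exp(X @ beta)
    p = X.shape[1]
    H = np.zeros((p, p))
    for t in _event_times(T, E):
        events = (T == t) & (E == 1)
        at_risk = T >= t
        d = events.sum()
        Xr, wr = X[at_risk], w[at_risk]
        s0 = wr.sum()
        s1 = (wr[:, None] * Xr).sum(axis=0)
        s2 = (Xr * wr[:, None]).T @ Xr
        ebar = s1 / s0
        H += d * (s2 / s0 - np.outer(ebar, ebar))
    return H


def centralized_breslow_fit(T, E, X, tol=1e-10):
    """Brute-force maximum partial likelihood estimate, SEs and loglik."""
    p = np.asarray(X).shape[1]
    res = optimize.minimize(
        breslow_negloglik,
        np.zeros(p),
        args=(T, E, X),
        jac=breslow_score,
        method="BFGS",
        options={"gtol": tol, "maxiter": 500},
    )
    # polish with explicit Newton steps on the brute-force derivatives
    beta = res.x
    for _ in range(10):
        g = -breslow_score(beta, T, E, X)
        H = breslow_hessian(beta, T, E, X)
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.abs(step).max() < 1e-12:
            break
    H = breslow_hessian(beta, T, E, X)
    cov = np.linalg.inv(H)
    return {
        "beta": beta,
        "se": np.sqrt(np.diag(cov)),
        "cov": cov,
        "loglik": -breslow_negloglik(beta, T, E, X),
        "loglik_null": -breslow_negloglik(np.zeros(p), T, E, X),
    }
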