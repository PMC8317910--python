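"""Reference implementations used only for validation.

These deliberately naive routines enumerate the Cox partial likelihood
risk-set by risk-set and maximize it numerically, independent of the fitting
backend used by :mod:`pehsurv.cox`.  They are practical only for tiny inputs
and exist so tests can compare the production path against a transparent
hand-written likelihood.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

__all__ = ["log_partial_likelihood", "brute_force_cox"]


def log_partial_likelihood(beta, times, events, X) -> float:
    """Explicitly enumerated Cox log partial likelihood (no tie handling).

    ``sum_{i: event} [ x_i'beta - log sum_{j: t_j >= t_i} exp(x_j'beta) ]``.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != times.shape[0]:
        X = X.T
    eta = X @ beta
    ll = 0.0
    for i in np.flatnonzero(events):
        risk = times >= times[i]
        ll += eta[i] - np.log(np.sum(np.exp(eta[risk])))
    return float(ll)


def brute_force_cox(times, events, X, x0=None) -> np.ndarray:
    """Maximize :func:`log_partial_likelihood` by direct numeric optimization."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(times):
        X = X.T
    p = X.shape[1]
    x0 = np.zeros(p) if x0 is None else np.asarray(x0, dtype=float)
    res = optimize.minimize(
        lambda b: -log_partial_likelihood(b, times, events, X),
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000, "maxfev": 20000},
    )
    if not res.success:
        raise RuntimeError(f"brute-force optimization failed: {res.message}")
    return np.atleast_1d(res.x)
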