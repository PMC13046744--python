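"""Minimal weighted Cox partial-likelihood solver (Breslow ties).

Used inside the mediation bootstrap where tens of thousands of small fits are
needed; agreement with lifelines' CoxPHFitter is asserted in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["cox_fit"]


def cox_fit(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    weights: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> np.ndarray:
    """Newton-Raphson MLE of the weighted Cox partial likelihood.

    Breslow tie handling; returns the coefficient vector.
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)

    order = np.argsort(time, kind="stable")
    X = X[order]
    time = time[order]
    event = event[order]
    w = w[order]

    # first index of each tied time, for every row
    first_idx = np.searchsorted(time, time, side="left")
    ev = event > 0
    ev_first = first_idx[ev]
    w_ev = w[ev]
    x_ev = X[ev]

    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        eta -= eta.max()  # guard overflow; cancels in ratios
        r = w * np.exp(eta)
        rx = r[:, None] * X
        rxx = rx[:, :, None] * X[:, None, :]
        # suffix sums over the risk sets
        s0 = np.cumsum(r[::-1])[::-1]
        s1 = np.cumsum(rx[::-1], axis=0)[::-1]
        s2 = np.cumsum(rxx[::-1], axis=0)[::-1]

        s0e = s0[ev_first]
        s1e = s1[ev_first]
        s2e = s2[ev_first]
        mu = s1e / s0e[:, None]
        grad = (w_ev[:, None] * (x_ev - mu)).sum(axis=0)
        v = s2e / s0e[:, None, None] - mu[:, :, None] * mu[:, None, :]
        hess = (w_ev[:, None, None] * v).sum(axis=0)

        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        beta = beta + step
        if np.abs(grad).max() < tol or np.abs(step).max() < 1e-10:
            break
    return beta
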