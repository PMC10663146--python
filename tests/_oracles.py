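"""Independent oracles used only by the test suite.

These deliberately re-derive results by the most transparent route
available — written-out Newton-Raphson on the binomial likelihood, and a
per-subject python loop for person-period bookkeeping — so they share no
code with the implementation they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def newton_logistic(X: np.ndarray, y: np.ndarray, tol: float = 1e-12,
                    maxiter: int = 200) -> np.ndarray:
    """Maximize the Bernoulli log-likelihood by plain Newton-Raphson."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        grad = X.T @ (y - p)
        hess = X.T @ (X * w[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def count_person_periods(cohort, spec) -> int:
    """Brute-force record count: loop over subjects one by one."""
    n_int = cohort.params.n_intervals
    first = spec.first_modelled_interval
    total = 0
    for ev in cohort.subjects["event_interval"]:
        last = n_int if pd.isna(ev) else min(int(ev), n_int)
        total += max(0, last - first + 1)
    return total
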