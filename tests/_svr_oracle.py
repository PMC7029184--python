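"""Brute-force epsilon-SVR oracle: solves the dual QP with a generic solver.

Independent of the package's libsvm-backed path; used to cross-check the
searchlight decoder.  The dual in beta = alpha - alpha* (expanded to the
nonnegative pair (alpha, alpha*)) is

    min  1/2 (a - a*)' K (a - a*) + eps * sum(a + a*) - y' (a - a*)
    s.t. sum(a - a*) = 0,  0 <= a, a* <= C,

solved with SLSQP; the weight vector is w = X' (a - a*).  The bias is
recovered as the exact minimizer of the primal epsilon-insensitive loss in
b given w (midpoint of the minimizing interval), which coincides with
libsvm's KKT-interval midpoint.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def svr_dual_qp(X: np.ndarray, y: np.ndarray, C: float = 1.0, eps: float = 0.1):
    """Return (w, b) of the linear epsilon-SVR via direct QP on the dual."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    K = X @ X.T

    def objective(z):
        beta = z[:n] - z[n:]
        return 0.5 * beta @ K @ beta + eps * z.sum() - y @ beta

    def grad(z):
        beta = z[:n] - z[n:]
        Kb = K @ beta
        return np.concatenate([Kb + eps - y, -Kb + eps + y])

    cons = {
        "type": "eq",
        "fun": lambda z: np.sum(z[:n] - z[n:]),
        "jac": lambda z: np.concatenate([np.ones(n), -np.ones(n)]),
    }
    bounds = [(0.0, C)] * (2 * n)
    z0 = np.zeros(2 * n)
    res = minimize(
        objective,
        z0,
        jac=grad,
        bounds=bounds,
        constraints=[cons],
        method="SLSQP",
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    beta = res.x[:n] - res.x[n:]

    # polish: classify the active set from the SLSQP solution and solve the
    # KKT equalities exactly on the free support vectors
    tol = 1e-6 * C
    at_upper = beta > C - tol
    at_lower = beta < -C + tol
    at_zero = np.abs(beta) < tol
    free = ~(at_upper | at_lower | at_zero)
    beta_polished = np.where(at_upper, C, np.where(at_lower, -C, 0.0))
    if free.any():
        s = np.sign(beta[free])  # +1: below the tube, -1: above
        rhs = y[free] - s * eps - K[np.ix_(free, ~free)] @ beta_polished[~free]
        nf = int(free.sum())
        A = np.zeros((nf + 1, nf + 1))
        A[:nf, :nf] = K[np.ix_(free, free)]
        A[:nf, nf] = 1.0
        A[nf, :nf] = 1.0
        rhs_full = np.concatenate([rhs, [-beta_polished[~free].sum()]])
        sol, *_ = np.linalg.lstsq(A, rhs_full, rcond=None)
        beta_f, b = sol[:nf], float(sol[nf])
        # accept the polish only if it stays feasible
        if np.all(np.abs(beta_f) <= C + tol):
            beta_polished[free] = np.clip(beta_f, -C, C)
            return X.T @ beta_polished, b
    w = X.T @ beta

    # exact 1-D minimization of the primal loss in b (piecewise linear)
    r = y - X @ w
    knots = np.sort(np.concatenate([r - eps, r + eps]))

    def primal_b(b):
        return C * np.maximum(np.abs(r - b) - eps, 0.0).sum()

    vals = np.array([primal_b(b) for b in knots])
    best = vals.min()
    best_knots = knots[vals <= best + 1e-12]
    b = 0.5 * (best_knots.min() + best_knots.max())
    return w, float(b)


def svr_predict_qp(X_train, y_train, X_test, C=1.0, eps=0.1):
    w, b = svr_dual_qp(X_train, y_train, C, eps)
    return np.asarray(X_test, dtype=float) @ w + b


def loro_accuracy_qp(patterns, runs, targets, C=1.0, eps=0.1, cap=None):
    """Leave-one-run-out Fisher-z accuracy with the QP solver in every fold.

    Mirrors the package's fold logic (train-only z-scaling, capped atanh of
    the fold correlation, zero-variance folds scoring 0) but solves the SVR
    independently.
    """
    patterns = np.asarray(patterns, dtype=float)
    runs = np.asarray(runs)
    targets = np.asarray(targets, dtype=float)
    if cap is None:
        cap = float(np.arctanh(1.0 - 1e-15))
    zs = []
    for run in np.unique(runs):
        test = runs == run
        train = ~test
        mu = patterns[train].mean(axis=0)
        sd = patterns[train].std(axis=0)
        sd = np.where(sd == 0, np.inf, sd)
        trz = (patterns[train] - mu) / sd
        tez = (patterns[test] - mu) / sd
        pred = svr_predict_qp(trz, targets[train], tez, C, eps)
        if np.std(pred) == 0 or np.std(targets[test]) == 0:
            zs.append(0.0)
            continue
        r = np.clip(np.corrcoef(pred, targets[test])[0, 1], -1.0, 1.0)
        zs.append(float(np.clip(np.arctanh(r) if abs(r) < 1 else np.sign(r) * np.inf,
                                -cap, cap)))
    return float(np.mean(zs))
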