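"""Independent brute-force solver of the fractional efficiency program.

Works directly in the intensity-vector space: for a fixed lambda the ratio
variables are determined coordinate-wise (alpha_i = sum_j lambda_j xD_ij /
xD_i0 and so on), feasibility is a set of box checks, and the objective is
the weighted fractional ratio.  The optimum is found by a coarse grid sweep
followed by SLSQP polishing from the best grid points — no Charnes-Cooper
transformation and no LP, so it is an independent check of the package's
solver path.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize

BIG = 50.0  # lambda cap for unconstrained-intensity searches


def ratios_for_lambda(lam, frontier, target):
    XD, XI, YG, YB = frontier
    xD0, xI0, yG0, yB0 = target
    lam = np.asarray(lam, dtype=float)
    return (lam @ XD / xD0, lam @ XI / xI0, lam @ YG / yG0, lam @ YB / yB0)


def feasible(lam, frontier, target, gamma="crs", tol=1e-9):
    alpha, gam, beta, theta = ratios_for_lambda(lam, frontier, target)
    if np.any(alpha > 1 + tol) or np.any(theta > 1 + tol):
        return False
    if np.any(gam < 1 - tol) or np.any(beta < 1 - tol):
        return False
    s = float(np.sum(lam))
    if gamma == "crs" and abs(s - 1) > tol:
        return False
    if gamma == "irs" and s > 1 + tol:
        return False
    if gamma == "drs" and s < 1 - tol:
        return False
    return True


def objective(lam, frontier, target, weights):
    alpha, gam, beta, theta = ratios_for_lambda(lam, frontier, target)
    num = weights.omega @ alpha + weights.nu @ theta
    den = weights.sigma @ gam + weights.mu @ beta
    return num / den


def _simplex_grid(n, steps):
    """All lambda on the unit simplex with coordinates multiple of 1/steps."""
    for c in itertools.combinations(range(steps + n - 1), n - 1):
        parts = np.diff((-1,) + c + (steps + n - 1,)) - 1
        yield parts / steps


def _box_grid(n, steps, hi):
    axes = [np.linspace(0, hi, steps + 1)] * n
    return itertools.product(*axes)


def brute_force_delta(frontier, target, weights, gamma="crs",
                      grid_steps=40, polish=True):
    """Brute-force optimum of the fractional program.

    Returns (delta, lam) or (None, None) if no feasible point was found.
    """
    XD = np.atleast_2d(np.asarray(frontier[0], float))
    frontier = tuple(np.atleast_2d(np.asarray(M, float)) for M in frontier)
    target = tuple(np.atleast_1d(np.asarray(v, float)) for v in target)
    n = XD.shape[0]

    if gamma == "crs":
        candidates = _simplex_grid(n, grid_steps)
    else:
        candidates = _box_grid(n, min(grid_steps, 12), 4.0)
    best, best_lam = np.inf, None
    for lam in candidates:
        lam = np.asarray(lam, float)
        if feasible(lam, frontier, target, gamma, tol=1e-7):
            val = objective(lam, frontier, target, weights)
            if val < best:
                best, best_lam = val, lam.copy()
    if best_lam is None and not polish:
        return None, None

    if polish:
        cons = []
        XD_, XI_, YG_, YB_ = frontier
        xD0, xI0, yG0, yB0 = target
        # alpha <= 1, theta <= 1 ; gamma >= 1, beta >= 1  (all linear in lambda)
        cons.append({"type": "ineq", "fun": lambda l: 1 - l @ XD_ / xD0})
        cons.append({"type": "ineq", "fun": lambda l: 1 - l @ YB_ / yB0})
        cons.append({"type": "ineq", "fun": lambda l: l @ XI_ / xI0 - 1})
        cons.append({"type": "ineq", "fun": lambda l: l @ YG_ / yG0 - 1})
        if gamma == "crs":
            cons.append({"type": "eq", "fun": lambda l: np.sum(l) - 1})
        elif gamma == "irs":
            cons.append({"type": "ineq", "fun": lambda l: 1 - np.sum(l)})
        elif gamma == "drs":
            cons.append({"type": "ineq", "fun": lambda l: np.sum(l) - 1})
        starts = [best_lam] if best_lam is not None else []
        starts += [np.full(n, 1.0 / n), *(np.eye(n) * 1.0)]
        for x0 in starts:
            res = minimize(lambda l: objective(l, frontier, target, weights),
                           x0, method="SLSQP",
                           bounds=[(0, BIG)] * n, constraints=cons,
                           options={"maxiter": 300, "ftol": 1e-12})
            if res.success and feasible(res.x, frontier, target, gamma, tol=1e-6):
                val = objective(res.x, frontier, target, weights)
                if val < best:
                    best, best_lam = val, res.x.copy()
    if best_lam is None:
        return None, None
    return float(best), best_lam
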