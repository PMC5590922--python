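"""Linear programs for the slacks-based efficiency model.

The efficiency measure is a linear-fractional program: minimise the ratio of
the weighted mean contraction of desirable inputs / undesirable outputs to
the weighted mean expansion of undesirable inputs / desirable outputs,
subject to the evaluated point being expressible through an intensity vector
``lambda`` over the frontier panel.  The Charnes-Cooper substitution
``t = 1/denominator`` turns it into the LP solved here with HiGHS:

    min   sum_i omega_i a_i + sum_h nu_h d_h
    s.t.  sum_l sigma_l b_l + sum_r mu_r c_r = 1
          XD' zeta = a * xD0,   XI' zeta = b * xI0       (element-wise rhs)
          YG' zeta = c * yG0,   YB' zeta = d * yB0
          sum(zeta) {=, <=, >=} t   or free      (intensity-sum regime)
          0 <= a <= t, b >= t, c >= t, 0 <= d <= t, zeta >= 0, t >= t_min

and the ratio variables are recovered as alpha = a/t, gamma = b/t,
beta = c/t, theta = d/t, lambda = zeta/t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .factors import PreferenceWeights

GAMMA_KINDS = ("crs", "irs", "drs", "free")

_STATUS = {0: "optimal", 1: "numerical", 2: "infeasible", 3: "unbounded", 4: "numerical"}


@dataclass(frozen=True)
class GammaSet:
    """Intensity-sum regime of the production possibility set.

    ``crs`` imposes ``sum(lambda) = 1`` (the convexity constraint), ``irs``
    ``sum(lambda) < 1`` and ``drs`` ``sum(lambda) > 1`` (implemented as
    closed constraints offset by ``eps``); ``free`` leaves the sum
    unconstrained and is used for returns-to-scale diagnosis.
    """

    kind: str = "crs"
    eps: float = 1e-9

    def __post_init__(self):
        if self.kind not in GAMMA_KINDS:
            raise ValueError(f"gamma kind must be one of {GAMMA_KINDS}, got {self.kind!r}")

    @classmethod
    def coerce(cls, value) -> "GammaSet":
        if isinstance(value, GammaSet):
            return value
        return cls(kind=str(value).lower())


@dataclass
class RatioLpResult:
    status: str
    objective: float | None = None
    alpha: np.ndarray | None = None   # DI contraction ratios, in [0, 1]
    gamma_: np.ndarray | None = None  # UI expansion ratios, >= 1
    beta: np.ndarray | None = None    # DO expansion ratios, >= 1
    theta: np.ndarray | None = None   # UO contraction ratios, in [0, 1]
    lam: np.ndarray | None = None     # intensity vector over the frontier panel
    t: float | None = None            # Charnes-Cooper scale variable


def solve_ratio_lp(
    frontier: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    target: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    weights: PreferenceWeights,
    gamma: GammaSet | str = "crs",
    t_min: float = 1e-6,
    contraction_upper: float = 1.0,
    expansion_lower: float = 1.0,
) -> RatioLpResult:
    """Solve the efficiency LP of one target against a frontier panel.

    ``frontier`` holds the (n, m)/(n, q)/(n, s)/(n, k) data matrices of the
    reference panel; ``target`` the evaluated DMU's vectors, which need not
    belong to the panel (mixed-period evaluation).  ``contraction_upper`` and
    ``expansion_lower`` relax the model's strict box bounds ``a, d <= t`` and
    ``b, c >= t`` for cross-period solves that would otherwise be infeasible.
    """
    gamma = GammaSet.coerce(gamma)
    XD, XI, YG, YB = (np.atleast_2d(np.asarray(M, dtype=float)) for M in frontier)
    xD0, xI0, yG0, yB0 = (np.atleast_1d(np.asarray(v, dtype=float)) for v in target)
    n = XD.shape[0]
    m, q, s, k = len(xD0), len(xI0), len(yG0), len(yB0)

    # variable layout: a(m) | b(q) | c(s) | d(k) | zeta(n) | t
    nv = m + q + s + k + n + 1
    i_a, i_b, i_c, i_d = 0, m, m + q, m + q + s
    i_z, i_t = m + q + s + k, nv - 1

    cobj = np.zeros(nv)
    cobj[i_a:i_a + m] = weights.omega
    cobj[i_d:i_d + k] = weights.nu

    Aeq, beq, Aub, bub = [], [], [], []

    row = np.zeros(nv)
    row[i_b:i_b + q] = weights.sigma
    row[i_c:i_c + s] = weights.mu
    Aeq.append(row); beq.append(1.0)

    for mat, vec, off in ((XD, xD0, i_a), (XI, xI0, i_b), (YG, yG0, i_c), (YB, yB0, i_d)):
        for i in range(mat.shape[1]):
            row = np.zeros(nv)
            row[i_z:i_z + n] = mat[:, i]
            row[off + i] = -vec[i]
            Aeq.append(row); beq.append(0.0)

    # box bounds coupled to t
    for i in range(m):
        row = np.zeros(nv); row[i_a + i] = 1.0; row[i_t] = -contraction_upper
        Aub.append(row); bub.append(0.0)
    for h in range(k):
        row = np.zeros(nv); row[i_d + h] = 1.0; row[i_t] = -contraction_upper
        Aub.append(row); bub.append(0.0)
    for l in range(q):
        row = np.zeros(nv); row[i_b + l] = -1.0; row[i_t] = expansion_lower
        Aub.append(row); bub.append(0.0)
    for r in range(s):
        row = np.zeros(nv); row[i_c + r] = -1.0; row[i_t] = expansion_lower
        Aub.append(row); bub.append(0.0)

    if gamma.kind == "crs":
        row = np.zeros(nv); row[i_z:i_z + n] = 1.0; row[i_t] = -1.0
        Aeq.append(row); beq.append(0.0)
    elif gamma.kind == "irs":
        row = np.zeros(nv); row[i_z:i_z + n] = 1.0; row[i_t] = -(1.0 - gamma.eps)
        Aub.append(row); bub.append(0.0)
    elif gamma.kind == "drs":
        row = np.zeros(nv); row[i_z:i_z + n] = -1.0; row[i_t] = 1.0 + gamma.eps
        Aub.append(row); bub.append(0.0)

    bounds = [(0.0, None)] * nv
    bounds[i_t] = (t_min, None)

    res = linprog(
        cobj,
        A_ub=np.array(Aub) if Aub else None,
        b_ub=np.array(bub) if bub else None,
        A_eq=np.array(Aeq),
        b_eq=np.array(beq),
        bounds=bounds,
        method="highs",
    )
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return RatioLpResult(status=status)
    t = float(res.x[i_t])
    return RatioLpResult(
        status="optimal",
        objective=float(res.fun),
        alpha=res.x[i_a:i_a + m] / t,
        gamma_=res.x[i_b:i_b + q] / t,
        beta=res.x[i_c:i_c + s] / t,
        theta=res.x[i_d:i_d + k] / t,
        lam=res.x[i_z:i_z + n] / t,
        t=t,
    )


def sum_lambda_range(
    frontier: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    target: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    weights: PreferenceWeights,
    delta_star: float,
    lam_cap: float = 1e6,
) -> tuple[float, float]:
    """Range of ``sum(lambda)`` over alternative optima at a fixed optimum.

    With the optimal ratio ``delta_star`` known, the fractional objective
    becomes the linear cut ``num - delta_star * den = 0``, so minimising and
    maximising ``sum(lambda)`` over the optimal face are two plain LPs in the
    original variables (lambda, alpha, gamma, beta, theta) with no intensity-
    sum constraint.  Used for returns-to-scale classification.
    """
    XD, XI, YG, YB = (np.atleast_2d(np.asarray(M, dtype=float)) for M in frontier)
    xD0, xI0, yG0, yB0 = (np.atleast_1d(np.asarray(v, dtype=float)) for v in target)
    n = XD.shape[0]
    m, q, s, k = len(xD0), len(xI0), len(yG0), len(yB0)
    nv = n + m + q + s + k
    i_l, i_a, i_b, i_c, i_d = 0, n, n + m, n + m + q, n + m + q + s

    Aeq, beq = [], []
    for mat, vec, off in ((XD, xD0, i_a), (XI, xI0, i_b), (YG, yG0, i_c), (YB, yB0, i_d)):
        for i in range(mat.shape[1]):
            row = np.zeros(nv)
            row[i_l:i_l + n] = mat[:, i]
            row[off + i] = -vec[i]
            Aeq.append(row); beq.append(0.0)
    row = np.zeros(nv)
    row[i_a:i_a + m] = weights.omega
    row[i_d:i_d + k] = weights.nu
    row[i_b:i_b + q] = -delta_star * weights.sigma
    row[i_c:i_c + s] = -delta_star * weights.mu
    Aeq.append(row); beq.append(0.0)

    bounds = ([(0.0, lam_cap)] * n + [(0.0, 1.0)] * m + [(1.0, None)] * q
              + [(1.0, None)] * s + [(0.0, 1.0)] * k)
    obj = np.zeros(nv)
    obj[i_l:i_l + n] = 1.0
    lo = linprog(obj, A_eq=np.array(Aeq), b_eq=np.array(beq), bounds=bounds, method="highs")
    hi = linprog(-obj, A_eq=np.array(Aeq), b_eq=np.array(beq), bounds=bounds, method="highs")
    if lo.status != 0 or hi.status != 0:
        raise RuntimeError(
            f"auxiliary intensity-sum LP failed (status {lo.status}/{hi.status})"
        )
    return float(lo.fun), float(-hi.fun)
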