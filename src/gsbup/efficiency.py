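"""Slacks-based efficiency scoring with undesirable factors and preferences.

The model scores each DMU by the minimal value of

    delta = (sum_i omega_i alpha_i + sum_h nu_h theta_h)
            / (sum_l sigma_l gamma_l + sum_r mu_r beta_r)

where ``alpha`` (desirable-input contraction) and ``theta``
(undesirable-output contraction) lie in [0, 1] while ``beta``
(desirable-output expansion) and ``gamma`` (undesirable-input expansion) are
at least 1, and the scaled point must be reachable as an intensity-weighted
combination of the observed panel.  ``delta = 1`` exactly when no feasible
improvement exists in any factor; the factor-wise slacks follow from the
ratios, e.g. the desirable-input excess is ``(1 - alpha) * xD0``.

The :class:`GsbupEfficiency` estimator freezes a frontier on ``fit`` and can
score arbitrary records against it with ``transform`` — the building block
the Malmquist index uses for its mixed-period evaluations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .factors import FactorSpec, PreferenceWeights, resolve_weights
from .lp import GammaSet, RatioLpResult, solve_ratio_lp, sum_lambda_range
from .panel import DmuRecord, Panel

log = logging.getLogger(__name__)

DEFAULT_TOL = 1e-6


class SolverError(RuntimeError):
    pass


@dataclass
class GsbupSolution:
    """Optimal solution of one efficiency evaluation.

    ``delta`` is the optimal ratio (equal to the LP objective); slacks are
    recovered from the ratio variables and the target's own vectors.
    """

    dmu_id: str
    period: object
    delta: float | None
    alpha: np.ndarray | None
    beta: np.ndarray | None
    gamma_: np.ndarray | None
    theta: np.ndarray | None
    lam: np.ndarray | None
    sD: np.ndarray | None          # desirable-input excess
    sI: np.ndarray | None          # undesirable-input shortfall
    sG: np.ndarray | None          # desirable-output shortfall
    sB: np.ndarray | None          # undesirable-output excess
    lp_t: float | None
    status: str
    gamma_kind: str = "crs"
    flags: set = field(default_factory=set)

    @property
    def slacks(self) -> np.ndarray:
        return np.concatenate([self.sD, self.sI, self.sG, self.sB])

    def objective_from_ratios(self, weights: PreferenceWeights) -> float:
        """Re-evaluate the fractional objective from the ratio variables."""
        num = float(weights.omega @ self.alpha + weights.nu @ self.theta)
        den = float(weights.sigma @ self.gamma_ + weights.mu @ self.beta)
        return num / den


def _solution_from_lp(
    res: RatioLpResult, target: DmuRecord, gamma_kind: str, flags: set | None = None
) -> GsbupSolution:
    if res.status != "optimal":
        return GsbupSolution(
            dmu_id=target.dmu_id, period=target.period, delta=None,
            alpha=None, beta=None, gamma_=None, theta=None, lam=None,
            sD=None, sI=None, sG=None, sB=None, lp_t=None,
            status=res.status, gamma_kind=gamma_kind, flags=flags or set(),
        )
    return GsbupSolution(
        dmu_id=target.dmu_id,
        period=target.period,
        delta=res.objective,
        alpha=res.alpha,
        beta=res.beta,
        gamma_=res.gamma_,
        theta=res.theta,
        lam=res.lam,
        sD=(1.0 - res.alpha) * target.xD,
        sI=(res.gamma_ - 1.0) * target.xI,
        sG=(res.beta - 1.0) * target.yG,
        sB=(1.0 - res.theta) * target.yB,
        lp_t=res.t,
        status="optimal",
        gamma_kind=gamma_kind,
        flags=flags or set(),
    )


def solve_gsbup(
    target: str,
    panel: Panel,
    weights: PreferenceWeights | None = None,
    gamma: GammaSet | str = "crs",
    period=None,
    t_min: float = 1e-6,
) -> GsbupSolution:
    """Score one DMU of ``panel`` against all DMUs of the same period."""
    gamma = GammaSet.coerce(gamma)
    if weights is None:
        weights = resolve_weights(panel.spec)
    weights.validate()
    XD, XI, YG, YB, _ = panel.matrices(period)
    rec = panel.record(target, period)
    res = solve_ratio_lp((XD, XI, YG, YB), (rec.xD, rec.xI, rec.yG, rec.yB),
                         weights, gamma, t_min=t_min)
    sol = _solution_from_lp(res, rec, gamma.kind)
    log.debug("solve dmu=%s period=%s gamma=%s status=%s delta=%s",
              target, rec.period, gamma.kind, sol.status, sol.delta)
    return sol


def is_efficient(sol: GsbupSolution, tol: float = DEFAULT_TOL) -> bool:
    """True iff all ratio variables are within ``tol`` of one.

    Equivalent (up to factor units) to all slack vectors vanishing: the model
    is efficient exactly when no contraction/expansion is possible.
    """
    if sol.status != "optimal":
        raise SolverError(f"solution for {sol.dmu_id!r} is {sol.status}, not optimal")
    dev = max(
        float(np.max(np.abs(1.0 - sol.alpha), initial=0.0)),
        float(np.max(np.abs(sol.gamma_ - 1.0), initial=0.0)),
        float(np.max(np.abs(sol.beta - 1.0), initial=0.0)),
        float(np.max(np.abs(1.0 - sol.theta), initial=0.0)),
    )
    return dev <= tol


def project(
    sol: GsbupSolution,
    target: DmuRecord,
    panel: Panel | None = None,
    tol: float = 1e-5,
) -> DmuRecord:
    """Frontier projection of ``target`` implied by an optimal solution.

    Returns ``(alpha*xD, gamma*xI, beta*yG, theta*yB)``.  When ``panel`` is
    given, the equivalent intensity-weighted form ``sum_j lambda_j * data_j``
    is also computed and the two must agree to relative ``tol``.
    """
    if sol.status != "optimal":
        raise SolverError(f"solution for {sol.dmu_id!r} is {sol.status}, not optimal")
    proj = DmuRecord(
        dmu_id=f"{target.dmu_id}_proj",
        period=target.period,
        xD=sol.alpha * target.xD,
        xI=sol.gamma_ * target.xI,
        yG=sol.beta * target.yG,
        yB=sol.theta * target.yB,
    )
    if panel is not None:
        XD, XI, YG, YB, _ = panel.matrices(target.period if not panel.is_single_period() else None)
        lam_form = np.concatenate([sol.lam @ XD, sol.lam @ XI, sol.lam @ YG, sol.lam @ YB])
        ratio_form = proj.stacked()
        scale = np.maximum(np.abs(ratio_form), 1.0)
        err = float(np.max(np.abs(lam_form - ratio_form) / scale))
        if err > tol:
            raise SolverError(
                f"projection forms disagree for {target.dmu_id!r}: max rel err {err:.3g}"
            )
    return proj


@dataclass
class RtsLabel:
    """Returns-to-scale diagnosis of one DMU.

    ``sum_lambda_range`` is the (min, max) of the intensity sum over all
    alternative optima of the unconstrained-intensity solve; a range touching
    1 is labelled CRS, entirely below 1 IRS, entirely above 1 DRS.
    """

    label: str
    sum_lambda_range: tuple[float, float]
    delta_free: float


def classify_rts(
    target: str,
    panel: Panel,
    weights: PreferenceWeights | None = None,
    period=None,
    tol: float = DEFAULT_TOL,
) -> RtsLabel:
    """Classify returns to scale via the intensity-sum range at the optimum."""
    if weights is None:
        weights = resolve_weights(panel.spec)
    XD, XI, YG, YB, _ = panel.matrices(period)
    rec = panel.record(target, period)
    frontier = (XD, XI, YG, YB)
    tvecs = (rec.xD, rec.xI, rec.yG, rec.yB)
    res = solve_ratio_lp(frontier, tvecs, weights, GammaSet("free"))
    if res.status != "optimal":
        raise SolverError(f"free-intensity solve for {target!r} is {res.status}")
    lo, hi = sum_lambda_range(frontier, tvecs, weights, res.objective)
    if lo <= 1.0 + tol and hi >= 1.0 - tol:
        label = "CRS"
    elif hi < 1.0:
        label = "IRS"
    else:
        label = "DRS"
    return RtsLabel(label=label, sum_lambda_range=(lo, hi), delta_free=res.objective)


class GsbupEfficiency(BaseEstimator):
    """Slacks-based efficiency scorer with undesirable factors.

    Parameters
    ----------
    gamma : {"crs", "irs", "drs", "free"} or GammaSet, default "crs"
        Intensity-sum regime; ``crs`` is the convexity constraint
        ``sum(lambda) = 1``.
    weights : PreferenceWeights, optional
        Preference weights; defaults to equal weights within each
        normalisation group, resolved from the panel's factor spec.
    tol : float, default 1e-6
        Efficiency tolerance on the ratio variables.
    t_min : float, default 1e-6
        Lower bound standing in for the strict positivity of the
        Charnes-Cooper scale variable.

    Attributes
    ----------
    solutions_ : dict mapping dmu_id -> GsbupSolution
    scores_ : pandas.Series of optimal delta per DMU
    efficient_ : pandas.Series of bool
    spec_ : list of FactorSpec of the fitted panel
    """

    def __init__(self, gamma="crs", weights=None, tol=DEFAULT_TOL, t_min=1e-6):
        self.gamma = gamma
        self.weights = weights
        self.tol = tol
        self.t_min = t_min

    def fit(self, panel: Panel, period=None):
        """Freeze a frontier from one period of ``panel`` and score its DMUs."""
        gamma = GammaSet.coerce(self.gamma)
        if period is None and not panel.is_single_period():
            raise ValueError("multi-period panel: pass period= to fit")
        weights = self.weights if self.weights is not None else resolve_weights(panel.spec)
        weights.validate()
        XD, XI, YG, YB, ids = panel.matrices(period)
        self.spec_ = list(panel.spec)
        self.weights_ = weights
        self.gamma_set_ = gamma
        self.frontier_ = (XD, XI, YG, YB)
        self.dmu_ids_ = ids
        self.period_ = period if period is not None else panel.periods[0]
        self._panel = panel.subset(self.period_) if not panel.is_single_period() else panel

        self.solutions_ = {}
        for rec in self._panel.records():
            res = solve_ratio_lp(self.frontier_, (rec.xD, rec.xI, rec.yG, rec.yB),
                                 weights, gamma, t_min=self.t_min)
            self.solutions_[rec.dmu_id] = _solution_from_lp(res, rec, gamma.kind)
        self.scores_ = pd.Series(
            {d: s.delta for d, s in self.solutions_.items()}, name="delta"
        )
        self.efficient_ = pd.Series(
            {d: s.status == "optimal" and is_efficient(s, self.tol)
             for d, s in self.solutions_.items()}, name="efficient"
        )
        return self

    def transform(self, X, relax_on_infeasible: bool = True) -> np.ndarray:
        """Score records against the fitted frontier; returns deltas.

        ``X`` may be a Panel, a sequence of DmuRecord, or a single DmuRecord.
        Records need not belong to the fitted period: this is the
        mixed-period evaluation, and infeasible strict box bounds are
        retried with relaxed boxes when ``relax_on_infeasible`` (the returned
        solutions carry a ``mixed_period_relaxed`` flag).
        """
        sols = self.cross_solutions(X, relax_on_infeasible)
        return np.array([s.delta if s.delta is not None else np.nan for s in sols])

    def cross_solutions(self, X, relax_on_infeasible: bool = True) -> list[GsbupSolution]:
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "frontier_")
        if isinstance(X, DmuRecord):
            records = [X]
        elif isinstance(X, Panel):
            records = list(X.records())
        else:
            records = list(X)
        out = []
        for rec in records:
            tvecs = (rec.xD, rec.xI, rec.yG, rec.yB)
            res = solve_ratio_lp(self.frontier_, tvecs, self.weights_,
                                 self.gamma_set_, t_min=self.t_min)
            flags = set()
            if res.status == "infeasible" and relax_on_infeasible:
                res = solve_ratio_lp(self.frontier_, tvecs, self.weights_,
                                     self.gamma_set_, t_min=self.t_min,
                                     contraction_upper=10.0, expansion_lower=0.1)
                if res.status == "optimal":
                    flags.add("mixed_period_relaxed")
            out.append(_solution_from_lp(res, rec, self.gamma_set_.kind, flags))
        return out

    def fit_transform(self, panel: Panel, period=None) -> np.ndarray:
        self.fit(panel, period)
        return self.scores_.to_numpy()

    def rts_(self) -> pd.Series:
        """Returns-to-scale label per fitted DMU (computed on demand)."""
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "frontier_")
        return pd.Series(
            {d: classify_rts(d, self._panel, self.weights_, tol=self.tol).label
             for d in self.dmu_ids_}, name="rts"
        )


def efficiency_table(
    panel: Panel,
    weights: PreferenceWeights | None = None,
    gamma: GammaSet | str = "crs",
    periods: Sequence | None = None,
    rts: bool = False,
    tol: float = DEFAULT_TOL,
) -> pd.DataFrame:
    """Score every DMU in every requested period; never aborts the batch.

    Returns one row per (dmu_id, period) with the optimal delta, efficiency
    flag, solver status and one column per recovered slack.  Per-DMU solver
    failures are recorded in the ``status`` column.
    """
    periods = list(periods) if periods is not None else panel.periods
    slack_names = (
        [f"s_{n}_excess" for n in panel.factor_names("DI")]
        + [f"s_{n}_shortfall" for n in panel.factor_names("UI")]
        + [f"s_{n}_shortfall" for n in panel.factor_names("DO")]
        + [f"s_{n}_excess" for n in panel.factor_names("UO")]
    )
    rows = []
    for period in periods:
        est = GsbupEfficiency(gamma=gamma, weights=weights, tol=tol)
        try:
            est.fit(panel, period)
        except Exception as exc:  # degenerate period: record and continue
            log.warning("period %r failed: %s", period, exc)
            continue
        for dmu, sol in est.solutions_.items():
            row = {"dmu_id": dmu, "period": period, "delta": sol.delta,
                   "efficient": (sol.status == "optimal" and is_efficient(sol, tol)),
                   "status": sol.status}
            if sol.status == "optimal":
                row.update(dict(zip(slack_names, sol.slacks)))
            if rts:
                try:
                    row["rts"] = classify_rts(dmu, panel, est.weights_, period, tol).label
                except SolverError as exc:
                    row["rts"] = "error"
                    log.warning("rts failed for %s/%r: %s", dmu, period, exc)
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Per-period mean score, efficient count and above-mean count."""
    out = []
    for period, grp in table.groupby("period"):
        ok = grp[grp["status"] == "optimal"]
        mean = ok["delta"].mean()
        out.append({
            "period": period,
            "mean_delta": mean,
            "n_efficient": int(ok["efficient"].sum()),
            "n_above_mean": int((ok["delta"] > mean).sum()),
            "n_dmus": len(grp),
        })
    return pd.DataFrame(out)
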