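"""Malmquist productivity index built on the slacks-based efficiency model.

For a DMU observed in periods t and t+1 the index composes four efficiency
evaluations: each period's data against each period's frontier.  Writing
``d[f, p]`` for the score of period-p data against the period-f frontier,

    M   = sqrt( d[t,t]/d[t,t+1] * d[t+1,t]/d[t+1,t+1] )
    TEC = d[t,t] / d[t+1,t+1]
    FS  = sqrt( d[t+1,t+1]/d[t,t+1] * d[t+1,t]/d[t,t] )

so that M = TEC * FS identically.  Note the orientation of this particular
index: scores are contraction ratios, so M < 1 signals productivity
improvement and FS < 1 a frontier that has progressed — the inverse of the
convention used with output-distance functions.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .efficiency import GsbupEfficiency
from .factors import PreferenceWeights
from .lp import GammaSet
from .panel import DmuRecord, Panel

log = logging.getLogger(__name__)


@dataclass
class MalmquistResult:
    dmu_id: str
    period_pair: tuple
    d_tt: float | None      # period-t data on period-t frontier
    d_t_t1: float | None    # period-(t+1) data on period-t frontier
    d_t1_t: float | None    # period-t data on period-(t+1) frontier
    d_t1_t1: float | None   # period-(t+1) data on period-(t+1) frontier
    M0: float | None
    TEC0: float | None
    FS0: float | None
    flags: set = field(default_factory=set)

    def interpretation(self) -> str:
        if self.M0 is None:
            return "infeasible"
        if abs(self.M0 - 1.0) < 1e-9:
            return "unchanged"
        return "improvement" if self.M0 < 1.0 else "decline"


def cross_period_delta(
    target: DmuRecord,
    frontier_panel: Panel,
    weights: PreferenceWeights | None = None,
    gamma: GammaSet | str = "crs",
) -> tuple[float | None, str, set]:
    """Score a record against a (possibly foreign-period) frontier panel.

    Returns ``(delta, status, flags)``.  The model's strict box bounds force
    contraction ratios <= 1 and expansion ratios >= 1 even against a foreign
    frontier, which can be infeasible (e.g. the target out-produces the whole
    frontier); such solves are retried with relaxed boxes and flagged
    ``mixed_period_relaxed``.
    """
    est = GsbupEfficiency(gamma=gamma, weights=weights)
    est.fit(frontier_panel)
    sol = est.cross_solutions(target)[0]
    return sol.delta, sol.status, sol.flags


def malmquist(
    dmu_id: str,
    panel_t: Panel,
    panel_t1: Panel,
    weights: PreferenceWeights | None = None,
    gamma: GammaSet | str = "crs",
) -> MalmquistResult:
    """Productivity change of one DMU between two single-period panels."""
    est_t = GsbupEfficiency(gamma=gamma, weights=weights).fit(panel_t)
    est_t1 = GsbupEfficiency(gamma=gamma, weights=weights).fit(panel_t1)
    return _malmquist_from_fitted(dmu_id, est_t, est_t1,
                                  panel_t.periods[0], panel_t1.periods[0],
                                  panel_t, panel_t1)


def _malmquist_from_fitted(
    dmu_id, est_t, est_t1, p_t, p_t1, panel_t, panel_t1
) -> MalmquistResult:
    rec_t = panel_t.record(dmu_id)
    rec_t1 = panel_t1.record(dmu_id)
    flags: set = set()

    d_tt = est_t.solutions_[dmu_id].delta
    d_t1_t1 = est_t1.solutions_[dmu_id].delta
    sol_cross_t = est_t.cross_solutions(rec_t1)[0]    # t frontier, t+1 data
    sol_cross_t1 = est_t1.cross_solutions(rec_t)[0]   # t+1 frontier, t data
    d_t_t1 = sol_cross_t.delta
    d_t1_t = sol_cross_t1.delta
    flags |= sol_cross_t.flags | sol_cross_t1.flags

    deltas = (d_tt, d_t_t1, d_t1_t, d_t1_t1)
    if any(d is None or not math.isfinite(d) or d <= 0 for d in deltas):
        flags.add("infeasible")
        return MalmquistResult(dmu_id, (p_t, p_t1), d_tt, d_t_t1, d_t1_t, d_t1_t1,
                               None, None, None, flags)
    M0 = math.sqrt((d_tt / d_t_t1) * (d_t1_t / d_t1_t1))
    TEC0 = d_tt / d_t1_t1
    FS0 = math.sqrt((d_t1_t1 / d_t_t1) * (d_t1_t / d_tt))
    return MalmquistResult(dmu_id, (p_t, p_t1), d_tt, d_t_t1, d_t1_t, d_t1_t1,
                           M0, TEC0, FS0, flags)


def _as_period_panels(panels) -> dict:
    if isinstance(panels, Panel):
        return {p: panels.subset(p) for p in panels.periods}
    return dict(panels)


def malmquist_table(
    panels: Mapping | Panel,
    weights: PreferenceWeights | None = None,
    gamma: GammaSet | str = "crs",
) -> pd.DataFrame:
    """Consecutive-pair Malmquist results for every DMU across a panel series.

    ``panels`` is either a multi-period Panel or a mapping period -> Panel.
    DMUs absent from one period of a pair are excluded from that pair with a
    warning.  Use :func:`malmquist_averages` for the multi-period summary.
    """
    by_period = _as_period_panels(panels)
    periods = sorted(by_period)
    if len(periods) < 2:
        raise ValueError("need at least two periods")
    fitted = {p: GsbupEfficiency(gamma=gamma, weights=weights).fit(by_period[p])
              for p in periods}
    rows = []
    for p_t, p_t1 in zip(periods[:-1], periods[1:]):
        ids_t = set(by_period[p_t].dmu_ids())
        ids_t1 = set(by_period[p_t1].dmu_ids())
        skipped = sorted((ids_t | ids_t1) - (ids_t & ids_t1))
        if skipped:
            warnings.warn(
                f"DMUs {skipped} missing in one of periods ({p_t!r}, {p_t1!r}); "
                "excluded from that pair", stacklevel=2)
        for dmu in sorted(ids_t & ids_t1):
            r = _malmquist_from_fitted(dmu, fitted[p_t], fitted[p_t1],
                                       p_t, p_t1, by_period[p_t], by_period[p_t1])
            rows.append({
                "dmu_id": dmu, "t": p_t, "t1": p_t1,
                "d_tt": r.d_tt, "d_t_t1": r.d_t_t1,
                "d_t1_t": r.d_t1_t, "d_t1_t1": r.d_t1_t1,
                "M0": r.M0, "TEC0": r.TEC0, "FS0": r.FS0,
                "flags": ",".join(sorted(r.flags)),
            })
    return pd.DataFrame(rows)


def malmquist_averages(table: pd.DataFrame) -> pd.DataFrame:
    """Multi-period per-DMU averages of M, TEC and FS.

    Malmquist indices compose multiplicatively across consecutive pairs, so
    the headline average is the geometric mean; the arithmetic mean is
    reported alongside for comparison.
    """
    def gmean(x):
        x = x.dropna()
        return float(np.exp(np.mean(np.log(x)))) if len(x) else np.nan

    out = table.groupby("dmu_id").agg(
        n_pairs=("M0", "count"),
        M0_gmean=("M0", gmean), TEC0_gmean=("TEC0", gmean), FS0_gmean=("FS0", gmean),
        M0_amean=("M0", "mean"), TEC0_amean=("TEC0", "mean"), FS0_amean=("FS0", "mean"),
    ).reset_index()
    return out


class MalmquistIndex(BaseEstimator):
    """Estimator wrapper: fit on a multi-period panel, expose pair results.

    Attributes
    ----------
    results_ : DataFrame of consecutive-pair indices (see malmquist_table)
    averages_ : DataFrame of per-DMU geometric/arithmetic means
    """

    def __init__(self, gamma="crs", weights=None):
        self.gamma = gamma
        self.weights = weights

    def fit(self, panels, y=None):
        self.results_ = malmquist_table(panels, weights=self.weights, gamma=self.gamma)
        self.averages_ = malmquist_averages(self.results_)
        return self

    def transform(self, panels=None) -> pd.DataFrame:
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "results_")
        return self.results_
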