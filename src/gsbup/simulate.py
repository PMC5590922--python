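"""Seeded synthetic-data generators with known ground truth.

The frontier generator plants DMUs on a common supporting hyperplane of the
convex (intensity-sum = 1) production possibility set, so they are provably
efficient, and degrades copies of them by role-consistent multipliers to
plant known inefficiency.  Because the efficiency measure is invariant to
rescaling a factor column across all DMUs, panels are generated at unit
scale and then scaled column-wise to realistic magnitudes — by default the
mean factor levels of the Hong Kong hospital system in 2013 (about 2750
full-time staff, 1030 beds, an 84% discharge rate, 445 thousand patient-days,
126 and 733 thousand emergency/outpatient attendances, and a 22 per-mille
mortality rate) when the panel has the matching 2/1/3/1 shape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .factors import FactorSpec
from .panel import Panel
from .tobit import TobitDesign

#: column means of the seven-cluster system in 2013, used as default magnitudes
#: for panels with the (m, q, s, k) = (2, 1, 3, 1) factor layout.
HKHA_2013_MEANS = (2747.0, 1030.0, 84.0, 445.0, 126.0, 733.0, 22.0)


@dataclass
class FrontierDesign:
    """Blueprint for a synthetic panel with a planted efficient frontier."""

    n_efficient: int = 4
    n_inefficient: int = 3
    m: int = 2
    q: int = 1
    s: int = 3
    k: int = 1
    seed: int = 0
    drift: float = 1.0                      # per-period multiplicative DO shift
    magnitudes: tuple | None = None          # per-column target means; None -> auto
    inefficiency_factors: dict | None = None  # dmu index -> dict(role -> multipliers)

    def __post_init__(self):
        if self.n_efficient < 1:
            raise ValueError("need n_efficient >= 1")
        if self.m < 1 or self.s < 1:
            raise ValueError("generator needs at least one DI and one DO factor")
        if self.m + self.q == 0 or self.s + self.k == 0:
            raise ValueError("need at least one input role and one output role")
        if self.drift <= 0:
            raise ValueError("drift must be positive")

    @property
    def dims(self):
        return self.m, self.q, self.s, self.k

    def spec(self) -> list[FactorSpec]:
        return (
            [FactorSpec(f"DI{i+1}", "DI") for i in range(self.m)]
            + [FactorSpec(f"UI{i+1}", "UI") for i in range(self.q)]
            + [FactorSpec(f"DO{i+1}", "DO") for i in range(self.s)]
            + [FactorSpec(f"UO{i+1}", "UO") for i in range(self.k)]
        )


def _sample_frontier_points(design: FrontierDesign, rng: np.random.Generator):
    """Points on a random supporting hyperplane w . z = 0 with z the signed
    factor vector (+DI, -UI, -DO, +UO); every strictly positive w makes the
    hyperplane supporting, hence every sampled point efficient."""
    m, q, s, k = design.dims
    wD = rng.uniform(1.0, 2.0, m)
    wI = rng.uniform(0.1, 0.2, q)
    wG = rng.uniform(0.1, 0.2, s)
    wB = rng.uniform(1.0, 2.0, k)
    pts = []
    while len(pts) < design.n_efficient:
        xD = rng.uniform(1.0, 2.0, m)
        xI = rng.uniform(1.0, 2.0, q)
        yB = rng.uniform(1.0, 2.0, k)
        yG = np.empty(s)
        yG[1:] = rng.uniform(1.0, 2.0, s - 1)
        resid = wD @ xD + wB @ yB - wI @ xI - wG[1:] @ yG[1:]
        if resid <= 0.1:      # rare for sensible dims; resample
            continue
        yG[0] = resid / wG[0]
        pts.append(np.concatenate([xD, xI, yG, yB]))
    return np.array(pts), (wD, wI, wG, wB)


def _default_multipliers(design: FrontierDesign, rng: np.random.Generator) -> dict:
    m, q, s, k = design.dims
    out = {}
    for j in range(design.n_inefficient):
        out[j] = {
            "DI": rng.uniform(0.6, 0.95, m),   # alpha-tilde <= 1: inputs inflated by 1/alpha
            "UI": rng.uniform(1.05, 1.3, q),   # gamma-tilde >= 1: UI deflated by 1/gamma
            "DO": rng.uniform(1.05, 1.5, s),   # beta-tilde >= 1: DO deflated by 1/beta
            "UO": rng.uniform(0.7, 0.95, k),   # theta-tilde <= 1: UO inflated by 1/theta
        }
    return out


def _check_multipliers(mult: dict) -> None:
    if np.any(np.asarray(mult["DI"]) > 1.0) or np.any(np.asarray(mult["UO"]) > 1.0):
        raise ValueError("DI/UO planted multipliers must be <= 1")
    if np.any(np.asarray(mult["UI"]) < 1.0) or np.any(np.asarray(mult["DO"]) < 1.0):
        raise ValueError("UI/DO planted multipliers must be >= 1")


def generate_frontier_panel(
    design: FrontierDesign, period=0
) -> tuple[Panel, pd.DataFrame]:
    """Generate a single-period panel plus its ground-truth table.

    Efficient DMUs lie on a common supporting hyperplane; inefficient DMUs
    are copies of randomly chosen efficient DMUs degraded by the planted
    multipliers (inputs inflated, desirable outputs deflated, and so on), so
    their generating point is a feasible frontier projection.  The truth
    table records the planted status, the generating DMU and the multipliers.
    """
    rng = np.random.default_rng(design.seed)
    m, q, s, k = design.dims
    eff, _ = _sample_frontier_points(design, rng)
    mults = design.inefficiency_factors
    if mults is None:
        mults = _default_multipliers(design, rng)
    gen_idx = rng.integers(0, design.n_efficient, design.n_inefficient)

    rows, truth = [], []
    names = [f"E{j+1:02d}" for j in range(design.n_efficient)] + \
            [f"I{j+1:02d}" for j in range(design.n_inefficient)]
    for j in range(design.n_efficient):
        rows.append(eff[j])
        truth.append({"dmu_id": names[j], "efficient": True, "generator": names[j]})
    for j in range(design.n_inefficient):
        mult = mults[j]
        _check_multipliers(mult)
        g = eff[gen_idx[j]]
        xD = g[:m] / np.asarray(mult["DI"], dtype=float)
        xI = g[m:m + q] / np.asarray(mult["UI"], dtype=float)
        yG = g[m + q:m + q + s] / np.asarray(mult["DO"], dtype=float)
        yB = g[m + q + s:] / np.asarray(mult["UO"], dtype=float)
        rows.append(np.concatenate([xD, xI, yG, yB]))
        truth.append({
            "dmu_id": names[design.n_efficient + j], "efficient": False,
            "generator": names[gen_idx[j]],
            "mult_DI": np.asarray(mult["DI"], dtype=float),
            "mult_UI": np.asarray(mult["UI"], dtype=float),
            "mult_DO": np.asarray(mult["DO"], dtype=float),
            "mult_UO": np.asarray(mult["UO"], dtype=float),
        })

    data = np.array(rows)
    mags = design.magnitudes
    if mags is None and (m, q, s, k) == (2, 1, 3, 1):
        mags = HKHA_2013_MEANS
    if mags is not None:
        mags = np.asarray(mags, dtype=float)
        data = data * (mags / data.mean(axis=0))  # column means hit targets exactly

    spec = design.spec()
    frame = pd.DataFrame(data, columns=[f.name for f in spec])
    frame.insert(0, "period", period)
    frame.insert(0, "dmu_id", names)
    truth_df = pd.DataFrame(truth)
    # keep the post-scaling generating points so projections can be checked
    gen_map = {t["dmu_id"]: i for i, t in enumerate(truth)}
    gen_rows = [data[gen_map[t["generator"]]] for t in truth]
    truth_df["generator_point"] = gen_rows
    return Panel(frame, spec), truth_df


def generate_drift_series(
    design: FrontierDesign,
    periods: int,
    static_dmus: tuple = (),
    own_decay: dict | None = None,
) -> list[Panel]:
    """Panel series with a multiplicative frontier drift on desirable outputs.

    Period ``p`` scales every DMU's desirable outputs by ``drift ** p``,
    except DMUs in ``static_dmus`` (frozen at period-0 data; their frontier
    moves away from them) and DMUs in ``own_decay`` (DO multiplied by
    ``own_decay[dmu] ** p`` instead — a pure technical-efficiency change when
    drift is 1 and the DMU is off-frontier).
    """
    if periods < 2:
        raise ValueError("need at least two periods")
    base, _ = generate_frontier_panel(design, period=0)
    do_cols = base.factor_names("DO")
    own_decay = own_decay or {}
    panels = []
    for p in range(periods):
        df = base.frame.copy()
        df["period"] = p
        scale = design.drift ** p
        for i, dmu in enumerate(df["dmu_id"]):
            if dmu in static_dmus:
                continue
            f = own_decay.get(dmu, None)
            df.loc[df.index[i], do_cols] = (
                base.frame.loc[base.frame.index[i], do_cols]
                * (f ** p if f is not None else scale)
            )
        panels.append(Panel(df, base.spec))
    return panels


def generate_tobit_panel(
    n: int,
    beta_true,
    sigma_true: float,
    censor_rate_target: float | None = None,
    seed: int = 0,
) -> tuple[TobitDesign, dict]:
    """Censored-regression data with known coefficients.

    Covariates are standard normal with a leading intercept column; the
    latent response ``X b + e`` is clipped to [0, 1].  Returns the design and
    an info dict with the achieved censoring fractions.  If a target
    censoring rate is requested and the achieved rate misses it by more than
    5 percentage points, a warning is emitted and generation proceeds.
    """
    beta_true = np.asarray(beta_true, dtype=float)
    p = len(beta_true)
    if n <= p:
        raise ValueError("need n > len(beta_true)")
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
    y_latent = X @ beta_true + sigma_true * rng.standard_normal(n)
    y = np.clip(y_latent, 0.0, 1.0)
    at_upper = float(np.mean(y_latent >= 1.0))
    at_lower = float(np.mean(y_latent <= 0.0))
    achieved = at_upper + at_lower
    if censor_rate_target is not None and abs(achieved - censor_rate_target) > 0.05:
        warnings.warn(
            f"achieved censoring {achieved:.3f} misses target {censor_rate_target:.3f} "
            "for the given coefficients; proceeding", stacklevel=2)
    design = TobitDesign(y, X, 0.0, 1.0)
    info = {"censored_upper": at_upper, "censored_lower": at_lower,
            "censored_total": achieved, "beta_true": beta_true,
            "sigma_true": float(sigma_true), "seed": seed}
    return design, info
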