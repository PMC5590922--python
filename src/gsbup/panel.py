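"""Panel container, CSV I/O, validation and descriptive reporting.

A :class:`Panel` holds observations of decision-making units (DMUs) — here
hospitals or hospital clusters — over one or more periods, with one column
per factor.  Factor roles come from a list of :class:`~gsbup.factors.FactorSpec`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .factors import FactorSpec, by_role, dims

log = logging.getLogger(__name__)

ID_COLS = ("dmu_id", "period")


class PanelSchemaError(ValueError):
    """Input file does not have the expected columns/shape."""


class PanelParseError(ValueError):
    """A cell could not be parsed as a number."""


class PanelValidationError(ValueError):
    """The data violate the model's domain requirements."""


@dataclass(frozen=True)
class DmuRecord:
    """Observed vectors of one DMU in one period.

    ``xD``/``xI`` are the desirable/undesirable input vectors, ``yG``/``yB``
    the desirable/undesirable output vectors.
    """

    dmu_id: str
    period: object
    xD: np.ndarray
    xI: np.ndarray
    yG: np.ndarray
    yB: np.ndarray

    def stacked(self) -> np.ndarray:
        return np.concatenate([self.xD, self.xI, self.yG, self.yB])


@dataclass
class ValidationReport:
    passed: bool
    issues: list[tuple] = field(default_factory=list)  # (dmu_id, factor, code, message)
    zero_substitutions: list[tuple] = field(default_factory=list)  # (dmu_id, period, factor, old, new)


class Panel:
    """A table of DMU observations plus its factor spec.

    Parameters
    ----------
    frame : pandas.DataFrame
        Columns ``dmu_id``, ``period`` and one numeric column per factor.
    spec : sequence of FactorSpec
    """

    def __init__(self, frame: pd.DataFrame, spec: Sequence[FactorSpec]):
        self.spec = list(spec)
        missing = [f.name for f in self.spec if f.name not in frame.columns]
        if missing:
            raise PanelSchemaError(f"panel is missing factor columns {missing}")
        for col in ID_COLS:
            if col not in frame.columns:
                raise PanelSchemaError(f"panel is missing required column {col!r}")
        if len(frame) == 0:
            raise PanelSchemaError("panel has no data rows")
        dup = frame.duplicated(subset=list(ID_COLS))
        if dup.any():
            pairs = frame.loc[dup, list(ID_COLS)].values.tolist()
            raise PanelSchemaError(f"duplicate (dmu_id, period) pairs: {pairs}")
        frame = frame[list(ID_COLS) + [f.name for f in self.spec]].copy()
        for f in self.spec:
            col = pd.to_numeric(frame[f.name], errors="coerce")
            bad = col.isna() & frame[f.name].notna() | frame[f.name].isna()
            if bad.any():
                row = int(np.flatnonzero(bad.values)[0])
                raise PanelParseError(
                    f"non-numeric or missing value in column {f.name!r}, row {row}"
                    f" (dmu_id={frame['dmu_id'].iloc[row]!r})"
                )
            frame[f.name] = col.astype(float)
        self.frame = frame.reset_index(drop=True)
        self.m, self.q, self.s, self.k = dims(self.spec)

    # -- shape helpers -------------------------------------------------
    @property
    def dims(self) -> tuple[int, int, int, int]:
        return self.m, self.q, self.s, self.k

    def factor_names(self, role: str | None = None) -> list[str]:
        if role is None:
            return [f.name for f in self.spec]
        return [f.name for f in by_role(self.spec)[role]]

    @property
    def periods(self) -> list:
        return sorted(self.frame["period"].unique().tolist())

    def dmu_ids(self, period=None) -> list[str]:
        df = self.frame if period is None else self.frame[self.frame["period"] == period]
        return df["dmu_id"].tolist()

    def subset(self, period) -> "Panel":
        df = self.frame[self.frame["period"] == period]
        if len(df) == 0:
            raise KeyError(f"no records for period {period!r}")
        return Panel(df, self.spec)

    def is_single_period(self) -> bool:
        return self.frame["period"].nunique() == 1

    # -- matrix/record access ------------------------------------------
    def matrices(self, period=None) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str]]:
        """Role-wise data matrices ``(XD, XI, YG, YB, dmu_ids)`` for one period.

        Each matrix has one row per DMU, in panel row order.
        """
        df = self.frame
        if period is not None:
            df = df[df["period"] == period]
        elif not self.is_single_period():
            raise ValueError("multi-period panel: pass period= explicitly")
        g = by_role(self.spec)
        mats = tuple(
            df[[f.name for f in g[role]]].to_numpy(dtype=float)
            for role in ("DI", "UI", "DO", "UO")
        )
        return (*mats, df["dmu_id"].tolist())

    def record(self, dmu_id: str, period=None) -> DmuRecord:
        df = self.frame
        if period is None:
            if not self.is_single_period():
                raise ValueError("multi-period panel: pass period= explicitly")
            period = df["period"].iloc[0]
        row = df[(df["dmu_id"] == dmu_id) & (df["period"] == period)]
        if len(row) != 1:
            raise KeyError(f"no unique record for ({dmu_id!r}, {period!r})")
        g = by_role(self.spec)
        vec = lambda role: row[[f.name for f in g[role]]].to_numpy(dtype=float)[0]
        return DmuRecord(dmu_id, period, vec("DI"), vec("UI"), vec("DO"), vec("UO"))

    def records(self, period=None) -> Iterator[DmuRecord]:
        df = self.frame if period is None else self.frame[self.frame["period"] == period]
        for _, row in df.iterrows():
            yield self.record(row["dmu_id"], row["period"])

    def __len__(self) -> int:
        return len(self.frame)

    def __repr__(self) -> str:
        m, q, s, k = self.dims
        return (f"Panel(n={len(self)}, periods={len(self.periods)}, "
                f"m={m}, q={q}, s={s}, k={k})")


def load_panel(path: str | Path, spec: Sequence[FactorSpec]) -> Panel:
    """Load a panel from CSV (``dmu_id, period, <factor...>`` with header row)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path, dtype={"dmu_id": str})
    except pd.errors.EmptyDataError as exc:
        raise PanelSchemaError(f"{path}: empty file") from exc
    if len(frame) == 0:
        raise PanelSchemaError(f"{path}: no data rows")
    return Panel(frame, spec)


def write_panel(panel: Panel, path: str | Path) -> None:
    """Write a panel back to CSV; float formatting round-trips exactly."""
    panel.frame.to_csv(path, index=False)


def validate_panel(
    panel: Panel, zero_policy: str = "substitute", zero_scale: float = 1e-3
) -> tuple[Panel, ValidationReport]:
    """Check non-negativity and positivity requirements; handle zeros.

    Every factor value must be non-negative, and each DMU needs at least one
    strictly positive input and output.  Zeros are a problem because the
    ratio variables divide by the evaluated DMU's own values; under
    ``zero_policy="substitute"`` a zero is replaced by ``zero_scale`` times
    that factor's cross-DMU mean (logged in the report), under ``"reject"``
    any zero raises.
    """
    if zero_policy not in ("substitute", "reject"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    report = ValidationReport(passed=True)
    df = panel.frame.copy()
    fnames = panel.factor_names()
    inputs = panel.factor_names("DI") + panel.factor_names("UI")
    outputs = panel.factor_names("DO") + panel.factor_names("UO")

    for _, row in df.iterrows():
        for name in fnames:
            if row[name] < 0:
                report.issues.append(
                    (row["dmu_id"], name, "negative",
                     f"negative value {row[name]!r} in period {row['period']!r}")
                )
        if inputs and all(row[n] == 0 for n in inputs):
            report.issues.append((row["dmu_id"], "", "all_zero_inputs",
                                  f"all inputs zero in period {row['period']!r}"))
        if outputs and all(row[n] == 0 for n in outputs):
            report.issues.append((row["dmu_id"], "", "all_zero_outputs",
                                  f"all outputs zero in period {row['period']!r}"))

    zero_mask = {name: df[name] == 0 for name in fnames}
    any_zero = any(mask.any() for mask in zero_mask.values())
    if any_zero and zero_policy == "reject":
        for name, mask in zero_mask.items():
            for i in np.flatnonzero(mask.values):
                report.issues.append(
                    (df["dmu_id"].iloc[i], name, "zero",
                     "zero value enters a ratio constraint (zero_policy='reject')")
                )
    elif any_zero:
        for name, mask in zero_mask.items():
            if not mask.any():
                continue
            repl = zero_scale * float(df[name].mean())
            for i in np.flatnonzero(mask.values):
                report.zero_substitutions.append(
                    (df["dmu_id"].iloc[i], df["period"].iloc[i], name, 0.0, repl)
                )
                log.info("substituting zero: dmu=%s period=%s factor=%s -> %g",
                         df["dmu_id"].iloc[i], df["period"].iloc[i], name, repl)
            df.loc[mask, name] = repl

    report.passed = not report.issues
    if not report.passed:
        errors = [i for i in report.issues if i[2] in
                  ("negative", "all_zero_inputs", "all_zero_outputs", "zero")]
        raise PanelValidationError(
            "panel validation failed: " + "; ".join(str(e) for e in errors[:10])
        )
    return Panel(df, panel.spec), report


def descriptive_stats(panel: Panel, period=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-factor summary statistics and the Pearson correlation matrix.

    Returns a ``(stats, corr)`` pair.  The rows of ``stats`` are maximum,
    minimum, median, mean, sample standard deviation (n-1 denominator),
    Fisher skewness and excess kurtosis.  A constant column yields SD 0 and
    NaN skewness/kurtosis with a warning.
    """
    df = panel.frame
    if period is not None:
        df = df[df["period"] == period]
    if len(df) < 2:
        raise PanelValidationError("descriptive statistics need at least 2 records")
    data = df[panel.factor_names()]
    rows = {}
    rows["max"] = data.max()
    rows["min"] = data.min()
    rows["median"] = data.median()
    rows["mean"] = data.mean()
    rows["sd"] = data.std(ddof=1)
    constant = rows["sd"] == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rows["skewness"] = pd.Series(sps.skew(data, axis=0, bias=True), index=data.columns)
        rows["kurtosis"] = pd.Series(sps.kurtosis(data, axis=0, fisher=True, bias=True),
                                     index=data.columns)
    if constant.any():
        names = list(data.columns[constant])
        rows["skewness"][constant] = np.nan
        rows["kurtosis"][constant] = np.nan
        warnings.warn(f"constant factor column(s) {names}: skewness/kurtosis undefined",
                      RuntimeWarning, stacklevel=2)
    stats = pd.DataFrame(rows).T
    corr = data.corr(method="pearson")
    return stats, corr
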