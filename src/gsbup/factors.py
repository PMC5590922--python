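"""Factor roles and preference weights.

Every column of a panel is assigned one of four roles:

* ``DI`` — desirable input (e.g. staff, beds): less is better.
* ``UI`` — undesirable input (e.g. discharge rate): more is better.
* ``DO`` — desirable output (e.g. attendances): more is better.
* ``UO`` — undesirable output (e.g. mortality rate): less is better.

The non-oriented slacks-based model weighs the contraction ratios of the
DI/UO group against the expansion ratios of the UI/DO group.  The preference
weights therefore come in two normalisation groups: the DI weights ``omega``
and UO weights ``nu`` sum to one, and the UI weights ``sigma`` and DO weights
``mu`` sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

ROLES = ("DI", "UI", "DO", "UO")

#: groups that must each carry total preference mass 1:
#: (DI, UO) enter the numerator of the efficiency ratio, (UI, DO) the denominator.
NUMERATOR_ROLES = ("DI", "UO")
DENOMINATOR_ROLES = ("UI", "DO")

_WEIGHT_TOL = 1e-12


class FactorSpecError(ValueError):
    """Raised for an invalid factor specification."""


@dataclass(frozen=True)
class FactorSpec:
    """Role assignment for one panel column.

    Parameters
    ----------
    name : str
        Column label in the panel.
    role : {"DI", "UI", "DO", "UO"}
    weight : float, optional
        Preference weight within the role's normalisation group.  Leave
        ``None`` to receive an equal share (see :func:`resolve_weights`).
    unit : str
        Free-text unit annotation, informational only.
    """

    name: str
    role: str
    weight: float | None = None
    unit: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise FactorSpecError(
                f"factor {self.name!r}: role must be one of {ROLES}, got {self.role!r}"
            )
        if self.weight is not None and self.weight < 0:
            raise FactorSpecError(f"factor {self.name!r}: weight must be >= 0")


@dataclass(frozen=True)
class PreferenceWeights:
    """Resolved weight vectors, ordered as the factors appear in the spec.

    ``omega`` (DI), ``sigma`` (UI), ``mu`` (DO), ``nu`` (UO).
    """

    omega: np.ndarray
    sigma: np.ndarray
    mu: np.ndarray
    nu: np.ndarray

    def validate(self) -> None:
        for arr, label in ((self.omega, "omega"), (self.sigma, "sigma"),
                           (self.mu, "mu"), (self.nu, "nu")):
            if np.any(np.asarray(arr) < 0):
                raise FactorSpecError(f"{label} weights must be non-negative")
        num = float(np.sum(self.omega) + np.sum(self.nu))
        den = float(np.sum(self.sigma) + np.sum(self.mu))
        if abs(num - 1.0) > 1e-9 or abs(den - 1.0) > 1e-9:
            raise FactorSpecError(
                "weights must satisfy sum(omega)+sum(nu)=1 and "
                f"sum(sigma)+sum(mu)=1; got {num:.12g} and {den:.12g}"
            )

    @classmethod
    def equal(cls, m: int, q: int, s: int, k: int) -> "PreferenceWeights":
        """Equal weights within each normalisation group."""
        if m + k == 0 or q + s == 0:
            raise FactorSpecError(
                "need at least one factor in the DI/UO group and one in the UI/DO group"
            )
        return cls(
            omega=np.full(m, 1.0 / (m + k)),
            sigma=np.full(q, 1.0 / (q + s)),
            mu=np.full(s, 1.0 / (q + s)),
            nu=np.full(k, 1.0 / (m + k)),
        )


def by_role(spec: Sequence[FactorSpec]) -> dict[str, list[FactorSpec]]:
    out: dict[str, list[FactorSpec]] = {r: [] for r in ROLES}
    for f in spec:
        out[f.role].append(f)
    return out


def dims(spec: Sequence[FactorSpec]) -> tuple[int, int, int, int]:
    """Counts (m, q, s, k) of DI, UI, DO, UO factors."""
    g = by_role(spec)
    return len(g["DI"]), len(g["UI"]), len(g["DO"]), len(g["UO"])


def resolve_weights(spec: Sequence[FactorSpec]) -> PreferenceWeights:
    """Resolve explicit/implicit preference weights for a factor spec.

    Within each normalisation group, either every factor carries an explicit
    weight (which must sum to one to within 1e-12) or none does (equal split).
    Mixing explicit and implicit weights inside one group is ambiguous and
    rejected.
    """
    g = by_role(spec)
    m, q, s, k = dims(spec)
    if m + k == 0 or q + s == 0:
        raise FactorSpecError(
            "need at least one DI or UO factor and at least one UI or DO factor"
        )
    resolved: dict[str, np.ndarray] = {}
    for roles, size in ((NUMERATOR_ROLES, m + k), (DENOMINATOR_ROLES, q + s)):
        members = [f for r in roles for f in g[r]]
        explicit = [f.weight for f in members if f.weight is not None]
        if not explicit:
            vals = {f.name: 1.0 / size for f in members}
        elif len(explicit) == len(members):
            total = sum(explicit)
            if abs(total - 1.0) > _WEIGHT_TOL:
                raise FactorSpecError(
                    f"explicit weights of group {roles} sum to {total!r}, expected 1"
                )
            vals = {f.name: float(f.weight) for f in members}
        else:
            raise FactorSpecError(
                f"group {roles}: give weights for all factors or none"
            )
        for f in members:
            resolved[f.name] = vals[f.name]
    w = PreferenceWeights(
        omega=np.array([resolved[f.name] for f in g["DI"]], dtype=float),
        sigma=np.array([resolved[f.name] for f in g["UI"]], dtype=float),
        mu=np.array([resolved[f.name] for f in g["DO"]], dtype=float),
        nu=np.array([resolved[f.name] for f in g["UO"]], dtype=float),
    )
    w.validate()
    return w


def load_factor_spec(path: str | Path) -> list[FactorSpec]:
    """Read a factor spec from a YAML mapping ``name -> {role, weight, unit}``."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or not raw:
        raise FactorSpecError(f"{path}: expected a non-empty mapping of factors")
    out = []
    for name, entry in raw.items():
        if isinstance(entry, str):
            entry = {"role": entry}
        out.append(
            FactorSpec(
                name=str(name),
                role=str(entry["role"]).upper(),
                weight=entry.get("weight"),
                unit=str(entry.get("unit", "")),
            )
        )
    return out


def save_factor_spec(spec: Iterable[FactorSpec], path: str | Path) -> None:
    doc = {
        f.name: {
            "role": f.role,
            **({"weight": float(f.weight)} if f.weight is not None else {}),
            **({"unit": f.unit} if f.unit else {}),
        }
        for f in spec
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
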