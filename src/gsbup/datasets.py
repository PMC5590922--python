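"""Bundled worked example: the seven Hong Kong hospital clusters, 2013.

The panel carries the published input-output levels of the seven geographic
clusters (two desirable inputs: full-time staff and beds; one undesirable
input: in-patient discharge rate; three desirable outputs: patient-days, ED
attendances, outpatient attendances; one undesirable output: crude mortality
rate).  The companion reference table holds the scores, returns-to-scale
labels and slacks as published alongside that panel, for comparison — see
:func:`compare_with_published`: parts of the published column are not
reproducible from the cluster-level panel itself (they appear to derive from
hospital-level data that was not published), and the comparison makes the
agreement and disagreement explicit instead of papering over it.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .efficiency import GsbupEfficiency
from .factors import FactorSpec, load_factor_spec
from .panel import Panel

_DATA = resources.files("gsbup") / "data"


def cluster_factor_spec() -> list[FactorSpec]:
    with resources.as_file(_DATA / "hkha_factors.yml") as p:
        return load_factor_spec(p)


def load_cluster_panel() -> Panel:
    """The seven-cluster 2013 panel (n=7, m=2, q=1, s=3, k=1)."""
    spec = cluster_factor_spec()
    with resources.as_file(_DATA / "hkha_clusters_2013.csv") as p:
        frame = pd.read_csv(p, dtype={"dmu_id": str})
    return Panel(frame, spec)


def load_cluster_reference() -> pd.DataFrame:
    """Published scores, RTS labels and slacks for the 2013 cluster panel."""
    with resources.as_file(_DATA / "hkha_clusters_2013_published.csv") as p:
        return pd.read_csv(p, dtype={"dmu_id": str}).set_index("dmu_id")


def compare_with_published(
    gamma: str = "crs", score_atol: float = 5e-4, slack_atol: float = 0.01
) -> pd.DataFrame:
    """Score the bundled panel and compare with the published reference.

    Returns one row per cluster with the computed score, the published score,
    and boolean ``score_matches`` / ``slacks_match`` columns.  Frontier
    membership (score exactly 1) is independent of the preference weights, so
    disagreement on an efficient cluster cannot be explained by weight
    choices; mismatches are reported, not reconciled.
    """
    panel = load_cluster_panel()
    ref = load_cluster_reference()
    est = GsbupEfficiency(gamma=gamma).fit(panel)
    rows = []
    slack_cols = [c for c in ref.columns if c.startswith("s_")]
    for dmu in panel.dmu_ids():
        sol = est.solutions_[dmu]
        pub_slacks = ref.loc[dmu, slack_cols].to_numpy(dtype=float)
        rows.append({
            "dmu_id": dmu,
            "score": sol.delta,
            "published_score": float(ref.loc[dmu, "score"]),
            "score_matches": abs(sol.delta - float(ref.loc[dmu, "score"])) <= score_atol,
            "slacks_match": bool((abs(sol.slacks - pub_slacks) <= slack_atol).all()),
        })
    return pd.DataFrame(rows).set_index("dmu_id")
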