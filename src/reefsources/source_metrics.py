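"""Graph-theoretic source metrics and key-source identification.

Five properties measure a reef's value as a larval source in each
scenario network (self-loops excluded throughout):

1. out_degree          -- number of distinct reefs it supplies
2. out_strength        -- total outgoing weight
3. strong_link_degree  -- out-edges carrying >10% of the sink's inflow
4. major_source_degree -- out-edges terminating at that network's "major
   sources" (reefs at or above their regional median on metrics 1-3
   simultaneously)
5. out_component_size  -- reefs reachable along directed positive edges

Reefs are percentile-ranked *within management regions* (demographically
relevant connectivity does not span the whole system, so a reef competes
against its regional peers).  A reef qualifies in a scenario when all
five regional percentiles are at or above 50, and is a *key source* when
it qualifies in at least half of the maximum observed number of
qualifying scenarios.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from reefsources.connectivity import ConnectivityNetwork, inflow_share

__all__ = [
    "METRIC_NAMES",
    "out_component_size",
    "network_metrics",
    "regional_rank",
    "identify_key_sources",
]

METRIC_NAMES = ("out_degree", "out_strength", "strong_link_degree",
                "major_source_degree", "out_component_size")

STRONG_LINK_SHARE = 0.1
QUALIFY_PERCENTILE = 50.0


def out_component_size(net: ConnectivityNetwork, reef_id: str) -> int:
    """Number of other reefs reachable from reef_id along directed
    positive-weight edges (the size of the node's out-component)."""
    if reef_id not in net.reef_ids:
        raise KeyError(reef_id)
    g = nx.from_numpy_array((net.off_diagonal() > 0),
                            create_using=nx.DiGraph)
    return len(nx.descendants(g, net.reef_ids.index(reef_id)))


def _out_component_sizes(adj: np.ndarray) -> np.ndarray:
    g = nx.from_numpy_array(adj, create_using=nx.DiGraph)
    return np.array([len(nx.descendants(g, i)) for i in range(adj.shape[0])])


def network_metrics(net: ConnectivityNetwork,
                    regions: dict[str, int]) -> pd.DataFrame:
    """The five source metrics for every reef of one scenario network."""
    off = net.off_diagonal()
    adj = off > 0
    share = inflow_share(net)

    out_degree = adj.sum(axis=1)
    out_strength = off.sum(axis=1)
    strong_link_degree = (share > STRONG_LINK_SHARE).sum(axis=1)

    # major sources of *this* network: at or above the regional median on
    # metrics 1-3 simultaneously
    region = np.array([regions[r] for r in net.reef_ids])
    major = np.ones(net.n, dtype=bool)
    for values in (out_degree, out_strength, strong_link_degree):
        med = np.empty(net.n)
        for reg in np.unique(region):
            m = region == reg
            med[m] = np.median(values[m])
        major &= values >= med
    major_source_degree = (adj & major[None, :]).sum(axis=1)

    return pd.DataFrame({
        "reef_id": net.reef_ids,
        "scenario_id": net.scenario_id,
        "out_degree": out_degree,
        "out_strength": out_strength,
        "strong_link_degree": strong_link_degree,
        "major_source_degree": major_source_degree,
        "out_component_size": _out_component_sizes(adj),
    })


def regional_rank(values: pd.Series, regions: dict[str, int]) -> pd.Series:
    """Mid-rank percentile of each value within its region, in [0, 100].

    Percentile = (rank - 0.5) / n * 100 with ties sharing the mean rank;
    a single-reef region scores 50 by this convention.
    """
    region = values.index.map(regions)
    out = pd.Series(np.nan, index=values.index, dtype=float)
    for reg in region.unique():
        m = region == reg
        v = values[m]
        out[m] = (rankdata(v.to_numpy(), method="average") - 0.5) / len(v) * 100.0
    return out


def qualification_counts(all_metrics: pd.DataFrame,
                         regions: dict[str, int]) -> pd.Series:
    """Scenarios in which each reef ranks at or above the regional 50th
    percentile on all five metrics simultaneously."""
    counts = None
    for _, grp in all_metrics.groupby("scenario_id", sort=True):
        grp = grp.set_index("reef_id")
        ok = pd.Series(True, index=grp.index)
        for name in METRIC_NAMES:
            pct = regional_rank(grp[name], regions)
            ok &= pct >= QUALIFY_PERCENTILE
        counts = ok.astype(int) if counts is None else counts.add(ok.astype(int),
                                                                  fill_value=0)
    if counts is None:
        raise ValueError("need at least one scenario")
    return counts.astype(int)


def identify_key_sources(all_metrics: pd.DataFrame,
                         regions: dict[str, int]) -> pd.DataFrame:
    """Consensus key sources over the scenario grid.

    all_metrics: concatenated network_metrics rows over scenarios.
    A reef is a key source when its number of qualifying scenarios is at
    least half the maximum observed over reefs (ceil).  Returns a frame
    indexed by reef_id with qualifying_scenario_count, threshold_count
    and is_key_source.
    """
    counts = qualification_counts(all_metrics, regions)
    max_count = int(counts.max())
    threshold = math.ceil(0.5 * max_count)
    is_key = (counts >= threshold) & (max_count > 0)
    return pd.DataFrame({
        "qualifying_scenario_count": counts,
        "threshold_count": threshold,
        "is_key_source": is_key,
    })
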