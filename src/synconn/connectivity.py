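"""Three-criterion functional-connectivity classification and per-state graphs.

A unit pair is *functionally connected* in a state when (1) its binned-count
Pearson correlation is at least ``r_min`` (0.2, the value that yields
p < 0.05 at the session's bin counts), (2) its cross-correlogram peak
exceeds two SDs above the correlogram mean, and (3) both units fired more
than 3,000 spikes over the session with at least 1,000 spikes in each of the
spontaneous and evoked states.  Each neuron's *connectivity index* is the
percentage of the other recorded neurons it is connected to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import canonical_pair
from .types import ValidationError


@dataclass
class ConnectivityCriteria:
    r_min: float = 0.2
    peak_z_min: float = 2.0
    min_total_spikes: int = 3000
    min_state_spikes: int = 1000

    def __post_init__(self) -> None:
        if min(self.r_min, self.peak_z_min, self.min_total_spikes, self.min_state_spikes) <= 0:
            raise ValidationError("all criteria thresholds must be positive")


def classify_pair(row: pd.Series | dict, criteria: ConnectivityCriteria | None = None) -> bool:
    """Apply the three-criterion rule to one pair-metrics record.

    The correlation and correlogram criteria are evaluated on the state
    being classified; the spike-count floors apply to the whole session and
    to both states, as the rule states them.  Non-evaluable metrics (NaN)
    classify as not connected.
    """
    c = criteria or ConnectivityCriteria()
    r = row["pearson_r"]
    z = row["peak_z"]
    if r is None or np.isnan(r) or z is None or np.isnan(z):
        return False
    counts_ok = (
        row["total_spikes_a"] > c.min_total_spikes
        and row["total_spikes_b"] > c.min_total_spikes
        and row["spont_spikes_a"] >= c.min_state_spikes
        and row["spont_spikes_b"] >= c.min_state_spikes
        and row["evoked_spikes_a"] >= c.min_state_spikes
        and row["evoked_spikes_b"] >= c.min_state_spikes
    )
    return bool(counts_ok and r >= c.r_min and z > c.peak_z_min)


@dataclass
class ConnectivityGraph:
    """Undirected per-state graph over the accepted units."""

    state: str
    graph: nx.Graph
    connectivity_index: dict[str, float] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(canonical_pair(a, b) for a, b in self.graph.edges)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def mean_index(self) -> float:
        return float(np.mean(list(self.connectivity_index.values())))

    def density(self) -> float:
        n = self.graph.number_of_nodes()
        if n < 2:
            return float("nan")
        return 2.0 * self.n_edges / (n * (n - 1))


def _index_from_graph(g: nx.Graph) -> dict[str, float]:
    n = g.number_of_nodes()
    if n < 2:
        return {u: 0.0 for u in g.nodes}
    return {u: 100.0 * g.degree(u) / (n - 1) for u in g.nodes}


def build_graph(
    metrics: pd.DataFrame,
    state: str,
    criteria: ConnectivityCriteria | None = None,
    nodes: list[str] | None = None,
) -> ConnectivityGraph:
    """Graph of connected pairs for one state, with per-node indices."""
    sub = metrics[metrics["state"] == state]
    if nodes is None:
        nodes = sorted(set(sub["unit_id_a"]) | set(sub["unit_id_b"]))
    if len(nodes) < 2:
        raise ValidationError("need at least two nodes")
    g = nx.Graph()
    g.add_nodes_from(sorted(nodes))
    c = criteria or ConnectivityCriteria()
    for _, row in sub.iterrows():
        if classify_pair(row, c):
            g.add_edge(row["unit_id_a"], row["unit_id_b"], r=row["pearson_r"], peak_z=row["peak_z"])
    return ConnectivityGraph(state, g, _index_from_graph(g))


def connectivity_index_table(
    g_spont: ConnectivityGraph, g_evoked: ConnectivityGraph
) -> pd.DataFrame:
    """Per-unit spontaneous/evoked indices and the relative change
    (evoked - spont) / spont; units with a zero spontaneous index are flagged
    not-evaluable (NaN) and excluded from averages."""
    if set(g_spont.nodes) != set(g_evoked.nodes):
        raise ValidationError("graphs must share one node set")
    rows = []
    for u in g_spont.nodes:
        s = g_spont.connectivity_index[u]
        e = g_evoked.connectivity_index[u]
        rows.append(
            {
                "unit_id": u,
                "index_spont": s,
                "index_evoked": e,
                "relative_change": (e - s) / s if s > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def overlap_fraction(g_evoked: ConnectivityGraph, g_spont: ConnectivityGraph) -> float:
    """Fraction of evoked-state edges that are also spontaneous-state edges.

    NaN when the evoked graph has no edges (not evaluable).
    """
    if set(g_evoked.nodes) != set(g_spont.nodes):
        raise ValidationError("graphs must share one node set")
    e_ev = set(g_evoked.edges)
    if not e_ev:
        return float("nan")
    return len(e_ev & set(g_spont.edges)) / len(e_ev)
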