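"""Topology statistics on the per-state connectivity graphs.

Covers the non-random-topology analyses: connection probability of pairs
sharing a common neighbor vs the Erdos-Renyi expectation, distance and
layer dependence of connectivity (single-shaft probe, so pair distance is
the depth difference), and tuning-congruence connection probabilities with
their finite-sample random baselines.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import ConnectivityGraph
from .types import UnitMeta, ValidationError

PAIR_DISTANCE_BIN_UM = 50.0


@dataclass
class TopologyStats:
    """Connection probabilities partitioned by common-neighbor status."""

    state: str
    p_common: float  # among pairs sharing >= 1 common neighbor
    p_nocommon: float  # among pairs sharing none
    p_expected: float  # Erdos-Renyi expectation = graph density
    n_common_pairs: int
    n_nocommon_pairs: int


def common_neighbor_stats(g: ConnectivityGraph) -> TopologyStats:
    """Partition all unordered pairs by whether they share a connected
    neighbor and report the connection probability within each partition.

    The partitioning and the scoring use the same graph, mirroring how the
    analysis is constructed from a single recorded network.  An empty
    partition yields NaN for its probability.
    """
    nodes = g.nodes
    if len(nodes) < 3:
        raise ValidationError("need at least 3 nodes")
    adj = {u: set(g.graph.neighbors(u)) for u in nodes}
    n_common = n_nocommon = c_common = c_nocommon = 0
    for a, b in combinations(nodes, 2):
        shared = bool((adj[a] & adj[b]) - {a, b})
        connected = g.graph.has_edge(a, b)
        if shared:
            n_common += 1
            c_common += connected
        else:
            n_nocommon += 1
            c_nocommon += connected
    return TopologyStats(
        state=g.state,
        p_common=c_common / n_common if n_common else float("nan"),
        p_nocommon=c_nocommon / n_nocommon if n_nocommon else float("nan"),
        p_expected=g.density(),
        n_common_pairs=n_common,
        n_nocommon_pairs=n_nocommon,
    )


def degree_preserving_null(
    g: ConnectivityGraph, n_swaps: int = 1000, seed: int = 0
) -> ConnectivityGraph:
    """Degree-preserving rewired null graph (optional alternative to the
    Erdos-Renyi expectation)."""
    h = g.graph.copy()
    if h.number_of_edges() >= 2:
        nx.double_edge_swap(h, nswap=n_swaps, max_tries=50 * n_swaps, seed=seed)
    from .connectivity import _index_from_graph

    return ConnectivityGraph(g.state, h, _index_from_graph(h))


# --------------------------------------------------------------------------
# distance dependence


def _depths(meta: list[UnitMeta], nodes: list[str]) -> dict[str, float]:
    lookup = {m.unit_id: m.depth_um for m in meta}
    missing = [u for u in nodes if u not in lookup]
    if missing:
        raise ValidationError(f"missing depth metadata for {missing}")
    return {u: lookup[u] for u in nodes}


def distance_profile(
    graphs: dict[str, ConnectivityGraph],
    meta: list[UnitMeta],
    bin_um: float = PAIR_DISTANCE_BIN_UM,
) -> pd.DataFrame:
    """Per-distance-bin connection probability per state, plus the
    evoked/spontaneous ratio where both are defined.

    Pair distance is the absolute depth difference (vertical single-shaft
    probe); bin 0 holds same-contact pairs.  Probabilities weighted by the
    per-bin pair counts average back to each graph's density.
    """
    states = list(graphs)
    nodes = graphs[states[0]].nodes
    for g in graphs.values():
        if g.nodes != nodes:
            raise ValidationError("graphs must share one node set")
    depth = _depths(meta, nodes)
    pairs = list(combinations(nodes, 2))
    d_um = np.array([abs(depth[a] - depth[b]) for a, b in pairs])
    bins = (d_um / bin_um).astype(int)
    records = []
    for b in sorted(set(bins)):
        sel = bins == b
        row: dict[str, object] = {
            "bin_low_um": b * bin_um,
            "distance_um": b * bin_um,
            "n_pairs": int(sel.sum()),
        }
        for state in states:
            g = graphs[state]
            connected = np.array([g.graph.has_edge(a, b_) for (a, b_), s in zip(pairs, sel) if s])
            row[f"p_{state}"] = float(connected.mean()) if connected.size else float("nan")
        if {"spontaneous", "evoked"} <= set(states):
            ps, pe = row["p_spontaneous"], row["p_evoked"]
            row["evoked_spont_ratio"] = pe / ps if ps and ps > 0 else float("nan")
        records.append(row)
    return pd.DataFrame(records)


def mean_connected_distance(g: ConnectivityGraph, meta: list[UnitMeta]) -> float:
    """Mean depth distance (um) among connected pairs; NaN when edgeless."""
    depth = _depths(meta, g.nodes)
    edges = g.edges
    if not edges:
        return float("nan")
    return float(np.mean([abs(depth[a] - depth[b]) for a, b in edges]))


# --------------------------------------------------------------------------
# layer dependence


def layer_stats(
    g_spont: ConnectivityGraph, g_evoked: ConnectivityGraph, meta: list[UnitMeta]
) -> pd.DataFrame:
    """Connection probability per layer and for intra- vs inter-layer pairs,
    with the relative desynchronization (evoked - spont) / spont of each
    grouping.  Groupings with fewer than one candidate pair are NaN."""
    layer = {m.unit_id: m.layer for m in meta}
    nodes = g_spont.nodes
    if g_evoked.nodes != nodes:
        raise ValidationError("graphs must share one node set")
    missing = [u for u in nodes if u not in layer]
    if missing:
        raise ValidationError(f"missing layer labels for {missing}")
    pairs = list(combinations(nodes, 2))

    groupings: dict[str, list[tuple[str, str]]] = {}
    for a, b in pairs:
        if layer[a] == layer[b]:
            groupings.setdefault(layer[a], []).append((a, b))
            groupings.setdefault("intra", []).append((a, b))
        else:
            groupings.setdefault("inter", []).append((a, b))

    rows = []
    for name, members in sorted(groupings.items()):
        ps = float(np.mean([g_spont.graph.has_edge(a, b) for a, b in members]))
        pe = float(np.mean([g_evoked.graph.has_edge(a, b) for a, b in members]))
        rows.append(
            {
                "group": name,
                "n_pairs": len(members),
                "p_spontaneous": ps,
                "p_evoked": pe,
                "relative_desynchronization": (pe - ps) / ps if ps > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# tuning congruence


@dataclass
class CongruenceStats:
    state: str
    observed: float  # fraction of connected pairs sharing a preference
    expected: float  # same-category pair fraction of the node set
    n_edges: int


def expected_congruence(preferences: dict[str, object], nodes: list[str]) -> float:
    """Finite-sample expected same-category fraction under random pairing:
    sum_k n_k (n_k - 1) / (N (N - 1)) over the observed preference counts."""
    cats = pd.Series([preferences[u] for u in nodes])
    n = len(nodes)
    if n < 2:
        raise ValidationError("need at least 2 nodes")
    counts = cats.value_counts()
    return float(sum(c * (c - 1) for c in counts) / (n * (n - 1)))


def congruence_stats(
    g: ConnectivityGraph, preferences: dict[str, object]
) -> CongruenceStats:
    """Observed fraction of connected pairs sharing the same preferred
    category vs the random-pairing expectation over the same unit set."""
    nodes = g.nodes
    missing = [u for u in nodes if u not in preferences or preferences[u] is None]
    if missing:
        raise ValidationError(f"missing preferences for {missing}")
    expected = expected_congruence(preferences, nodes)
    edges = g.edges
    if not edges:
        return CongruenceStats(g.state, float("nan"), expected, 0)
    observed = float(np.mean([preferences[a] == preferences[b] for a, b in edges]))
    return CongruenceStats(g.state, observed, expected, len(edges))
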