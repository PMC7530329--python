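"""Centrality analysis of the lncRNA-mRNA network.

Three per-node measures, all on the undirected unweighted graph:

* degree — number of incident edges;
* betweenness centrality — sum over unordered node pairs (s, t), s != v != t,
  of the fraction of shortest s-t paths passing through v (unnormalized);
* closeness centrality — reciprocal of the summed shortest-path distance
  from v to every node it can reach (unnormalized reciprocal-sum form).

Hub candidates are the nodes appearing in the top-k of all three rankings.
"""

from __future__ import annotations

import warnings

import networkx as nx
import pandas as pd

from .datatypes import LNCRNA

CENTRALITY_DIMENSIONS = ("degree", "betweenness", "closeness")


def compute_centralities(g: nx.Graph) -> pd.DataFrame:
    """Degree, betweenness and closeness for every node of ``g``.

    Returns a DataFrame indexed by node with columns ``node_class``,
    ``degree``, ``betweenness``, ``closeness``.  Disconnected graphs are
    handled per component: closeness sums distances over the reachable set
    only (an isolated node gets 0), betweenness counts no cross-component
    pairs.  An edgeless graph raises ``ValueError``.
    """
    if g.number_of_edges() == 0:
        raise ValueError("graph has no edges; centralities undefined")
    bc = nx.betweenness_centrality(g, normalized=False)
    closeness = {}
    for node in g.nodes:
        dists = nx.single_source_shortest_path_length(g, node)
        total = sum(d for d in dists.values())
        closeness[node] = 1.0 / total if total > 0 else 0.0
    table = pd.DataFrame(
        {
            "node_class": pd.Series(dict(g.nodes(data="node_class"))),
            "degree": pd.Series(dict(g.degree())),
            "betweenness": pd.Series(bc),
            "closeness": pd.Series(closeness),
        }
    )
    return table.sort_index()


def top_k_nodes(table: pd.DataFrame, dimension: str, k: int) -> set[str]:
    """Top-k node set for one dimension, ties at the k-th value included."""
    if dimension not in CENTRALITY_DIMENSIONS:
        raise ValueError(f"unknown dimension {dimension!r}")
    ranked = table[dimension].sort_values(
        ascending=False, kind="mergesort"
    )  # stable; secondary order = index order of the (sorted) table
    if k >= len(ranked):
        return set(ranked.index)
    cutoff = ranked.iloc[k - 1]
    return set(ranked.index[ranked >= cutoff])


def top_k_overlap(
    table: pd.DataFrame, k: int = 10, restrict_class: str | None = LNCRNA
) -> set[str]:
    """Nodes in the top-k of degree, betweenness and closeness simultaneously.

    The intersection is filtered to ``restrict_class`` (pass ``None`` to keep
    all classes).  If ``k`` exceeds the node count, all nodes are used and a
    warning is issued.
    """
    if table.empty:
        raise ValueError("centrality table is empty")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > len(table):
        warnings.warn(
            f"k={k} exceeds node count {len(table)}; using all nodes"
        )
        k = len(table)
    overlap = set(table.index)
    for dim in CENTRALITY_DIMENSIONS:
        overlap &= top_k_nodes(table, dim, k)
    if restrict_class is not None:
        overlap = {
            n for n in overlap if table.loc[n, "node_class"] == restrict_class
        }
    return overlap
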