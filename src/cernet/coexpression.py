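"""Pearson co-expression screening and lncRNA-centric ceRNA module extraction.

Edges of the lncRNA-mRNA network are screened on the log2 expression matrix:
a pair survives when r > r_min and p < p_max (strict, default 0.6 / 0.05),
with the two-sided p-value from the t-transform

    t = r * sqrt((n - 2) / (1 - r^2)),  df = n - 2.

For a surviving lncRNA, the ceRNA module collects its retained co-expressed
mRNAs plus every miRNA adjacent (in the global triple network) to both the
lncRNA and at least one member mRNA, with both edge layers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, TripleNetwork

R_MIN = 0.6
P_MAX = 0.05


@dataclass
class CoexpressionPair:
    """One lncRNA-mRNA network edge with its expression correlation."""

    lnc_id: str
    mrna_id: str
    r: float
    p: float


@dataclass
class CeRNAModule:
    """A lncRNA-centered sub-network: co-expressed mRNAs and shared miRNAs."""

    lnc_id: str
    mrna_ids: set[str]
    mirna_ids: set[str]
    lnc_mi_edges: set[tuple[str, str]] = field(default_factory=set)
    mrna_mi_edges: set[tuple[str, str]] = field(default_factory=set)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_node(self.lnc_id, node_class="lncRNA")
        for m in self.mrna_ids:
            g.add_node(m, node_class="mRNA")
        for mi in self.mirna_ids:
            g.add_node(mi, node_class="miRNA")
        g.add_edges_from(self.lnc_mi_edges, layer="lnc_mi")
        g.add_edges_from(self.mrna_mi_edges, layer="mrna_mi")
        return g


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson r and its two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(xc @ yc) / denom
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def coexpressed_pairs(
    lclmn: nx.Graph,
    expr: ExpressionMatrix,
    r_min: float = R_MIN,
    p_max: float = P_MAX,
) -> list[CoexpressionPair]:
    """Screen every network edge; keep pairs with r > r_min and p < p_max.

    Edges whose endpoints lack expression rows are skipped with a warning.
    An empty network yields an empty list.
    """
    retained: list[CoexpressionPair] = []
    missing: set[str] = set()
    have = set(expr.values.index)
    for u, v in sorted(lclmn.edges):
        if lclmn.nodes[u].get("node_class") == "mRNA":
            u, v = v, u  # orient lnc first
        if u not in have or v not in have:
            missing.update({u, v} - have)
            continue
        r, p = pearson_with_p(expr.values.loc[u], expr.values.loc[v])
        if r > r_min and p < p_max:
            retained.append(CoexpressionPair(u, v, r, p))
    if missing:
        warnings.warn(
            f"{len(missing)} network node(s) missing from the expression "
            f"matrix were skipped: {sorted(missing)[:8]}"
        )
    retained.sort(key=lambda cp: (cp.lnc_id, cp.mrna_id))
    return retained


def extract_module(
    lnc_id: str, pairs: list[CoexpressionPair], g: TripleNetwork
) -> CeRNAModule:
    """ceRNA module of one lncRNA from its retained co-expression pairs.

    The module's miRNAs are exactly those adjacent to the lncRNA AND to at
    least one member mRNA in the global triple network ``g``.
    """
    members = {cp.mrna_id for cp in pairs if cp.lnc_id == lnc_id}
    if not members:
        raise ValueError(f"{lnc_id!r} has no retained co-expression pairs")
    if lnc_id not in g.lnc_mi:
        raise KeyError(f"{lnc_id!r} absent from the triple network")
    lnc_partners = g.lnc_mi[lnc_id]
    mirnas: set[str] = set()
    mrna_edges: set[tuple[str, str]] = set()
    for mrna in sorted(members):
        shared = lnc_partners & g.mrna_mi.get(mrna, frozenset())
        mirnas |= shared
        mrna_edges |= {(mrna, mi) for mi in shared}
    lnc_edges = {(lnc_id, mi) for mi in mirnas}
    return CeRNAModule(lnc_id, members, mirnas, lnc_edges, mrna_edges)


def pairs_to_frame(pairs: list[CoexpressionPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [(cp.lnc_id, cp.mrna_id, cp.r, cp.p) for cp in pairs],
        columns=["lnc_id", "mrna_id", "r", "p"],
    )
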