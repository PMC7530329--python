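"""Global and DE triple networks and the hypergeometric ceRNA pairing test.

A lncRNA and an mRNA are candidate ceRNA partners when they share more
miRNAs than chance predicts.  With t miRNAs targeting the mRNA, n targeting
the lncRNA, r shared, and a universe of m miRNAs, the upper-tail probability

    P = 1 - sum_{i=0}^{r-1} C(t, i) C(m-t, n-i) / C(m, n)

is the probability of sharing at least r partners under random draws.
Pairs are scored over the DE triple network, Benjamini-Hochberg corrected,
and the significant pairs form the bipartite lncRNA-mRNA network (the
disease lncRNA-mRNA network, e.g. the LCLMN in lung cancer).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .datatypes import LNCRNA, MRNA, InteractionTable, TripleNetwork

PAIR_ALPHA = 0.01


@dataclass
class CeRNAPair:
    """One scored lncRNA-mRNA candidate with its shared-miRNA counts."""

    lnc_id: str
    mrna_id: str
    t: int  # miRNAs interacting with the mRNA
    n: int  # miRNAs interacting with the lncRNA
    r: int  # shared miRNAs
    m: int  # miRNA universe size
    p: float
    adjusted_p: float = float("nan")


def build_global_network(
    lnc_mi: InteractionTable, mrna_mi: InteractionTable
) -> TripleNetwork:
    """Merge the two bipartite tables into the global triple network."""
    if lnc_mi.gene_class != LNCRNA or mrna_mi.gene_class != MRNA:
        raise ValueError(
            "expected an lncRNA-miRNA table and an mRNA-miRNA table, got "
            f"{lnc_mi.gene_class!r} and {mrna_mi.gene_class!r}"
        )
    return TripleNetwork(lnc_mi.partners(), mrna_mi.partners())


def extract_de_subnetwork(
    g: TripleNetwork, de_lnc: set[str], de_mrna: set[str]
) -> TripleNetwork:
    """Restrict to DE lncRNA/mRNA nodes; miRNAs without edges drop out."""
    return TripleNetwork(
        {k: v for k, v in g.lnc_mi.items() if k in de_lnc},
        {k: v for k, v in g.mrna_mi.items() if k in de_mrna},
    )


def log_hypergeom_sf(t: int, n: int, r: int, m: int) -> float:
    """log P(X >= r) for X ~ Hypergeom(m, t, n), summed in log space."""
    if r == 0:
        return 0.0
    hi = min(t, n)
    lo = max(r, n - (m - t))  # need n - i <= m - t
    if lo > hi:
        return -np.inf
    i = np.arange(lo, hi + 1)
    log_terms = (
        gammaln(t + 1)
        - gammaln(i + 1)
        - gammaln(t - i + 1)
        + gammaln(m - t + 1)
        - gammaln(n - i + 1)
        - gammaln(m - t - (n - i) + 1)
        - (gammaln(m + 1) - gammaln(n + 1) - gammaln(m - n + 1))
    )
    return float(logsumexp(log_terms))


def hypergeom_pvalue(t: int, n: int, r: int, m: int) -> float:
    """Upper-tail shared-miRNA probability P(X >= r); exact, in [0, 1]."""
    for name, v in (("t", t), ("n", n), ("r", r), ("m", m)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    if r > min(t, n):
        raise ValueError(f"r={r} exceeds min(t={t}, n={n})")
    if t > m or n > m:
        raise ValueError(f"t={t} and n={n} must not exceed m={m}")
    return float(min(1.0, np.exp(log_hypergeom_sf(t, n, r, m))))


def score_cerna_pairs(
    de_net: TripleNetwork,
    m_universe: int | None = None,
    count_network: TripleNetwork | None = None,
) -> list[CeRNAPair]:
    """Score every DE lncRNA-mRNA pair sharing at least one miRNA.

    Partner counts t, n and the shared count r are taken from
    ``count_network`` when given (normally the global triple network, so the
    counts live in the same universe as m) and from ``de_net`` otherwise.
    ``m_universe`` defaults to the counting network's distinct-miRNA count.
    Pairs with r = 0 cannot be ceRNA partners (P = 1) and are not scored.
    Results are sorted by (p, lnc_id, mrna_id) for reproducibility.
    """
    if not de_net.lnc_mi or not de_net.mrna_mi:
        raise ValueError("DE network has no lncRNA-mRNA candidates to score")
    counts = count_network if count_network is not None else de_net
    m = m_universe if m_universe is not None else len(counts.mirna_nodes)

    pairs: list[CeRNAPair] = []
    for lnc in sorted(de_net.lnc_mi):
        lnc_partners = counts.lnc_mi.get(lnc, frozenset())
        n = len(lnc_partners)
        if n > m:
            raise ValueError(f"m_universe={m} smaller than n={n} for {lnc}")
        for mrna in sorted(de_net.mrna_mi):
            mrna_partners = counts.mrna_mi.get(mrna, frozenset())
            t = len(mrna_partners)
            if t > m:
                raise ValueError(f"m_universe={m} smaller than t={t} for {mrna}")
            r = len(lnc_partners & mrna_partners)
            if r == 0:
                continue
            p = hypergeom_pvalue(t, n, r, m)
            pairs.append(CeRNAPair(lnc, mrna, t, n, r, m, p))

    if pairs:
        adjusted = multipletests([pp.p for pp in pairs], method="fdr_bh")[1]
        for pp, ap in zip(pairs, adjusted):
            pp.adjusted_p = float(ap)
    pairs.sort(key=lambda pp: (pp.p, pp.lnc_id, pp.mrna_id))
    return pairs


def build_lclmn(pairs: list[CeRNAPair], alpha: float = PAIR_ALPHA) -> nx.Graph:
    """Bipartite lncRNA-mRNA graph of pairs with adjusted_p < alpha.

    Node attribute ``node_class`` is ``lncRNA`` or ``mRNA``; every edge
    carries the full pair record (t, n, r, m, p, adjusted_p).  Nodes appear
    only when they touch at least one significant edge.
    """
    g = nx.Graph()
    for pp in pairs:
        if pp.adjusted_p < alpha:
            g.add_node(pp.lnc_id, node_class=LNCRNA)
            g.add_node(pp.mrna_id, node_class=MRNA)
            g.add_edge(
                pp.lnc_id,
                pp.mrna_id,
                t=pp.t,
                n=pp.n,
                r=pp.r,
                m=pp.m,
                p=pp.p,
                adjusted_p=pp.adjusted_p,
            )
    g.graph["n_lnc"] = sum(
        1 for _n, c in g.nodes(data="node_class") if c == LNCRNA
    )
    g.graph["n_mrna"] = sum(1 for _n, c in g.nodes(data="node_class") if c == MRNA)
    g.graph["n_edges"] = g.number_of_edges()
    return g


def pairs_to_frame(pairs: list[CeRNAPair]) -> pd.DataFrame:
    """Tabular view of scored pairs (columns mirror the on-disk schema)."""
    return pd.DataFrame(
        [
            (pp.lnc_id, pp.mrna_id, pp.t, pp.n, pp.r, pp.m, pp.p, pp.adjusted_p)
            for pp in pairs
        ],
        columns=["lnc_id", "mrna_id", "t", "n", "r", "m", "p", "adjusted_p"],
    )
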