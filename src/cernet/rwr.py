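"""Random walk with restart (RWR) gene prioritization with permutation p-values.

The walker iterates

    p_{t+1} = (1 - r) W p_t + r p_0

where W is the column-normalized adjacency matrix, p_0 puts mass 1/|seeds|
on each seed node, and r is the restart probability (default 0.5).
Iteration stops when the L1 difference between successive vectors falls
below ``tol`` (default 1e-10); the fixed point p_inf scores every node's
proximity to the seed set.

Significance of each candidate lncRNA score is empirical: pseudo-seed sets
of the same size are drawn uniformly without replacement from the mRNA
nodes (keeping the graph, hence its topology, fixed), the walk is rerun,
and perm_p = m / n where m counts permutations whose score strictly exceeds
the observed one over n permutations.  A degree-preserving edge-rewiring
null is available as an alternative randomization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import LNCRNA, MRNA


@dataclass
class RWRConfig:
    """Parameters of the walk and of its permutation test."""

    seed_genes: set[str] = field(default_factory=set)
    restart_prob: float = 0.5
    tol: float = 1e-10
    max_iter: int = 10_000
    n_perm: int = 5000
    rng_seed: int = 0
    perm_method: str = "seed_resample"  # or "rewire"

    def __post_init__(self) -> None:
        if not 0.0 < self.restart_prob < 1.0:
            raise ValueError("restart_prob must be in (0, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.perm_method not in ("seed_resample", "rewire"):
            raise ValueError(f"unknown perm_method {self.perm_method!r}")


@dataclass
class RWRResult:
    """Steady-state probabilities plus per-candidate empirical significance.

    ``scores`` is indexed by node (columns ``node_class``, ``steady_prob``);
    ``candidates`` holds the lncRNA rows with ``m_exceed`` and ``perm_p``,
    sorted ascending by (perm_p, node id).
    """

    scores: pd.DataFrame
    candidates: pd.DataFrame
    n_perm: int


def column_normalize(g: nx.Graph) -> tuple[np.ndarray, list[str]]:
    """Column-stochastic transition matrix W and its node ordering.

    Isolated nodes are dropped with a warning first; W[i, j] = 1/degree(j)
    for every edge (i, j), so each column sums to exactly 1.
    """
    isolates = sorted(nx.isolates(g))
    if isolates:
        warnings.warn(f"dropping {len(isolates)} isolated node(s) from the walk")
        g = g.subgraph([n for n in g.nodes if n not in set(isolates)])
    nodes = sorted(g.nodes)
    if not nodes:
        raise ValueError("graph has no connected nodes")
    index = {n: i for i, n in enumerate(nodes)}
    W = np.zeros((len(nodes), len(nodes)))
    deg = dict(g.degree())
    for u, v in g.edges:
        W[index[u], index[v]] = 1.0 / deg[v]
        W[index[v], index[u]] = 1.0 / deg[u]
    if not np.allclose(W.sum(axis=0), 1.0):
        raise RuntimeError("column normalization failed (internal inconsistency)")
    return W, nodes


def _seed_vector(nodes: list[str], seed_genes: set[str]) -> np.ndarray:
    present = sorted(set(seed_genes) & set(nodes))
    dropped = set(seed_genes) - set(present)
    if dropped:
        warnings.warn(
            f"{len(dropped)} seed gene(s) not in the network were dropped: "
            f"{sorted(dropped)[:8]}"
        )
    if not present:
        raise ValueError("no seed gene is present in the network")
    p0 = np.zeros(len(nodes))
    index = {n: i for i, n in enumerate(nodes)}
    for s in present:
        p0[index[s]] = 1.0 / len(present)
    return p0


def rwr_propagate(
    W: np.ndarray,
    nodes: list[str],
    seed_genes: set[str],
    config: RWRConfig | None = None,
) -> pd.Series:
    """Iterate the restart walk to its fixed point; returns p_inf by node."""
    cfg = config or RWRConfig()
    p0 = _seed_vector(nodes, seed_genes)
    r = cfg.restart_prob
    p = p0.copy()
    for _ in range(cfg.max_iter):
        p_next = (1.0 - r) * (W @ p) + r * p0
        delta = np.abs(p_next - p).sum()
        p = p_next
        if delta < cfg.tol:
            return pd.Series(p, index=nodes, name="steady_prob")
    raise RuntimeError(
        f"RWR did not converge in {cfg.max_iter} iterations "
        f"(last L1 delta {delta:.3e}, tol {cfg.tol:.1e})"
    )


def _rewire_bipartite(g: nx.Graph, rng: np.random.Generator) -> nx.Graph:
    """Degree-preserving rewiring that keeps the lncRNA/mRNA bipartition."""
    h = g.copy()
    edges = [tuple(e) for e in h.edges]
    n_swaps = 10 * len(edges)
    classes = dict(h.nodes(data="node_class"))
    for _ in range(n_swaps):
        i, j = rng.integers(len(edges)), rng.integers(len(edges))
        if i == j:
            continue
        (a, b), (c, d) = edges[i], edges[j]
        # orient both edges lnc -> mrna before swapping partners
        if classes.get(a) == MRNA:
            a, b = b, a
        if classes.get(c) == MRNA:
            c, d = d, c
        if a == c or b == d or h.has_edge(a, d) or h.has_edge(c, b):
            continue
        h.remove_edge(*edges[i])
        h.remove_edge(*edges[j])
        h.add_edge(a, d)
        h.add_edge(c, b)
        edges[i], edges[j] = (a, d), (c, b)
    return h


def rwr_permutation_p(g: nx.Graph, config: RWRConfig) -> RWRResult:
    """Observed walk plus an empirical permutation p-value per candidate lncRNA.

    With ``perm_method='seed_resample'`` (default) each permutation draws
    |seeds| pseudo-seeds uniformly without replacement from the graph's mRNA
    nodes and reruns the walk on the fixed graph; with ``'rewire'`` the graph
    is degree-preservingly rewired instead and the original seeds reused.
    perm_p of a candidate is the fraction of permutations whose score
    strictly exceeds the observed score.
    """
    W, nodes = column_normalize(g)
    classes = dict(g.nodes(data="node_class"))
    observed = rwr_propagate(W, nodes, config.seed_genes, config)

    candidates = [n for n in nodes if classes.get(n) == LNCRNA]
    mrna_nodes = [n for n in nodes if classes.get(n) == MRNA]
    effective_seeds = sorted(set(config.seed_genes) & set(nodes))
    n_seeds = len(effective_seeds)
    if config.perm_method == "seed_resample" and len(mrna_nodes) < n_seeds:
        raise ValueError(
            f"cannot draw {n_seeds} pseudo-seeds from {len(mrna_nodes)} mRNA nodes"
        )

    rng = np.random.default_rng(config.rng_seed)
    obs = observed.loc[candidates].to_numpy() if candidates else np.empty(0)
    m_exceed = np.zeros(len(candidates), dtype=int)
    for _ in range(config.n_perm):
        if config.perm_method == "seed_resample":
            pseudo = set(rng.choice(mrna_nodes, size=n_seeds, replace=False))
            perm = rwr_propagate(W, nodes, pseudo, config)
        else:
            h = _rewire_bipartite(g, rng)
            Wp, nodes_p = column_normalize(h)
            perm = rwr_propagate(Wp, nodes_p, set(effective_seeds), config)
        if candidates:
            m_exceed += perm.loc[candidates].to_numpy() > obs

    scores = pd.DataFrame(
        {"node_class": pd.Series(classes), "steady_prob": observed}
    ).loc[nodes]
    cand = pd.DataFrame(
        {
            "node_class": [classes.get(n) for n in candidates],
            "steady_prob": obs,
            "m_exceed": m_exceed,
            "perm_p": m_exceed / config.n_perm,
        },
        index=pd.Index(candidates, name="node"),
    ).sort_values(["perm_p", "node"], kind="mergesort")
    return RWRResult(scores, cand, config.n_perm)


def solve_fixed_point(
    W: np.ndarray, nodes: list[str], seed_genes: set[str], restart_prob: float = 0.5
) -> pd.Series:
    """Direct linear solve of (I - (1-r) W) p = r p_0 (reference route)."""
    p0 = _seed_vector(nodes, seed_genes)
    A = np.eye(len(nodes)) - (1.0 - restart_prob) * W
    p = np.linalg.solve(A, restart_prob * p0)
    return pd.Series(p, index=nodes, name="steady_prob")
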