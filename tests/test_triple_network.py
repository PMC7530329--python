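"""Network assembly and the shared-miRNA hypergeometric test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cernet.datatypes import InteractionTable, TripleNetwork
from cernet.synthetic_data import SimulationConfig, simulate_expression, simulate_interactions
from cernet.triple_network import (
    build_global_network,
    build_lclmn,
    extract_de_subnetwork,
    hypergeom_pvalue,
    pairs_to_frame,
    score_cerna_pairs,
)


def table(rows, gene_class):
    return InteractionTable(
        pd.DataFrame(rows, columns=["gene_id", "mirna_id"]), gene_class
    )


def enumeration_pvalue(t, n, r, m):
    """Brute force: fraction of n-subsets of an m-universe with >= r hits
    among the mRNA's t partners."""
    universe = range(m)
    targets = set(range(t))
    hits = total = 0
    for subset in itertools.combinations(universe, n):
        total += 1
        if len(targets & set(subset)) >= r:
            hits += 1
    return hits / total


class TestBuildNetworks:
    def test_minimal_merge(self):
        g = build_global_network(
            table([("L1", "mi1")], "lncRNA"), table([("G1", "mi2")], "mRNA")
        )
        assert g.summary() == {
            "n_lnc": 1, "n_mrna": 1, "n_mirna": 2,
            "n_lnc_mi_edges": 1, "n_mrna_mi_edges": 1,
        }

    def test_duplicate_rows_do_not_add_edges(self):
        g = build_global_network(
            table([("L1", "mi1")] * 3, "lncRNA"), table([("G1", "mi1")], "mRNA")
        )
        assert g.n_lnc_mi_edges == 1

    def test_gene_class_collision_is_an_error(self):
        with pytest.raises(ValueError, match="both lncRNA and mRNA"):
            build_global_network(
                table([("X", "mi1")], "lncRNA"), table([("X", "mi2")], "mRNA")
            )

    def test_synthetic_counts_match_generator_bookkeeping(self):
        cfg = SimulationConfig(seed=12)
        _, truth = simulate_expression(cfg)
        lnc_mi, mrna_mi = simulate_interactions(cfg, truth)
        g = build_global_network(lnc_mi, mrna_mi)
        assert g.n_lnc_mi_edges == lnc_mi.n_edges
        assert g.n_mrna_mi_edges == mrna_mi.n_edges
        assert g.lnc_nodes == lnc_mi.genes
        assert g.mirna_nodes == lnc_mi.mirnas | mrna_mi.mirnas

    def test_de_restriction_identity_and_empty(self):
        g = build_global_network(
            table([("L1", "mi1"), ("L2", "mi2")], "lncRNA"),
            table([("G1", "mi1")], "mRNA"),
        )
        same = extract_de_subnetwork(g, g.lnc_nodes, g.mrna_nodes)
        assert same.summary() == g.summary()
        empty = extract_de_subnetwork(g, set(), set())
        assert empty.summary()["n_mirna"] == 0

    def test_de_restriction_hand_case(self):
        g = build_global_network(
            table([("L1", "mi1"), ("L1", "mi2"), ("L1", "mi3"), ("L2", "mi4")],
                  "lncRNA"),
            table([("G1", "mi1")], "mRNA"),
        )
        sub = extract_de_subnetwork(g, {"L1"}, set())
        assert sub.summary() == {
            "n_lnc": 1, "n_mrna": 0, "n_mirna": 3,
            "n_lnc_mi_edges": 3, "n_mrna_mi_edges": 0,
        }


class TestHypergeomPvalue:
    def test_zero_overlap_gives_one(self):
        assert hypergeom_pvalue(3, 2, 0, 10) == 1.0

    def test_small_case_by_enumeration(self):
        # 3 of 10 two-subsets of a 5-universe contain >= 2 of 3 targets
        assert hypergeom_pvalue(3, 2, 2, 5) == pytest.approx(0.3, abs=1e-12)

    def test_saturated_mrna_always_overlaps(self):
        assert hypergeom_pvalue(7, 4, 4, 7) == pytest.approx(1.0)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_pvalue(3, 2, 3, 10)  # r > min(t, n)
        with pytest.raises(ValueError):
            hypergeom_pvalue(11, 2, 1, 10)  # t > m
        with pytest.raises(ValueError):
            hypergeom_pvalue(3, -1, 0, 10)

    @pytest.mark.parametrize("m", [5, 8])
    def test_matches_exhaustive_enumeration(self, m):
        for t in range(m + 1):
            for n in range(m + 1):
                for r in range(min(t, n) + 1):
                    assert hypergeom_pvalue(t, n, r, m) == pytest.approx(
                        enumeration_pvalue(t, n, r, m), abs=1e-12
                    )

    def test_matches_scipy_survival_function(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            m = int(rng.integers(1, 400))
            t = int(rng.integers(0, m + 1))
            n = int(rng.integers(0, m + 1))
            r = int(rng.integers(0, min(t, n) + 1))
            assert hypergeom_pvalue(t, n, r, m) == pytest.approx(
                float(stats.hypergeom.sf(r - 1, m, t, n)), rel=1e-10, abs=1e-12
            )

    def test_monotone_in_r_and_t(self):
        ps = [hypergeom_pvalue(10, 8, r, 40) for r in range(9)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        pt = [hypergeom_pvalue(t, 8, 3, 40) for t in range(3, 41)]
        assert all(a <= b + 1e-12 for a, b in zip(pt, pt[1:]))

    def test_complement_identity_against_cdf(self):
        rng = np.random.default_rng(14)
        for _ in range(100):
            m = int(rng.integers(2, 200))
            t = int(rng.integers(1, m + 1))
            n = int(rng.integers(1, m + 1))
            r = int(rng.integers(1, min(t, n) + 1))
            upper = hypergeom_pvalue(t, n, r, m)
            lower = float(stats.hypergeom.cdf(r - 1, m, t, n))
            assert upper + lower == pytest.approx(1.0, abs=1e-9)


class TestScorePairs:
    def _net(self):
        lnc = table([("L1", "mi1"), ("L1", "mi2"), ("L2", "mi9")], "lncRNA")
        mrna = table([("G1", "mi1"), ("G1", "mi2"), ("G2", "mi8")], "mRNA")
        return build_global_network(lnc, mrna)

    def test_disjoint_pair_not_scored(self):
        g = self._net()
        pairs = score_cerna_pairs(g, m_universe=10)
        scored = {(p.lnc_id, p.mrna_id) for p in pairs}
        assert ("L1", "G2") not in scored and ("L2", "G1") not in scored
        assert ("L1", "G1") in scored

    def test_single_pair_bh_is_identity(self):
        g = build_global_network(
            table([("L1", "mi1")], "lncRNA"), table([("G1", "mi1")], "mRNA")
        )
        (pair,) = score_cerna_pairs(g, m_universe=20)
        assert pair.adjusted_p == pytest.approx(pair.p)
        assert (pair.t, pair.n, pair.r, pair.m) == (1, 1, 1, 20)

    def test_m_universe_too_small_is_an_error(self):
        g = self._net()
        with pytest.raises(ValueError, match="m_universe"):
            score_cerna_pairs(g, m_universe=1)

    def test_bh_matches_stepup_reference(self):
        cfg = SimulationConfig(seed=15)
        _, truth = simulate_expression(cfg)
        g = build_global_network(*simulate_interactions(cfg, truth))
        pairs = score_cerna_pairs(g)
        p = np.array([pp.p for pp in pairs])
        # step-up reference: sort, scale by n/rank, cumulative min from the top
        order = np.argsort(p, kind="mergesort")
        scaled = p[order] * len(p) / np.arange(1, len(p) + 1)
        ref = np.minimum.accumulate(scaled[::-1])[::-1]
        ref = np.minimum(ref, 1.0)
        adj = np.array([pp.adjusted_p for pp in pairs])[order]
        assert np.allclose(adj, ref)
        assert (adj >= p[order] - 1e-15).all()

    def test_planted_pairs_score_lower_than_background(self):
        cfg = SimulationConfig(
            shared_mirna_boost=8, background_degree=5.0, n_mirna=200, seed=16
        )
        _, truth = simulate_expression(cfg)
        g = build_global_network(*simulate_interactions(cfg, truth))
        de_net = extract_de_subnetwork(g, truth.de_lnc_ids, truth.de_mrna_ids)
        pairs = score_cerna_pairs(de_net, count_network=g)
        planted = [p.adjusted_p for p in pairs
                   if (p.lnc_id, p.mrna_id) in truth.planted_pairs]
        rest = [p.adjusted_p for p in pairs
                if (p.lnc_id, p.mrna_id) not in truth.planted_pairs]
        assert planted and rest
        assert np.mean(planted) < np.mean(rest)


class TestBuildLclmn:
    def _pairs(self):
        g = build_global_network(
            table([("L1", "mi1"), ("L2", "mi2")], "lncRNA"),
            table([("G1", "mi1"), ("G2", "mi2")], "mRNA"),
        )
        return score_cerna_pairs(g, m_universe=50)

    def test_no_significant_pairs_gives_empty_graph(self):
        g = build_lclmn(self._pairs(), alpha=1e-6)
        assert g.number_of_nodes() == 0 and g.number_of_edges() == 0

    def test_vacuous_alpha_admits_every_pair(self):
        pairs = self._pairs()
        g = build_lclmn(pairs, alpha=1.0 + 1e-9)
        assert g.number_of_edges() == len(pairs)
        # no isolated nodes by construction
        assert all(d > 0 for _n, d in g.degree())

    def test_edge_attributes_carry_pair_record(self):
        pairs = self._pairs()
        g = build_lclmn(pairs, alpha=1.1)
        attrs = g.edges["L1", "G1"]
        assert {"t", "n", "r", "m", "p", "adjusted_p"} <= set(attrs)

    def test_frame_round_trip_columns(self):
        df = pairs_to_frame(self._pairs())
        assert list(df.columns) == ["lnc_id", "mrna_id", "t", "n", "r", "m", "p",
                                    "adjusted_p"]
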