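"""Pearson screening of network edges and ceRNA module extraction."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats

from cernet.coexpression import (
    coexpressed_pairs,
    extract_module,
    pearson_with_p,
)
from cernet.datatypes import InteractionTable
from cernet.synthetic_data import SimulationConfig, simulate_expression, simulate_interactions
from cernet.triple_network import (
    build_global_network,
    build_lclmn,
    extract_de_subnetwork,
    score_cerna_pairs,
)
from tests.conftest import make_matrix


class TestPearsonWithP:
    def test_exact_linearity(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, p = pearson_with_p(x, 2 * x + 1)
        assert r == pytest.approx(1.0) and p == 0.0
        r, _ = pearson_with_p(x, -x)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_case(self):
        r, _p = pearson_with_p([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8, abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(19)
        for n in (5, 10, 50):
            x, y = rng.normal(size=(2, n))
            r, p = pearson_with_p(x, y)
            ref = stats.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_constant_vector_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_with_p([1, 1, 1], [1, 2, 3])

    def test_length_mismatch_and_short_input(self):
        with pytest.raises(ValueError, match="mismatch"):
            pearson_with_p([1, 2, 3], [1, 2])
        with pytest.raises(ValueError, match="at least 3"):
            pearson_with_p([1, 2], [1, 2])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        hnp.arrays(np.float64, 8, elements=st.floats(-50, 50)),
        hnp.arrays(np.float64, 8, elements=st.floats(-50, 50)),
    )
    def test_symmetry_and_covariance_oracle(self, x, y):
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        r_xy, p_xy = pearson_with_p(x, y)
        r_yx, p_yx = pearson_with_p(y, x)
        assert r_xy == pytest.approx(r_yx, abs=1e-12)
        assert p_xy == pytest.approx(p_yx, abs=1e-12)
        # from-scratch covariance/variance oracle
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        oracle = cov / (x.std() * y.std())
        assert r_xy == pytest.approx(oracle, abs=1e-9)
        # invariance under positive affine maps
        r_aff, _ = pearson_with_p(3.0 * x + 2.0, y)
        assert r_aff == pytest.approx(r_xy, abs=1e-9)


def simulated_lclmn(cfg):
    matrix, truth = simulate_expression(cfg)
    g = build_global_network(*simulate_interactions(cfg, truth))
    de_net = extract_de_subnetwork(g, truth.de_lnc_ids, truth.de_mrna_ids)
    pairs = score_cerna_pairs(de_net, count_network=g)
    return matrix, truth, g, build_lclmn(pairs)


class TestCoexpressedPairs:
    def test_threshold_is_strictly_greater_than(self):
        # a pair whose correlation equals r_min exactly must be excluded
        g = nx.Graph()
        g.add_node("L1", node_class="lncRNA")
        g.add_node("G1", node_class="mRNA")
        g.add_edge("L1", "G1")
        rng = np.random.default_rng(25)
        m = make_matrix(rng.normal(size=(2, 10)))
        m.values.index = ["L1", "G1"]
        r, p = pearson_with_p(m.values.loc["L1"], m.values.loc["G1"])
        assert coexpressed_pairs(g, m, r_min=r, p_max=1.0) == []
        if r > 0:  # nudging the threshold below r admits the pair
            kept = coexpressed_pairs(g, m, r_min=r - 1e-12, p_max=1.0)
            assert [(cp.lnc_id, cp.mrna_id) for cp in kept] == [("L1", "G1")]

    def test_empty_network_yields_empty_list(self):
        m = make_matrix(np.zeros((2, 3)))
        assert coexpressed_pairs(nx.Graph(), m) == []

    def test_missing_expression_rows_are_skipped_with_warning(self):
        g = nx.Graph()
        g.add_node("L1", node_class="lncRNA")
        g.add_node("MISSING", node_class="mRNA")
        g.add_edge("L1", "MISSING")
        m = make_matrix(np.random.default_rng(0).normal(size=(1, 5)))
        m.values.index = ["L1"]
        with pytest.warns(UserWarning, match="missing from the expression"):
            assert coexpressed_pairs(g, m) == []

    def test_recovers_planted_coexpression(self):
        cfg = SimulationConfig(coexpr_r=0.9, n_pairs_samples=20,
                               shared_mirna_boost=8, n_mirna=200, seed=23)
        matrix, truth, _g, lclmn = simulated_lclmn(cfg)
        planted_edges = {e for e in truth.planted_pairs if lclmn.has_edge(*e)}
        assert planted_edges  # the planted pairs reach the network
        retained = {
            (cp.lnc_id, cp.mrna_id) for cp in coexpressed_pairs(lclmn, matrix)
        }
        assert planted_edges <= retained

    def test_independent_noise_rarely_passes_joint_threshold(self):
        rng = np.random.default_rng(24)
        g = nx.Graph()
        n_edges = 200
        for i in range(n_edges):
            g.add_node(f"L{i}", node_class="lncRNA")
            g.add_node(f"G{i}", node_class="mRNA")
            g.add_edge(f"L{i}", f"G{i}")
        m = make_matrix(rng.normal(size=(2 * n_edges, 20)))
        m.values.index = [f"L{i}" for i in range(n_edges)] + [
            f"G{i}" for i in range(n_edges)
        ]
        retained = coexpressed_pairs(g, m)
        assert len(retained) / n_edges <= 0.05


class TestExtractModule:
    def _triple(self):
        lnc = InteractionTable(
            pd.DataFrame(
                [("L1", "mi1"), ("L1", "mi2"), ("L1", "mi3")],
                columns=["gene_id", "mirna_id"],
            ),
            "lncRNA",
        )
        mrna = InteractionTable(
            pd.DataFrame(
                [("G1", "mi2"), ("G1", "mi3"), ("G1", "mi4"), ("G2", "mi3"),
                 ("G2", "mi9")],
                columns=["gene_id", "mirna_id"],
            ),
            "mRNA",
        )
        return build_global_network(lnc, mrna)

    def _pair(self, lnc, mrna):
        from cernet.coexpression import CoexpressionPair

        return CoexpressionPair(lnc, mrna, 0.9, 1e-6)

    def test_hand_built_intersection(self):
        module = extract_module("L1", [self._pair("L1", "G1")], self._triple())
        assert module.mirna_ids == {"mi2", "mi3"}
        assert module.mrna_ids == {"G1"}
        assert ("L1", "mi2") in module.lnc_mi_edges
        assert ("G1", "mi4") not in module.mrna_mi_edges

    def test_union_of_per_mrna_intersections(self):
        module = extract_module(
            "L1", [self._pair("L1", "G1"), self._pair("L1", "G2")], self._triple()
        )
        assert module.mirna_ids == {"mi2", "mi3"}
        assert ("G2", "mi3") in module.mrna_mi_edges
        assert ("G2", "mi9") not in module.mrna_mi_edges

    def test_module_soundness_invariant(self):
        g = self._triple()
        module = extract_module(
            "L1", [self._pair("L1", "G1"), self._pair("L1", "G2")], g
        )
        for mi in module.mirna_ids:
            assert mi in g.lnc_mi["L1"]
            assert any(mi in g.mrna_mi[m] for m in module.mrna_ids)

    def test_no_retained_pairs_is_an_error(self):
        with pytest.raises(ValueError, match="no retained"):
            extract_module("L1", [], self._triple())

    def test_unknown_lncrna_is_an_error(self):
        with pytest.raises(KeyError, match="absent"):
            extract_module("L9", [self._pair("L9", "G1")], self._triple())

    def test_module_graph_has_both_layers(self):
        module = extract_module("L1", [self._pair("L1", "G1")], self._triple())
        g = module.to_graph()
        assert g.nodes["L1"]["node_class"] == "lncRNA"
        assert g.has_edge("L1", "mi2") and g.has_edge("G1", "mi2")
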