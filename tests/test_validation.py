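"""Connectance, correlation networks, scored-edge filtering, co-expression tests."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from grnprune.errors import ConfigurationError
from grnprune.model import ExpressionMatrix, InteractionNetwork, RegulatoryNetwork
from grnprune.validation import (
    coexpression_comparison,
    compare_connectance,
    connectance,
    correlation_network,
    filter_scored_edges,
    welch_t,
)


class TestConnectance:
    def test_direct_formula(self):
        ppi = InteractionNetwork([("T1", "T2"), ("T2", "T3")])
        assert connectance({"T1", "T2", "T3"}, ppi) == pytest.approx(2 / 3)

    def test_clique_reaches_one(self):
        tfs = ["a", "b", "c", "d"]
        ppi = InteractionNetwork(list(combinations(tfs, 2)))
        assert connectance(tfs, ppi) == 1.0

    def test_single_regulator_undefined(self):
        assert connectance({"T1"}, InteractionNetwork([])) is None
        assert connectance(set(), InteractionNetwork([])) is None

    def test_missing_regulators_stay_in_denominator(self):
        ppi = InteractionNetwork([("T1", "T2")], nodes=["T1", "T2"])
        # T9 not in the ppi at all: 1 hit of 3 possible pairs
        assert connectance({"T1", "T2", "T9"}, ppi) == pytest.approx(1 / 3)

    def test_brute_force_enumeration_small(self):
        """rho equals hand count for every regulator pair/triple over every
        ppi subgraph of a 4-TF universe (exhaustive at small scale)."""
        tfs = ["A", "B", "C", "D"]
        all_pairs = list(combinations(tfs, 2))
        for mask in range(2 ** len(all_pairs)):
            edges = [p for i, p in enumerate(all_pairs) if mask >> i & 1]
            ppi = InteractionNetwork(edges, nodes=tfs)
            for size in (2, 3, 4):
                for regs in combinations(tfs, size):
                    hits = sum(
                        1 for a, b in combinations(sorted(regs), 2)
                        if (a, b) in ppi.edges or (b, a) in ppi.edges
                    )
                    expected = hits / (size * (size - 1) / 2)
                    rho = connectance(regs, ppi)
                    assert rho == pytest.approx(expected)
                    assert 0.0 <= rho <= 1.0


class TestCompareConnectance:
    def test_hand_example_better(self):
        ppi = InteractionNetwork([("A", "B")])
        before = RegulatoryNetwork([("A", "g"), ("B", "g"), ("C", "g")])
        after = RegulatoryNetwork([("A", "g"), ("B", "g")])
        rep = compare_connectance(before, after, ppi)
        assert rep.per_gene["g"] == (pytest.approx(1 / 3), 1.0)
        assert (rep.better, rep.worse, rep.equal) == (1.0, 0.0, 0.0)

    def test_identical_networks_all_equal(self):
        ppi = InteractionNetwork([("A", "B")])
        net = RegulatoryNetwork([("A", "g"), ("B", "g"), ("A", "h"), ("B", "h")])
        rep = compare_connectance(net, net, ppi)
        assert rep.equal == 1.0 and rep.n_comparable == 2

    def test_undefined_genes_counted_separately(self):
        ppi = InteractionNetwork([("A", "B")])
        before = RegulatoryNetwork([("A", "g"), ("B", "g")])
        after = RegulatoryNetwork([("A", "g")])  # single regulator -> undefined
        rep = compare_connectance(before, after, ppi)
        assert rep.n_comparable == 0 and rep.n_undefined == 1

    def test_after_targets_must_be_subset(self):
        with pytest.raises(ValueError):
            compare_connectance(
                RegulatoryNetwork([("A", "g")]),
                RegulatoryNetwork([("A", "h")]),
                InteractionNetwork([]),
            )

    def test_fractions_match_brute_force_tally(self, rng):
        tfs = [f"T{i}" for i in range(8)]
        ppi_edges = [p for p in combinations(tfs, 2) if rng.random() < 0.3]
        ppi = InteractionNetwork(ppi_edges, nodes=tfs)
        before_edges, after_edges = set(), set()
        for gi in range(20):
            gene = f"g{gi}"
            regs = rng.choice(8, size=rng.integers(2, 6), replace=False)
            for r in regs:
                before_edges.add((tfs[r], gene))
            kept = regs[: rng.integers(1, len(regs) + 1)]
            for r in kept:
                after_edges.add((tfs[r], gene))
        before = RegulatoryNetwork(before_edges)
        after = RegulatoryNetwork(after_edges)
        rep = compare_connectance(before, after, ppi)

        # independent tally straight from the definition
        nb = nw = ne = nu = 0
        for gene in after.target_ids:
            def rho(net):
                regs = sorted(net.regulators_of(gene))
                if len(regs) < 2:
                    return None
                hits = sum(1 for a, b in combinations(regs, 2) if ppi.has_edge(a, b))
                return hits / (len(regs) * (len(regs) - 1) / 2)
            rb, ra = rho(before), rho(after)
            if rb is None or ra is None:
                nu += 1
            elif ra > rb:
                nb += 1
            elif ra < rb:
                nw += 1
            else:
                ne += 1
        total = nb + nw + ne
        assert rep.n_undefined == nu
        assert rep.better == pytest.approx(nb / total)
        assert rep.worse == pytest.approx(nw / total)
        assert rep.equal == pytest.approx(ne / total)
        assert rep.better + rep.worse + rep.equal == pytest.approx(1.0)


def _expr(rows: dict[str, np.ndarray]) -> ExpressionMatrix:
    mat = np.vstack(list(rows.values()))
    mat = mat - mat.min()
    return ExpressionMatrix.from_arrays(
        list(rows), [f"s{i}" for i in range(mat.shape[1])], mat
    )


class TestCorrelationNetwork:
    def test_perfectly_correlated_pair(self, rng):
        a = rng.standard_normal(100)
        expr = _expr({"T1": a, "T2": 2 * a + 5})
        net = correlation_network(expr, {"T1", "T2"}, 0.85)
        assert net.edges == {("T1", "T2")}

    def test_anticorrelated_pair_excluded_by_positive_convention(self, rng):
        a = rng.standard_normal(100)
        expr = _expr({"T1": a, "T2": -a})
        assert len(correlation_network(expr, {"T1", "T2"}, 0.25)) == 0
        assert len(correlation_network(expr, {"T1", "T2"}, 0.25, absolute=True)) == 1

    def test_edges_match_pairwise_oracle(self, rng):
        base = rng.standard_normal(200)
        rows = {
            f"T{i}": w * base + (1 - w) * rng.standard_normal(200)
            for i, w in enumerate([0.9, 0.7, 0.5, 0.2, 0.0])
        }
        expr = _expr(rows)
        for threshold in (0.25, 0.45, 0.65, 0.85):
            net = correlation_network(expr, rows.keys(), threshold)
            expected = set()
            for a, b in combinations(sorted(rows), 2):
                r = np.corrcoef(rows[a], rows[b])[0, 1]
                if r >= threshold:
                    expected.add((a, b))
            assert net.edges == expected

    def test_nodes_are_tfs_with_at_least_one_edge(self, rng):
        a = rng.standard_normal(100)
        expr = _expr({"T1": a, "T2": a + 0.01 * rng.standard_normal(100),
                      "T3": rng.standard_normal(100)})
        net = correlation_network(expr, {"T1", "T2", "T3"}, 0.85)
        assert net.nodes == {"T1", "T2"}

    def test_zero_variance_tf_excluded_with_warning(self, rng):
        expr = _expr({"T1": rng.standard_normal(50), "T2": np.full(50, 3.0)})
        with pytest.warns(UserWarning, match="zero-variance"):
            net = correlation_network(expr, {"T1", "T2"}, 0.25)
        assert len(net) == 0

    def test_invariant_to_common_sample_scaling(self, rng):
        rows = {f"T{i}": np.abs(rng.standard_normal(80)) + 1 for i in range(4)}
        expr1 = _expr(rows)
        scale = 3.5
        expr2 = ExpressionMatrix(expr1.data * scale)
        n1 = correlation_network(expr1, rows.keys(), 0.25)
        n2 = correlation_network(expr2, rows.keys(), 0.25)
        assert n1.edges == n2.edges


class TestFilterScoredEdges:
    def frame(self):
        return pd.DataFrame(
            {
                "protein1": ["A", "A", "B"],
                "protein2": ["B", "C", "C"],
                "combined_score": [0.8, 0.499, 0.95],
                "textmining": [0.61, 0.6, 0.2],
            }
        )

    def test_boundary_kept_below_dropped(self):
        net = filter_scored_edges(self.frame(), "combined_score", 0.8)
        assert net.edges == {("A", "B"), ("B", "C")}
        net = filter_scored_edges(self.frame(), "combined_score", 0.5)
        assert ("A", "C") not in net.edges

    def test_alternate_evidence_channel(self):
        net = filter_scored_edges(self.frame(), "textmining", 0.6)
        assert net.edges == {("A", "B"), ("A", "C")}  # 0.6 boundary kept

    def test_thousand_scale_rescaled(self):
        df = self.frame()
        df["combined_score"] = [800, 499, 950]
        net = filter_scored_edges(df, "combined_score", 0.8)
        assert net.edges == {("A", "B"), ("B", "C")}

    def test_unknown_field_lists_available(self):
        with pytest.raises(ConfigurationError, match="textmining"):
            filter_scored_edges(self.frame(), "nope", 0.5)


class TestCoexpression:
    def test_welch_matches_textbook_formula(self):
        a = np.array([0.4, 0.5, 0.6])
        b = np.array([0.1, 0.2, 0.3])
        t, p = welch_t(a, b)
        # independent closed-form computation
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se = np.sqrt(va / len(a) + vb / len(b))
        t_expected = (a.mean() - b.mean()) / se
        df = (va / len(a) + vb / len(b)) ** 2 / (
            (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1)
        )
        from scipy.stats import t as tdist

        p_expected = 2 * tdist.sf(abs(t_expected), df)
        assert t == pytest.approx(t_expected)
        assert p == pytest.approx(p_expected)

    def _nets_and_expr(self, rng):
        base = rng.standard_normal(120)
        rows = {"T1": rng.standard_normal(120), "T2": rng.standard_normal(120),
                "T3": rng.standard_normal(120)}
        # co-regulated genes: correlated through `base`
        for i in range(4):
            rows[f"c{i}"] = base + 0.4 * rng.standard_normal(120)
        # unrelated genes
        for i in range(4):
            rows[f"u{i}"] = rng.standard_normal(120)
        expr = _expr(rows)
        after_edges = {(tf, f"c{i}") for tf in ("T1", "T2") for i in range(4)}
        before_edges = set(after_edges) | {
            (tf, f"u{i}") for tf in ("T1", "T2") for i in range(4)
        }
        return RegulatoryNetwork(before_edges), RegulatoryNetwork(after_edges), expr

    def test_identity_comparison_gives_zero_t(self, rng):
        before, _, expr = self._nets_and_expr(rng)
        rep = coexpression_comparison(before, before, expr, 2)
        assert rep.per_k[2].t_statistic == pytest.approx(0.0)
        assert rep.per_k[2].n_pairs_before == rep.per_k[2].n_pairs_after

    def test_coregulated_pairs_more_correlated_after(self, rng):
        before, after, expr = self._nets_and_expr(rng)
        rep = coexpression_comparison(before, after, expr, 2)
        row = rep.per_k[2]
        assert row.mean_r_after > row.mean_r_before
        assert row.t_statistic > 0

    def test_cumulative_pair_sets_shrink_with_k(self, rng):
        before, after, expr = self._nets_and_expr(rng)
        rep = coexpression_comparison(before, after, expr, 3)
        assert rep.per_k[3].n_pairs_before <= rep.per_k[2].n_pairs_before

    def test_sparse_k_reported_with_nan(self, rng):
        net = RegulatoryNetwork([("T1", "a"), ("T1", "b"), ("T2", "a"), ("T2", "b")])
        expr = _expr({g: rng.standard_normal(60) for g in ("a", "b")})
        rep = coexpression_comparison(net, net, expr, 2)
        # only one pair -> t/p undefined
        assert np.isnan(rep.per_k[2].t_statistic)

    def test_k_max_validated(self, rng):
        net = RegulatoryNetwork([("T1", "a")])
        expr = _expr({"a": rng.standard_normal(60)})
        with pytest.raises(ValueError):
            coexpression_comparison(net, net, expr, 1)
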