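"""Information-cost formulas, their identities, and threshold behaviour."""

import math
import random

import pytest

from powergraph import (
    InputError,
    PowerComponent,
    decompose,
    delta_i,
    delta_i_coefficient,
    edge_cost,
    edge_removal_repair_cost,
    power_cost,
    total_compression,
    validate_graph,
)

from conftest import (
    oracle_total_compression_bits,
    random_graph,
    random_valid_components,
)


class TestPowerCost:
    def test_four_bit_identifiers(self):
        # 4 member identifiers + 2 power-node identifiers, 4 bits each
        assert power_cost(2, 2, 16) == 24.0

    def test_minimal_case_one_bit_identifiers(self):
        assert power_cost(1, 1, 2) == 4.0

    def test_symmetric_in_sides(self):
        for n_a in range(1, 6):
            for n_b in range(1, 6):
                assert power_cost(n_a, n_b, 8) == power_cost(n_b, n_a, 8)

    def test_n_below_two_rejected(self):
        with pytest.raises(InputError):
            power_cost(1, 1, 1)


class TestEdgeCost:
    def test_directed_biclique(self):
        # 4 edges x 2 identifiers x 4 bits each
        assert edge_cost(2, 2, 0, 16, "directed") == 32.0

    def test_undirected_triangle_as_self_overlap(self):
        # A = B = a 3-clique: 9 - 3*4/2 = 3 distinct edges, 6 identifiers
        assert edge_cost(3, 3, 3, 8, "undirected_noself") == 18.0

    def test_undirected_without_overlap_matches_directed(self):
        for n_a in range(1, 5):
            for n_b in range(1, 5):
                assert edge_cost(n_a, n_b, 0, 16, "undirected_noself") == edge_cost(
                    n_a, n_b, 0, 16, "directed"
                )

    def test_inconsistent_overlap_rejected(self):
        with pytest.raises(InputError):
            edge_cost(2, 3, 3, 16, "undirected_noself")


class TestDeltaI:
    def test_single_edge_never_compressible(self):
        for N in (2, 8, 34):
            comp = PowerComponent(frozenset({"a"}), frozenset({"b"}))
            assert delta_i(comp, N, "directed") == -2 * math.log2(N)

    def test_directed_k22(self):
        comp = PowerComponent(frozenset({"a", "b"}), frozenset({"c", "d"}))
        assert delta_i(comp, 16, "directed") == 8.0

    def test_undirected_five_clique(self):
        nodes = frozenset("abcde")
        comp = PowerComponent(nodes, nodes)
        # 10 clique edges cost 60 bits raw vs a 36-bit poweredge
        assert delta_i(comp, 8, "undirected_noself") == 24.0

    def test_undirected_triangle_negative(self):
        nodes = frozenset("abc")
        comp = PowerComponent(nodes, nodes)
        assert delta_i(comp, 8, "undirected_noself") == -6.0

    def test_matches_edge_minus_power_cost(self):
        for mode in ("directed", "undirected_self", "undirected_noself"):
            for n_a in range(1, 7):
                for n_b in range(1, 7):
                    n_ab = 0 if mode == "directed" else min(n_a, n_b) // 2
                    c = delta_i_coefficient(n_a, n_b, n_ab, mode)
                    expect = edge_cost(n_a, n_b, n_ab, 16, mode) - power_cost(n_a, n_b, 16)
                    assert c * math.log2(16) == expect

    def test_monotone_benefit_in_n_b(self):
        """Each added B-column of a biclique adds 2 n_A log2 N savings
        against one log2 N identifier, so the gain strictly increases."""
        for n_a in range(1, 8):
            prev = None
            for n_b in range(1, 10):
                cur = delta_i_coefficient(n_a, n_b, 0, "directed")
                if prev is not None:
                    assert cur > prev
                prev = cur


class TestThresholds:
    def test_pair_needs_two_common_neighbors(self):
        # n_A = 2: positive gain iff n_B >= 2
        for n_b in range(1, 11):
            coeff = delta_i_coefficient(2, n_b, 0, "undirected_noself")
            assert (coeff > 0) == (n_b >= 2)

    def test_star_needs_four_leaves(self):
        for n_b in range(1, 11):
            coeff = delta_i_coefficient(1, n_b, 0, "undirected_noself")
            assert (coeff > 0) == (n_b >= 4)

    def test_exhaustive_sign_sweep(self):
        """Sign of the gain agrees with 2 e(A,B) vs n_A + n_B + 2 for all
        disjoint side sizes up to 10, in every mode."""
        for mode in ("directed", "bipartite", "undirected_noself", "undirected_self"):
            for n_a in range(1, 11):
                for n_b in range(1, 11):
                    coeff = delta_i_coefficient(n_a, n_b, 0, mode)
                    assert (coeff > 0) == (2 * n_a * n_b > n_a + n_b + 2)


class TestTotalCompression:
    def _graph_with_two_disjoint_bicliques(self):
        edges = []
        a1, b1 = [f"a{i}" for i in range(2)], [f"b{i}" for i in range(3)]
        a2, b2 = [f"c{i}" for i in range(3)], [f"d{i}" for i in range(3)]
        for u in a1:
            edges += [(u, v) for v in b1]
        for u in a2:
            edges += [(u, v) for v in b2]
        g = validate_graph(a1 + b1 + a2 + b2, edges, "directed")
        return (
            g,
            PowerComponent(frozenset(a1), frozenset(b1)),
            PowerComponent(frozenset(a2), frozenset(b2)),
        )

    def test_single_component_equals_its_gain(self):
        g, c1, _ = self._graph_with_two_disjoint_bicliques()
        dec = decompose(g, [c1])
        assert dec.delta_i_total == delta_i(c1, g.n_nodes, g.mode)

    def test_disjoint_components_add(self):
        g, c1, c2 = self._graph_with_two_disjoint_bicliques()
        dec = decompose(g, [c1, c2])
        expected = delta_i(c1, g.n_nodes, g.mode) + delta_i(c2, g.n_nodes, g.mode)
        assert dec.delta_i_total == pytest.approx(expected, abs=1e-12)

    def test_duplicate_pays_full_overlap_penalty(self):
        g, c1, _ = self._graph_with_two_disjoint_bicliques()
        once = decompose(g, [c1]).delta_i_total
        twice = decompose(g, [c1, c1]).delta_i_total
        penalty = 2 * math.log2(g.n_nodes) * c1.n_a * c1.n_b
        assert twice == pytest.approx(2 * once - penalty, abs=1e-12)
        assert twice < once

    def test_zero_marginal_component_changes_nothing_in_coverage(self):
        """Covered edges and remainder are unchanged by re-adding an
        already-covered component; only its poweredge cost is paid."""
        g, c1, _ = self._graph_with_two_disjoint_bicliques()
        dec1 = decompose(g, [c1])
        dec2 = decompose(g, [c1, c1])
        assert dec1.remainder == dec2.remainder

    def test_matches_sum_minus_overlap_penalty_identity(self):
        """The first-principles total equals sum_k delta_i_k minus
        2 log2 N per repeated edge coverage (the shortcut identity)."""
        rng = random.Random(31)
        checked = 0
        for _ in range(300):
            g = random_graph(rng)
            comps = random_valid_components(rng, g)
            if not comps:
                continue
            dec = decompose(g, comps)
            log2N = math.log2(g.n_nodes)
            shortcut = sum(
                delta_i(c, g.n_nodes, g.mode, g.allow_self) for c in dec.selected
            ) - 2 * log2N * dec.total_overlap
            assert dec.delta_i_total == pytest.approx(shortcut, abs=1e-9)
            checked += 1
        assert checked >= 150

    def test_oracle_equivalence_exact(self):
        """Description-length accounting oracle agrees exactly on random
        small graphs and random valid component sets."""
        rng = random.Random(47)
        checked = 0
        for _ in range(250):
            g = random_graph(rng, max_n=12)
            comps = random_valid_components(rng, g)
            dec = decompose(g, comps)
            assert total_compression(dec) == dec.delta_i_total
            assert dec.delta_i_total == oracle_total_compression_bits(g, comps)
            checked += 1
        assert checked >= 250


class TestEdgeRemovalRepairCost:
    def test_star_repairs_for_free(self):
        for k in range(1, 9):
            assert edge_removal_repair_cost(1, k, 16) == 0.0

    def test_example_value(self):
        assert edge_removal_repair_cost(3, 7, 16) == 16.0

    def test_symmetric(self):
        for n_a in range(1, 6):
            for n_b in range(1, 6):
                assert edge_removal_repair_cost(n_a, n_b, 32) == edge_removal_repair_cost(
                    n_b, n_a, 32
                )

    def test_approximates_exact_repair_recomputation(self):
        """The cheapest exact repair after deleting one biclique edge
        (evict one endpoint from its side; re-encode that node's intact
        edges individually) changes the gain by (2 min(n_A, n_B) - 1)
        identifiers; the stated approximation 2 log2 N (min - 1) matches
        it to within a single log2 N identifier."""
        N = 16
        log2N = math.log2(N)

        def gain_after_evicting(side: int, n_a: int, n_b: int) -> float:
            # component shrinks on one side; the evicted node's surviving
            # edges (its row/column minus the deleted edge) go raw
            if side == 0:
                shrunk = delta_i_coefficient(n_a - 1, n_b, 0, "directed")
                raw = n_b - 1
            else:
                shrunk = delta_i_coefficient(n_a, n_b - 1, 0, "directed")
                raw = n_a - 1
            # raw edges contribute zero gain relative to listing them
            return shrunk * log2N - 0 * raw

        for n_a in range(2, 7):
            for n_b in range(2, 9):
                old = delta_i_coefficient(n_a, n_b, 0, "directed") * log2N
                best_new = max(
                    gain_after_evicting(0, n_a, n_b), gain_after_evicting(1, n_a, n_b)
                )
                exact_change = old - best_new
                approx = edge_removal_repair_cost(n_a, n_b, N)
                assert exact_change == pytest.approx(
                    (2 * min(n_a, n_b) - 1) * log2N, abs=1e-9
                )
                assert abs(approx - exact_change) <= log2N + 1e-9
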