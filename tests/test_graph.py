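"""Graph construction: weights, neighbor ranges, arcs, feasible ranges."""

import numpy as np
import pytest

from subvoxseg.costs import CostVolume
from subvoxseg.deformation import DeformationField
from subvoxseg.graph import (Constraints, build_graph, neighbor_ranges,
                             node_weights)

from conftest import random_small_graph, surface_membership


class TestConstraints:
    def test_validation(self):
        with pytest.raises(ValueError, match="nonnegative"):
            Constraints(dx=-1.0)
        with pytest.raises(ValueError, match="separation pairs"):
            Constraints(n_surfaces=2)
        with pytest.raises(ValueError, match="out of order"):
            Constraints(n_surfaces=2, sep=((5.0, 3.0),))
        with pytest.raises(ValueError, match="minimum separation"):
            Constraints(n_surfaces=2, sep=((-1.0, 3.0),))


class TestNodeWeights:
    def test_direct_example(self):
        assert np.array_equal(node_weights(np.array([5.0, 3.0, 2.0])),
                              [5.0, -2.0, -1.0])

    def test_prefix_sums_reproduce_costs(self):
        rng = np.random.default_rng(0)
        c = rng.normal(size=(4, 3, 16))
        w = node_weights(c)
        assert np.allclose(np.cumsum(w, axis=-1), c, atol=1e-12)

    def test_depth_k_summation_oracle(self):
        rng = np.random.default_rng(1)
        c = rng.normal(size=64)
        w = node_weights(c)
        for k in (0, 10, 31, 63):
            assert np.isclose(w[:k + 1].sum(), c[k], atol=1e-10)

    def test_empty_and_nonfinite(self):
        with pytest.raises(ValueError, match="empty"):
            node_weights(np.array([]))
        with pytest.raises(ValueError, match="non-finite"):
            node_weights(np.array([1.0, np.inf]))


class TestNeighborRanges:
    def test_integer_columns_delta_one(self):
        col = np.arange(6, dtype=float)
        bm = neighbor_ranges(col, col, 1.0)
        assert np.array_equal(bm, np.maximum(np.arange(6) - 1, 0))

    def test_deformed_window_example(self):
        bm = neighbor_ranges(np.array([2.4]),
                             np.array([0.6, 1.6, 2.6, 3.4]), 1.0)
        assert bm[0] == 1  # window [1.4, 3.4] -> lowest feasible is 1.6

    def test_matches_brute_force_and_proper_ordering(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = int(rng.integers(2, 9))
            zA = np.cumsum(rng.uniform(0.05, 1.95, size=n))
            zB = np.cumsum(rng.uniform(0.05, 1.95, size=n))
            # j = i is always within delta, so every window is non-empty
            delta = float(np.abs(zA - zB).max() + 0.1)
            bm = neighbor_ranges(zA, zB, delta)
            brute = np.array([
                min(j for j in range(n) if abs(zA[i] - zB[j]) <= delta)
                for i in range(n)])
            assert np.array_equal(bm, brute)
            assert np.all(np.diff(bm) >= 0)  # properly ordered

    def test_nonmonotone_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            neighbor_ranges(np.array([1.0, 0.5]), np.array([0.0, 1.0]), 1.0)


def _cost(values):
    return CostVolume(values, 0.3, "dark_to_bright")


class TestBuildGraph:
    def test_conventional_construction_exact(self):
        rng = np.random.default_rng(3)
        X, Y, Z = 3, 3, 4
        cons = Constraints(dx=1.0, dy=1.0, n_surfaces=1)
        g = build_graph([_cost(rng.normal(size=(X, Y, Z)))], None, cons)

        def nid(x, y, k):
            return (x * Y + y) * Z + k

        expected = set()
        for x in range(X):
            for y in range(Y):
                for k in range(1, Z):  # intra-column downward
                    expected.add((nid(x, y, k), nid(x, y, k - 1)))
                for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    xb, yb = x + dx, y + dy
                    if 0 <= xb < X and 0 <= yb < Y:
                        for k in range(Z):  # bottom-most under delta = 1
                            expected.add((nid(x, y, k),
                                          nid(xb, yb, max(k - 1, 0))))
        bottoms = [nid(x, y, 0) for x in range(X) for y in range(Y)]
        got = set(zip(g.arcs_tail.tolist(), g.arcs_head.tolist()))
        base = set(zip(bottoms, np.roll(bottoms, -1).tolist()))
        assert got == expected | base
        assert np.array_equal(g.zprime[..., :],
                              np.broadcast_to(np.arange(Z, dtype=float),
                                              (X, Y, Z)))

    def test_two_surface_separation_arcs_on_single_column(self):
        rng = np.random.default_rng(4)
        Z = 12
        cons = Constraints(dx=1.0, dy=1.0, n_surfaces=2, sep=((3.0, 8.0),))
        g = build_graph([_cost(rng.normal(size=(1, 1, Z))),
                         _cost(rng.normal(size=(1, 1, Z)))], None, cons)
        # feasible ranges: subgraph 0 over k = 0..8, subgraph 1 over 3..11
        assert (g.k_min.tolist(), g.k_max.tolist()) == ([0, 3], [8, 11])
        got = set(zip(g.arcs_tail.tolist(), g.arcs_head.tolist()))
        for k in range(0, 9):  # lower node -> lowest upper >= k + 3
            tail = int(g.node_id(0, 0, 0, k))
            head = int(g.node_id(1, 0, 0, k + 3))
            assert (tail, head) in got
        for j in range(3, 12):  # upper node -> lowest lower >= j - 8
            tail = int(g.node_id(1, 0, 0, j))
            head = int(g.node_id(0, 0, 0, max(j - 8, 0)))
            assert (tail, head) in got

    def test_single_surface_counts_invariant_under_deformation(self):
        # without separation coupling the feasible k-range is the full
        # column, so node and arc counts cannot depend on the field
        rng = np.random.default_rng(5)
        X, Y, Z = 3, 2, 6
        cons = Constraints(dx=1.0, dy=1.0, n_surfaces=1)
        costs = [_cost(rng.normal(size=(X, Y, Z)))]
        ref = build_graph(costs, None, cons)
        for _ in range(10):
            D = DeformationField(
                rng.uniform(-0.49, 0.49, size=(X, Y, Z, 3)), eta=1.0)
            g = build_graph(costs, D, cons)
            assert g.n_nodes == ref.n_nodes
            assert g.arc_counts == ref.arc_counts
            assert g.fallback_count == 0

    def test_self_closure_of_feasible_surfaces(self):
        from subvoxseg.solver import enumerate_closed_sets_oracle

        rng = np.random.default_rng(6)
        checked = 0
        while checked < 5:
            g = random_small_graph(rng)
            tops, costs = enumerate_closed_sets_oracle(g)
            if len(tops) == 0 or len(tops) > 500:
                continue
            checked += 1
            for t in tops:
                member = surface_membership(g, t)
                # closedness: no arc leaves the set
                assert member[g.arcs_head[member[g.arcs_tail]]].all()

    def test_infeasible_separation_raises(self):
        rng = np.random.default_rng(7)
        cons = Constraints(dx=1.0, dy=1.0, n_surfaces=2, sep=((5.0, 8.0),))
        with pytest.raises(ValueError, match="infeasible"):
            build_graph([_cost(rng.normal(size=(2, 2, 5)))] * 2, None, cons)

    def test_strictly_increasing_zprime_required(self):
        # a non-normalized field is rejected before z-order even matters
        disp = np.zeros((2, 2, 4, 3))
        disp[..., 2] = 0.7
        with pytest.raises(ValueError, match="normalized"):
            build_graph([_cost(np.zeros((2, 2, 4)))],
                        DeformationField(disp, eta=1.0),
                        Constraints())

    def test_cost_count_mismatch(self):
        with pytest.raises(ValueError, match="cost volumes"):
            build_graph([_cost(np.zeros((2, 2, 4)))],
                        None, Constraints(n_surfaces=2, sep=((1.0, 2.0),)))

    def test_node_cost_prefix_matches_costs(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(2, 2, 5))
        g = build_graph([_cost(vals)], None, Constraints())
        csum = g.node_cost_prefix()
        assert np.allclose(csum[0], vals, atol=1e-12)
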