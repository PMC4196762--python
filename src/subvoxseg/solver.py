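"""Minimum-cost closed set via s-t maximum flow, plus verification oracles.

The reduction is the standard one: a source arc of capacity ``-w`` feeds
every negative-weight node, every positive-weight node drains to the sink
with capacity ``w``, and all constraint arcs get a capacity exceeding any
possible cut.  The source side of a minimum cut is a minimum-weight closed
set, and the total weight satisfies ``sum(negative weights) + max-flow``.

To force a non-empty solution, a constant larger than the total absolute
weight is subtracted from one base (bottom) node; the base ring then pulls
every bottom node (and its separation closure) into the minimum closed
set, and the constant cancels out of the surface comparison.

The returned set is canonicalized to the inclusion-minimal minimum closed
set (breadth-first reachability from the source in the residual graph),
i.e. the lowest optimal upper envelope, making the output deterministic
across max-flow implementations.

Weights are scaled to integers (default factor 1e6) so the scipy max-flow
backend is exact; the factor is automatically reduced in decades when the
capacities would overflow 32-bit integers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

from .graph import SegGraph

__all__ = ["ClosedSet", "min_closed_set", "enumerate_closed_sets_oracle",
           "dp_single_surface_2d"]

log = logging.getLogger(__name__)

INT32_MAX = np.iinfo(np.int32).max


@dataclass
class ClosedSet:
    """Solver output: node membership, per-column top indices, diagnostics.

    ``total_weight`` is the sum of the original (unshifted) node weights of
    all member nodes, which by the telescoping transform equals the summed
    on-surface cost of the extracted surfaces.
    """

    membership: np.ndarray          # bool per node id
    tops: np.ndarray                # (lambda, X, Y) int top k per column
    total_weight: float
    flow_value: float               # max-flow on the shifted weights
    shifted_negative_sum: float     # sum of negative shifted weights
    base_shift: float               # constant subtracted from one base node
    scale: float
    info: dict = field(default_factory=dict)


def _node_weight_vector(g: SegGraph) -> np.ndarray:
    X, Y, _ = g.shape
    parts = []
    for s in range(g.n_surfaces):
        lo, hi = g.k_min[s], g.k_max[s]
        parts.append(g.weights[s, :, :, lo:hi + 1].reshape(-1))
    return np.concatenate(parts)


def min_closed_set(g: SegGraph, scale: float = 1e6) -> ClosedSet:
    """Compute the inclusion-minimal minimum-weight closed set of ``g``."""
    w = _node_weight_vector(g)
    n = w.size
    base_shift = 1.0 + float(np.abs(w).sum())
    w_adj = w.copy()
    w_adj[g.bottom_ids[0]] -= base_shift

    # integer scaling, reduced until capacities fit int32
    while True:
        w_int = np.rint(w_adj * scale).astype(np.int64)
        neg_sum = int(-w_int[w_int < 0].sum())
        inf_cap = neg_sum + 1
        if inf_cap <= INT32_MAX:
            break
        scale /= 10.0
        log.info("min_closed_set: reducing weight scale to %g", scale)
        if scale < 1.0:
            raise OverflowError("cannot scale weights into int32 range")

    source, sink = n, n + 1
    neg = np.flatnonzero(w_int < 0)
    pos = np.flatnonzero(w_int > 0)
    rows = np.concatenate([np.full(neg.size, source), pos, g.arcs_tail])
    cols = np.concatenate([neg, np.full(pos.size, sink), g.arcs_head])
    caps = np.concatenate([-w_int[neg], w_int[pos],
                           np.full(g.arcs_tail.size, inf_cap, dtype=np.int64)])
    cap = coo_matrix((caps, (rows, cols)), shape=(n + 2, n + 2)).tocsr()
    cap.sum_duplicates()
    cap.data = np.minimum(cap.data, inf_cap)
    cap = cap.astype(np.int32)

    res = maximum_flow(cap, source, sink)
    residual = cap - res.flow
    residual.data = (residual.data > 0).astype(np.int32)
    residual.eliminate_zeros()
    order = breadth_first_order(residual, source, directed=True,
                                return_predecessors=False)
    membership = np.zeros(n, dtype=bool)
    members = order[order < n]
    membership[members] = True

    if not membership.any():
        raise RuntimeError("empty closed set despite mandatory base")

    # per-column tops; membership must be a downward-closed prefix
    X, Y, _ = g.shape
    tops = np.empty((g.n_surfaces, X, Y), dtype=int)
    pos0 = 0
    for s in range(g.n_surfaces):
        ln = int(g.col_len[s])
        m = membership[pos0:pos0 + X * Y * ln].reshape(X, Y, ln)
        pos0 += X * Y * ln
        counts = m.sum(axis=-1)
        if (counts == 0).any():
            raise RuntimeError("column with empty membership")
        prefix_ok = (m[..., :-1] >= m[..., 1:]).all() if ln > 1 else True
        if not prefix_ok:
            raise RuntimeError("closed set is not a column prefix")
        tops[s] = g.k_min[s] + counts - 1

    total = float(w[membership].sum())
    flow_value = res.flow_value / scale
    shifted_neg = float(w_int[w_int < 0].sum()) / scale
    # duality on the scaled integers: sum over C of w_int == neg + flow
    lhs = int(w_int[membership].sum())
    rhs = int(w_int[w_int < 0].sum()) + int(res.flow_value)
    if lhs != rhs:
        raise RuntimeError(f"max-flow duality violated: {lhs} != {rhs}")

    return ClosedSet(
        membership=membership, tops=tops, total_weight=total,
        flow_value=flow_value, shifted_negative_sum=shifted_neg,
        base_shift=base_shift, scale=scale,
        info={"flow_value_int": int(res.flow_value),
              "n_nodes": n, "n_arcs": g.n_arcs},
    )


def _column_ranges(g: SegGraph):
    """(s, x, y) column list with feasible k-ranges, in a fixed order."""
    X, Y, _ = g.shape
    cols = []
    for s in range(g.n_surfaces):
        for x in range(X):
            for y in range(Y):
                cols.append((s, x, y))
    return cols


def enumerate_closed_sets_oracle(g: SegGraph, limit: int = 1_000_000):
    """Exhaustively enumerate all feasible surface sets with total costs.

    Independent of the arc construction and the max-flow solver: top
    indices are enumerated per column over the feasible k-ranges, filtered
    directly by the smoothness and separation windows on the deformed
    coordinates, and costs summed from the per-column cost prefix.

    Returns ``(tops, costs)`` sorted ascending by cost; ``tops`` has shape
    ``(n_feasible, n_columns)`` in the order of ``(s, x, y)`` C-iteration.
    """
    cols = _column_ranges(g)
    sizes = [int(g.col_len[s]) for (s, _, _) in cols]
    total = 1
    for sz in sizes:
        total *= sz
        if total > limit:
            raise ValueError(f"enumeration would exceed {limit} combinations")

    grids = np.meshgrid(*[np.arange(sz) for sz in sizes], indexing="ij")
    combos = np.stack([gr.ravel() for gr in grids], axis=1)  # (N, ncols)
    ks = combos + np.array([g.k_min[s] for (s, _, _) in cols])

    col_index = {c: i for i, c in enumerate(cols)}
    X, Y, _ = g.shape
    zp = g.zprime
    feasible = np.ones(len(combos), dtype=bool)

    def zvals(ci: int) -> np.ndarray:
        s, x, y = cols[ci]
        return zp[x, y, ks[:, ci]]

    for ci, (s, x, y) in enumerate(cols):
        for dx_, dy_, delta in ((1, 0, g.constraints.dx),
                                (0, 1, g.constraints.dy)):
            xb, yb = x + dx_, y + dy_
            if xb < X and yb < Y:
                cj = col_index[(s, xb, yb)]
                feasible &= np.abs(zvals(ci) - zvals(cj)) <= delta + 1e-12
        if s + 1 < g.n_surfaces:
            lo, up = g.constraints.sep[s]
            cj = col_index[(s + 1, x, y)]
            d = zvals(cj) - zvals(ci)
            feasible &= (d >= lo - 1e-12) & (d <= up + 1e-12)

    csum = g.node_cost_prefix()
    costs = np.zeros(len(combos))
    for ci, (s, x, y) in enumerate(cols):
        costs += csum[s, x, y, ks[:, ci]]

    tops = ks[feasible]
    costs = costs[feasible]
    order = np.argsort(costs, kind="stable")
    return tops[order], costs[order]


def dp_single_surface_2d(cost: np.ndarray, delta: float,
                         zprime: np.ndarray | None = None
                         ) -> tuple[np.ndarray, float]:
    """Dynamic-programming oracle for one surface in one B-scan.

    ``cost`` is ``(n_columns, Z)``; ``zprime`` optionally gives deformed
    node heights per column (defaults to integer heights).  Minimizes the
    summed cost under ``|z'(i, k) - z'(i+1, k')| <= delta`` and returns the
    canonical optimum: per column, the lowest node that lies on any
    minimum-cost surface (the pointwise minimum of all optimal surfaces,
    which is itself optimal for interval constraints).
    """
    c = np.asarray(cost, dtype=np.float64)
    n, Z = c.shape
    zp = (np.broadcast_to(np.arange(Z, dtype=float), c.shape).copy()
          if zprime is None else np.asarray(zprime, dtype=np.float64))

    def compat(i: int, j: int) -> np.ndarray:
        # boolean (Z_i, Z_j) compatibility between columns i and j
        return np.abs(zp[i][:, None] - zp[j][None, :]) <= delta + 1e-12

    big = np.inf
    F = np.empty_like(c)
    F[0] = c[0]
    for i in range(1, n):
        m = compat(i - 1, i)
        prev = np.where(m, F[i - 1][:, None], big)
        F[i] = c[i] + prev.min(axis=0)
    B = np.empty_like(c)
    B[n - 1] = c[n - 1]
    for i in range(n - 2, -1, -1):
        m = compat(i, i + 1)
        nxt = np.where(m, B[i + 1][None, :], big)
        B[i] = c[i] + nxt.min(axis=1)
    opt = float(F[n - 1].min())
    on_opt = np.abs(F + B - c - opt) <= 1e-9 * max(1.0, abs(opt))
    surface = np.argmax(on_opt, axis=1)  # lowest marked k per column
    return surface, opt
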