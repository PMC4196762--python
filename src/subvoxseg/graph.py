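"""Node-weighted directed graph construction for optimal surface search.

Every voxel column contributes a node-column; node ``k`` of column (x, y)
sits at deformed height ``z'(x,y,k) = k + D_z(x,y,k)`` (in voxels of the
analysis grid), or exactly at ``k`` for the conventional Euclidean graph.
Node weights follow the telescoping transform ``w(k) = c(k) - c(k-1)``
(``w(k_min) = c(k_min)``), so the total weight of a downward-closed column
prefix with top ``t`` equals the on-surface cost ``c(t)``.

Arcs encode feasibility:

* intra-column arcs point downward, forcing membership to be a column
  prefix (each surface crosses a column exactly once);
* inter-column arcs point to the bottom-most neighbor on each adjacent
  column (4-neighborhood), encoding the smoothness bounds ``dx, dy``
  evaluated on the deformed coordinates;
* inter-subgraph arcs couple corresponding columns of adjacent surface
  subgraphs with the separation window ``delta_low <= z'_{s+1} - z'_s <=
  delta_up`` (one arc direction enforces each bound);
* base arcs link the bottom nodes of all columns into a ring so the bottom
  slab (and its separation closure) is always a feasible closed set.

Because deformed neighbor ranges are properly ordered (z' is strictly
increasing along every column), the bottom-most-neighbor arcs preserve the
self-closure property that makes the minimum closed set correspond to the
optimal surface set.

With a positive minimum-separation bound, nodes too close to the volume
top or bottom can never lie on a feasible surface; as in the classical
multi-surface construction, each subgraph is therefore restricted to a
feasible k-range (computed from the integer bounds plus a one-voxel margin
for the half-voxel deformations, hence independent of the deformation
itself).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .costs import CostVolume
from .deformation import DeformationField

__all__ = ["Constraints", "SegGraph", "node_weights", "neighbor_ranges",
           "build_graph"]

log = logging.getLogger(__name__)


@dataclass
class Constraints:
    """Surface smoothness and separation bounds.

    ``dx``/``dy``: maximum allowed z-change (deformed voxel units) per unit
    column step along x/y.  ``sep``: one ``(delta_low, delta_up)`` pair per
    adjacent surface pair; required when ``n_surfaces > 1``.
    """

    dx: float = 1.0
    dy: float = 1.0
    n_surfaces: int = 1
    sep: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.dx < 0 or self.dy < 0:
            raise ValueError("smoothness bounds must be nonnegative")
        if self.n_surfaces < 1:
            raise ValueError("n_surfaces must be >= 1")
        self.sep = tuple((float(a), float(b)) for a, b in self.sep)
        if len(self.sep) != self.n_surfaces - 1:
            raise ValueError(
                f"need {self.n_surfaces - 1} separation pairs, got {len(self.sep)}")
        for lo, up in self.sep:
            if lo > up:
                raise ValueError(f"separation bounds out of order: ({lo}, {up})")
            if lo < 0:
                raise ValueError("minimum separation must be nonnegative")


def node_weights(cost_column: np.ndarray) -> np.ndarray:
    """Telescoping weight transform: w(0)=c(0), w(k)=c(k)-c(k-1)."""
    c = np.asarray(cost_column, dtype=np.float64)
    if c.size == 0:
        raise ValueError("empty cost column")
    if not np.isfinite(c).all():
        raise ValueError("non-finite cost in column")
    w = np.empty_like(c)
    w[..., 0] = c[..., 0]
    w[..., 1:] = np.diff(c, axis=-1)
    return w


def _bottommost(zA: np.ndarray, zB: np.ndarray, lo: float, hi: float
                ) -> tuple[np.ndarray, np.ndarray]:
    """Smallest index j on column(s) B with ``zB[j] - zA[i] in [lo, hi]``.

    ``zA``: (..., nA), ``zB``: (..., nB), both strictly increasing along the
    last axis.  Returns ``(bm, fallback)``: where no j qualifies, ``bm`` is
    the index of the node nearest to the window and ``fallback`` is True.
    """
    nB = zB.shape[-1]
    target = zA[..., :, None] + lo
    cnt = (zB[..., None, :] < target).sum(axis=-1)  # (..., nA)
    bm = np.minimum(cnt, nB - 1)
    zB_bm = np.take_along_axis(zB, bm, axis=-1)
    ok = (cnt < nB) & (zB_bm <= zA + hi)
    fallback = ~ok
    if fallback.any():
        # nearest node to the interval [zA+lo, zA+hi]: candidate above is
        # bm, candidate below is bm-1 (when cnt==nB the top node is below)
        below = np.maximum(bm - (cnt < nB).astype(int), 0)
        zB_below = np.take_along_axis(zB, below, axis=-1)
        d_above = np.abs(zB_bm - (zA + hi))
        d_below = np.abs((zA + lo) - zB_below)
        nearest = np.where(d_below <= d_above, below, bm)
        bm = np.where(fallback, nearest, bm)
    return bm, fallback


def neighbor_ranges(colA: np.ndarray, colB: np.ndarray, delta: float
                    ) -> np.ndarray:
    """Bottom-most neighbor index on colB for every node of colA under the
    symmetric window ``|z'_A(i) - z'_B(j)| <= delta``.

    The top-most neighbor follows by the mirror symmetry
    ``tm(i) = nB - 1 - bm_rev(i)`` on reversed, negated columns.
    """
    colA = np.asarray(colA, dtype=np.float64)
    colB = np.asarray(colB, dtype=np.float64)
    if (np.diff(colA) <= 0).any() or (np.diff(colB) <= 0).any():
        raise ValueError("columns must be strictly increasing")
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    bm, fb = _bottommost(colA, colB, -delta, delta)
    if fb.any():
        log.warning("neighbor_ranges: %d empty windows resolved by "
                    "nearest-node fallback", int(fb.sum()))
    return bm


def _feasible_ranges(Z: int, cons: Constraints, max_dz: float
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-subgraph feasible k-ranges under the separation chain."""
    lam = cons.n_surfaces
    k_min = np.zeros(lam, dtype=int)
    k_max = np.full(lam, Z - 1, dtype=int)
    m = 2.0 * max_dz
    for s in range(lam - 1):  # bottom-up
        lo, up = cons.sep[s]
        k_min[s + 1] = max(k_min[s + 1], math.ceil(k_min[s] + lo + m))
        k_max[s + 1] = min(k_max[s + 1], math.floor(k_max[s] + up - m))
    for s in range(lam - 2, -1, -1):  # top-down
        lo, up = cons.sep[s]
        k_max[s] = min(k_max[s], math.floor(k_max[s + 1] - lo - m))
        k_min[s] = max(k_min[s], math.ceil(k_min[s + 1] - up + m))
    if (k_min > k_max).any():
        s = int(np.argmax(k_min > k_max))
        raise ValueError(
            f"infeasible constraints: subgraph {s} has empty feasible "
            f"z-range for Z={Z} and separation {cons.sep}")
    return k_min, k_max


@dataclass
class SegGraph:
    """Constructed surface-segmentation graph.

    Node ids enumerate, per subgraph, the feasible k-range of every column
    in C order (x, y, k).  ``weights`` is dense ``(lambda, X, Y, Z)`` with
    entries outside the feasible ranges unused.
    """

    shape: tuple[int, int, int]
    n_surfaces: int
    zprime: np.ndarray              # (X, Y, Z), deformed z in voxel units
    k_min: np.ndarray               # (lambda,)
    k_max: np.ndarray               # (lambda,)
    weights: np.ndarray             # (lambda, X, Y, Z)
    arcs_tail: np.ndarray
    arcs_head: np.ndarray
    arc_counts: dict
    bottom_ids: np.ndarray
    constraints: Constraints
    deformed: bool
    fallback_count: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def col_len(self) -> np.ndarray:
        return self.k_max - self.k_min + 1

    @property
    def n_nodes(self) -> int:
        X, Y, _ = self.shape
        return int(X * Y * self.col_len.sum())

    @property
    def n_arcs(self) -> int:
        return int(len(self.arcs_tail))

    def subgraph_offset(self, s: int) -> int:
        X, Y, _ = self.shape
        return int(X * Y * self.col_len[:s].sum())

    def node_id(self, s, x, y, k):
        """Vectorized node id for (subgraph, x, y, k)."""
        X, Y, _ = self.shape
        s = np.asarray(s)
        L = self.col_len
        offs = np.concatenate([[0], np.cumsum(L)[:-1]]) * X * Y
        return (offs[s] + (np.asarray(x) * Y + np.asarray(y)) * L[s]
                + np.asarray(k) - self.k_min[s])

    def node_cost_prefix(self) -> np.ndarray:
        """Per-column cumulative weight: entry (s,x,y,t) is the on-surface
        cost c'(t) of placing surface s at top t (telescoping identity)."""
        csum = np.full_like(self.weights, np.nan)
        for s in range(self.n_surfaces):
            lo, hi = self.k_min[s], self.k_max[s]
            csum[s, :, :, lo:hi + 1] = np.cumsum(
                self.weights[s, :, :, lo:hi + 1], axis=-1)
        return csum

    def stats(self) -> dict:
        return {
            "shape": list(self.shape),
            "n_surfaces": self.n_surfaces,
            "n_nodes": self.n_nodes,
            "n_arcs": self.n_arcs,
            "arc_counts": {k: int(v) for k, v in self.arc_counts.items()},
            "k_ranges": [[int(a), int(b)] for a, b in
                         zip(self.k_min, self.k_max)],
            "deformed": self.deformed,
            "fallback_count": int(self.fallback_count),
        }


def build_graph(costs: CostVolume | list[CostVolume],
                D: DeformationField | None,
                cons: Constraints) -> SegGraph:
    """Assemble the full lambda-surface graph (see module docstring).

    ``costs``: one warped (or raw, for the conventional graph) cost volume
    per surface, all on one grid.  ``D``: a normalized deformation field,
    or None for the exact conventional Euclidean construction.
    """
    cost_list = [costs] if isinstance(costs, CostVolume) else list(costs)
    if len(cost_list) != cons.n_surfaces:
        raise ValueError(
            f"need {cons.n_surfaces} cost volumes, got {len(cost_list)}")
    shape = cost_list[0].shape
    for c in cost_list[1:]:
        if c.shape != shape:
            raise ValueError("cost volumes must share one grid")
    X, Y, Z = shape

    if D is None:
        zprime = np.broadcast_to(np.arange(Z, dtype=np.float64),
                                 shape).copy()
        max_dz = 0.0
    else:
        if D.grid_shape != shape:
            raise ValueError("deformation grid does not match cost grid")
        if not D.is_normalized:
            raise ValueError("deformation must be normalized")
        rel = D.relative()
        zprime = np.arange(Z, dtype=np.float64) + rel[..., 2]
        max_dz = float(np.abs(rel[..., 2]).max())
        if (np.diff(zprime, axis=-1) <= 0).any():
            raise ValueError("deformed columns must be strictly increasing")

    k_min, k_max = _feasible_ranges(Z, cons, max_dz)

    weights = np.zeros((cons.n_surfaces, X, Y, Z))
    for s in range(cons.n_surfaces):
        lo, hi = k_min[s], k_max[s]
        weights[s, :, :, lo:hi + 1] = node_weights(
            cost_list[s].values[:, :, lo:hi + 1])

    # node id layout
    L = k_max - k_min + 1
    offs = np.concatenate([[0], np.cumsum(L)[:-1]]) * X * Y

    def ids(s: int, x: np.ndarray, y: np.ndarray, k: np.ndarray) -> np.ndarray:
        return offs[s] + (x * Y + y) * L[s] + (k - k_min[s])

    tails: list[np.ndarray] = []
    heads: list[np.ndarray] = []
    counts: dict[str, int] = {}
    fallback_total = 0

    def add(tail: np.ndarray, head: np.ndarray, kind: str) -> None:
        tails.append(tail.astype(np.int64).ravel())
        heads.append(head.astype(np.int64).ravel())
        counts[kind] = counts.get(kind, 0) + tail.size

    gx, gy = np.meshgrid(np.arange(X), np.arange(Y), indexing="ij")

    # intra-column downward arcs
    for s in range(cons.n_surfaces):
        ks = np.arange(k_min[s] + 1, k_max[s] + 1)
        if ks.size:
            xx, yy, kk = np.meshgrid(np.arange(X), np.arange(Y), ks,
                                     indexing="ij")
            add(ids(s, xx, yy, kk), ids(s, xx, yy, kk - 1), "intra_column")

    # inter-column smoothness arcs, 4-neighborhood, both directions
    shifts = [((1, 0), cons.dx), ((-1, 0), cons.dx),
              ((0, 1), cons.dy), ((0, -1), cons.dy)]
    for s in range(cons.n_surfaces):
        lo, hi = k_min[s], k_max[s]
        zr = zprime[:, :, lo:hi + 1]
        for (sx, sy), delta in shifts:
            axis = 0 if sx else 1
            # slice A (tails) and B (heads) along the shifted axis
            if axis == 0:
                sl_a = (slice(1, None) if sx == 1 else slice(None, -1))
                sl_b = (slice(None, -1) if sx == 1 else slice(1, None))
                zA, zB = zr[sl_a, :, :], zr[sl_b, :, :]
                xa, ya = gx[sl_a, :], gy[sl_a, :]
                xb, yb = gx[sl_b, :], gy[sl_b, :]
            else:
                sl_a = (slice(1, None) if sy == 1 else slice(None, -1))
                sl_b = (slice(None, -1) if sy == 1 else slice(1, None))
                zA, zB = zr[:, sl_a, :], zr[:, sl_b, :]
                xa, ya = gx[:, sl_a], gy[:, sl_a]
                xb, yb = gx[:, sl_b], gy[:, sl_b]
            bm, fb = _bottommost(zA, zB, -delta, delta)
            fallback_total += int(fb.sum())
            kk = np.broadcast_to(np.arange(lo, hi + 1), bm.shape)
            tail = ids(s, xa[..., None], ya[..., None], kk)
            head = ids(s, xb[..., None], yb[..., None], bm + lo)
            add(tail, head, "inter_column")

    # inter-subgraph separation arcs on corresponding columns
    for s in range(cons.n_surfaces - 1):
        d_lo, d_up = cons.sep[s]
        z1 = zprime[:, :, k_min[s]:k_max[s] + 1]
        z2 = zprime[:, :, k_min[s + 1]:k_max[s + 1] + 1]
        # lower surface node -> lowest upper-surface node >= z1 + d_lo
        bm12, fb12 = _bottommost(z1, z2, d_lo, d_up)
        # upper surface node -> lowest lower-surface node >= z2 - d_up
        bm21, fb21 = _bottommost(z2, z1, -d_up, -d_lo)
        fallback_total += int(fb12.sum() + fb21.sum())
        k1 = np.broadcast_to(np.arange(k_min[s], k_max[s] + 1), bm12.shape)
        k2 = np.broadcast_to(np.arange(k_min[s + 1], k_max[s + 1] + 1),
                             bm21.shape)
        add(ids(s, gx[..., None], gy[..., None], k1),
            ids(s + 1, gx[..., None], gy[..., None], bm12 + k_min[s + 1]),
            "inter_subgraph")
        add(ids(s + 1, gx[..., None], gy[..., None], k2),
            ids(s, gx[..., None], gy[..., None], bm21 + k_min[s]),
            "inter_subgraph")

    # base ring over the bottom nodes of every column of every subgraph
    bottoms = np.concatenate(
        [ids(s, gx, gy, np.full_like(gx, k_min[s])).ravel()
         for s in range(cons.n_surfaces)])
    if bottoms.size > 1:
        add(bottoms, np.roll(bottoms, -1), "base")

    if fallback_total:
        log.warning("build_graph: %d empty neighbor windows resolved by "
                    "nearest-node fallback", fallback_total)

    return SegGraph(
        shape=shape, n_surfaces=cons.n_surfaces, zprime=np.asarray(zprime),
        k_min=k_min, k_max=k_max, weights=weights,
        arcs_tail=np.concatenate(tails), arcs_head=np.concatenate(heads),
        arc_counts=counts, bottom_ids=bottoms, constraints=cons,
        deformed=D is not None, fallback_count=fallback_total,
        meta={"max_rel_dz": max_dz},
    )
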