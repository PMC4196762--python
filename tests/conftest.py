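"""Shared helpers for the test suite."""

import numpy as np

from subvoxseg.costs import CostVolume
from subvoxseg.deformation import DeformationField
from subvoxseg.graph import Constraints, build_graph


def random_small_graph(rng, force_lambda=None):
    """Random small graph for which exhaustive enumeration is tractable.

    Separation windows have width 2, at least as wide as any gap between
    consecutive deformed node heights (each gap is strictly below 2 with
    half-voxel displacements), so the nearest-node fallback can never fire
    and the enumeration oracle's strict constraint filter describes exactly
    the feasible set encoded by the arcs.

    Costs are dyadic (multiples of 1/8), hence exactly representable under
    the solver's integer weight scaling, allowing exact cost comparison.
    """
    lam = int(rng.integers(1, 3)) if force_lambda is None else force_lambda
    while True:
        X = int(rng.integers(1, 4))
        Y = int(rng.integers(1, 4))
        Z = int(rng.integers(3, 6))
        if Z ** (lam * X * Y) <= 300_000:
            break
    if lam == 2 and Z < 5:
        Z = 5
    lo = float(rng.integers(0, 2))
    sep = ((lo, lo + 2.0),) if lam == 2 else ()
    cons = Constraints(dx=float(rng.choice([1.0, 2.0])),
                       dy=float(rng.choice([1.0, 2.0])),
                       n_surfaces=lam, sep=sep)
    costs = [CostVolume(rng.integers(-40, 40, size=(X, Y, Z)) / 8.0,
                        0.3, "dark_to_bright") for _ in range(lam)]
    D = (DeformationField(rng.uniform(-0.49, 0.49, size=(X, Y, Z, 3)),
                          eta=1.0)
         if rng.random() < 0.6 else None)
    return build_graph(costs, D, cons)


def surface_membership(g, tops):
    """Boolean node membership induced by per-column top indices.

    ``tops`` is a flat vector over the (s, x, y) C-order column list, as
    returned by the enumeration oracle.
    """
    n = g.n_nodes
    member = np.zeros(n, dtype=bool)
    X, Y, _ = g.shape
    ci = 0
    for s in range(g.n_surfaces):
        for x in range(X):
            for y in range(Y):
                ks = np.arange(g.k_min[s], tops[ci] + 1)
                member[g.node_id(np.full_like(ks, s), np.full_like(ks, x),
                                 np.full_like(ks, y), ks)] = True
                ci += 1
    return member
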