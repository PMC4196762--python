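"""Model/Results front end tying the pipeline together.

:class:`SurfaceSegmentationModel` is constructed from a volume plus the
feasibility constraints and cost parameters; :meth:`fit` runs cost
computation, (optionally) deformation-field estimation and cost warping,
graph construction, the max-flow solve, and surface extraction, returning
a :class:`SegmentationResults` carrying the surfaces, solver diagnostics,
and a ``summary()`` table.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .costs import CostVolume, gaussian_derivative_cost, warp_costs
from .deformation import (DeformationField, compute_deformation,
                          gvf_deformation, normalize_deformation)
from .graph import Constraints, SegGraph, build_graph
from .solver import ClosedSet, min_closed_set
from .surfaces import SurfaceSet, extract_surfaces, smooth_surface, thickness_map
from .volume import Volume

__all__ = ["SurfaceSegmentationModel", "SegmentationResults"]


class SurfaceSegmentationModel:
    """Terrain-like surface segmentation of a 3D volume.

    Parameters
    ----------
    volume
        The intensity volume (a :class:`Volume` or a 3D array).
    constraints
        Smoothness/separation :class:`Constraints`; defaults to a single
        surface with ``dx = dy = 1``.
    transitions
        Per-surface intensity transition along +z, each
        ``"dark_to_bright"`` or ``"bright_to_dark"``.
    mode
        ``"conventional"`` (integer-grid graph), ``"non_euclidean"``
        (deformed graph, subvoxel output), or ``"smoothed_conventional"``
        (conventional followed by lateral surface smoothing).
    sigma_cost, sigma_reg
        Gaussian scales (voxels) of the edge cost kernel and of the
        deformation regularization. Both default to 0.3.
    deformation_method
        ``"neg_gradient"`` or ``"gvf"``.
    """

    def __init__(self, volume: Volume | np.ndarray,
                 constraints: Constraints | None = None, *,
                 transitions: tuple[str, ...] | str = "dark_to_bright",
                 mode: str = "non_euclidean",
                 sigma_cost: float = 0.3,
                 sigma_reg: float = 0.3,
                 deformation_method: str = "neg_gradient",
                 gvf_mu: float = 0.1, gvf_n_iter: int = 200,
                 gvf_tol: float = 1e-4,
                 smooth_fwhm: float = 2.3548,
                 weight_scale: float = 1e6):
        self.volume = volume if isinstance(volume, Volume) else Volume(volume)
        self.constraints = constraints or Constraints()
        if isinstance(transitions, str):
            transitions = (transitions,) * self.constraints.n_surfaces
        if len(transitions) != self.constraints.n_surfaces:
            raise ValueError("need one transition per surface")
        self.transitions = tuple(transitions)
        if mode not in ("conventional", "non_euclidean",
                        "smoothed_conventional"):
            raise ValueError(f"unknown mode {mode!r}")
        self.mode = mode
        self.sigma_cost = float(sigma_cost)
        self.sigma_reg = float(sigma_reg)
        if deformation_method not in ("neg_gradient", "gvf"):
            raise ValueError(f"unknown deformation method {deformation_method!r}")
        self.deformation_method = deformation_method
        self.gvf_params = (float(gvf_mu), int(gvf_n_iter), float(gvf_tol))
        self.smooth_fwhm = float(smooth_fwhm)
        self.weight_scale = float(weight_scale)

    @classmethod
    def from_file(cls, path, **kwargs) -> "SurfaceSegmentationModel":
        from .volume import read_volume

        return cls(read_volume(path), **kwargs)

    # -- pipeline pieces (exposed for inspection/testing) ------------------

    def compute_costs(self) -> list[CostVolume]:
        return [gaussian_derivative_cost(self.volume, self.sigma_cost, tr)
                for tr in self.transitions]

    def compute_deformation_field(self, costs: list[CostVolume]
                                  ) -> DeformationField:
        """Normalized deformation field from the combined cost.

        With several surfaces the per-surface costs are combined by a
        pointwise minimum (most boundary-like wins) before deriving the
        field, so one field serves all subgraphs.
        """
        combined = costs[0] if len(costs) == 1 else CostVolume(
            np.minimum.reduce([c.values for c in costs]),
            costs[0].sigma, costs[0].transition, costs[0].spacing)
        if self.deformation_method == "gvf":
            mu, n_iter, tol = self.gvf_params
            raw = gvf_deformation(combined, mu, n_iter, tol, self.sigma_reg)
        else:
            raw = compute_deformation(combined, self.sigma_reg)
        return normalize_deformation(raw)

    def fit(self) -> "SegmentationResults":
        costs = self.compute_costs()
        if self.mode == "non_euclidean":
            D = self.compute_deformation_field(costs)
            node_costs = [warp_costs(c, D) for c in costs]
        else:
            D = None
            node_costs = costs
        g = build_graph(node_costs, D, self.constraints)
        cs = min_closed_set(g, self.weight_scale)
        surf = extract_surfaces(cs, g)
        if self.mode == "smoothed_conventional":
            surf = smooth_surface(surf, self.smooth_fwhm)
        return SegmentationResults(self, surf, g, cs, D)


@dataclass
class SegmentationResults:
    """Fitted surfaces plus the graph/solver diagnostics behind them."""

    model: SurfaceSegmentationModel
    surfaces: SurfaceSet
    graph: SegGraph
    closed_set: ClosedSet
    deformation: DeformationField | None = None
    meta: dict = field(default_factory=dict)

    @property
    def total_cost(self) -> float:
        return self.closed_set.total_weight

    @property
    def eta(self) -> float | None:
        return None if self.deformation is None else self.deformation.eta

    @property
    def max_displacement(self) -> float | None:
        if self.deformation is None:
            return None
        return self.deformation.max_relative_displacement()

    def thickness(self, pair: tuple[int, int] = (0, 1), mask=None):
        return thickness_map(self.surfaces, pair, mask)

    def evaluate(self, reference, bias: float = 0.0, mask=None):
        from .evaluation import surface_errors

        return surface_errors(self.surfaces, reference, bias, mask)

    def manifest(self) -> dict:
        m = self.model
        return {
            "mode": m.mode,
            "n_surfaces": m.constraints.n_surfaces,
            "dx": m.constraints.dx, "dy": m.constraints.dy,
            "sep": [list(p) for p in m.constraints.sep],
            "sigma_cost": m.sigma_cost, "sigma_reg": m.sigma_reg,
            "deformation_method": m.deformation_method,
            "transitions": list(m.transitions),
            "eta": self.eta,
            "max_displacement": self.max_displacement,
            "total_cost": self.total_cost,
            "graph": self.graph.stats(),
            "flow_value": self.closed_set.flow_value,
        }

    def summary(self) -> str:
        """Human-readable fit report."""
        m = self.model
        buf = io.StringIO()
        w = buf.write
        w("Optimal Surface Segmentation Results\n")
        w("=" * 52 + "\n")
        w(f"{'mode':<28}{m.mode}\n")
        w(f"{'grid (x, y, z)':<28}{m.volume.shape}\n")
        w(f"{'surfaces':<28}{m.constraints.n_surfaces}\n")
        w(f"{'smoothness (dx, dy)':<28}({m.constraints.dx:g}, "
          f"{m.constraints.dy:g})\n")
        if m.constraints.sep:
            w(f"{'separation bounds':<28}{list(m.constraints.sep)}\n")
        w(f"{'cost sigma (voxels)':<28}{m.sigma_cost:g}\n")
        if self.deformation is not None:
            w(f"{'deformation method':<28}{m.deformation_method}\n")
            w(f"{'regularization sigma':<28}{m.sigma_reg:g}\n")
            w(f"{'normalization eta':<28}{self.eta:.6g}\n")
            w(f"{'max |D|/spacing':<28}{self.max_displacement:.6g}\n")
        w(f"{'graph nodes':<28}{self.graph.n_nodes}\n")
        w(f"{'graph arcs':<28}{self.graph.n_arcs}\n")
        w(f"{'max-flow value':<28}{self.closed_set.flow_value:.6g}\n")
        w(f"{'total surface cost':<28}{self.total_cost:.6g}\n")
        w("-" * 52 + "\n")
        w(f"{'surface':<10}{'mean z':>10}{'min z':>10}{'max z':>10}\n")
        for s in range(self.surfaces.n_surfaces):
            h = self.surfaces.heights[s]
            w(f"{s:<10}{h.mean():>10.3f}{h.min():>10.3f}{h.max():>10.3f}\n")
        return buf.getvalue()
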