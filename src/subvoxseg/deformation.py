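"""Voxel-confined deformation fields derived from cost volumes.

The deformation field moves every graph node from its voxel center toward
the locations where a boundary is most likely (locally decreasing cost),
increasing node density there.  Two constructions are provided:

* ``neg_gradient`` (default): the negative gradient of the Gaussian-
  regularized cost, ``D = -grad(G_sigma_reg * c)``;
* ``gvf``: a gradient vector flow field, the minimizer of
  ``integral mu*|grad v|^2 + |grad f|^2 |v - grad f|^2`` with
  ``f = G_sigma * (-c)``, which diffuses the gradient into homogeneous
  regions and therefore has a larger capture range.

Either field must then be normalized so that the single largest per-axis
displacement, relative to the voxel size, equals exactly half a voxel:
the node of every voxel stays inside that voxel, which preserves the
z-order along every column and keeps the graph structure valid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate1d

from .costs import CostVolume, gaussian_kernel

__all__ = ["DeformationField", "compute_deformation", "normalize_deformation",
           "gvf_deformation", "apply_deformation"]

log = logging.getLogger(__name__)

_CENTRAL_DIFF = np.array([0.5, 0.0, -0.5])  # correlate1d -> (f[x+1]-f[x-1])/2


def _central_gradient(arr: np.ndarray, axis: int) -> np.ndarray:
    """Central differences with reflect boundary handling."""
    return correlate1d(arr, _CENTRAL_DIFF[::-1], axis=axis, mode="reflect")


@dataclass
class DeformationField:
    """Per-voxel 3-vector of node displacements in physical units.

    ``displacement[..., a] / spacing[a]`` is the displacement in voxels
    along axis ``a``; after normalization its magnitude never exceeds 0.5.
    """

    displacement: np.ndarray  # (X, Y, Z, 3)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    eta: float | None = None  # normalization factor applied, if any
    sigma_reg: float | None = None
    method: str = "neg_gradient"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=np.float64)
        if self.displacement.ndim != 4 or self.displacement.shape[-1] != 3:
            raise ValueError("displacement must have shape (X, Y, Z, 3)")
        if not np.isfinite(self.displacement).all():
            raise ValueError("deformation field contains non-finite values")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.displacement.shape[:3]

    def relative(self) -> np.ndarray:
        """Displacements in voxel units per axis."""
        return self.displacement / np.asarray(self.spacing)

    @property
    def is_normalized(self) -> bool:
        return bool((np.abs(self.relative()) <= 0.5 + 1e-12).all())

    def max_relative_displacement(self) -> float:
        return float(np.abs(self.relative()).max())

    def component_volumes(self):
        """The three displacement components as scalar volumes."""
        from .volume import Volume

        return tuple(Volume(self.displacement[..., a].copy(), self.spacing)
                     for a in range(3))

    @classmethod
    def zero(cls, shape: tuple[int, int, int],
             spacing=(1.0, 1.0, 1.0)) -> "DeformationField":
        return cls(np.zeros(tuple(shape) + (3,)), spacing, eta=1.0)


def compute_deformation(cost: CostVolume, sigma_reg: float) -> DeformationField:
    """Negative gradient of the Gaussian-regularized cost (un-normalized).

    ``sigma_reg`` is the regularization scale in voxels; 0 disables the
    smoothing.  Gradients are central differences in index space, divided
    by the voxel spacing to give physical units, so the vectors point from
    each voxel center toward locally decreasing cost.
    """
    if sigma_reg < 0:
        raise ValueError("sigma_reg must be >= 0")
    sm = cost.values
    if sigma_reg > 0:
        g = gaussian_kernel(sigma_reg)
        for ax in range(3):
            sm = correlate1d(sm, g, axis=ax, mode="reflect")
    disp = np.empty(cost.shape + (3,))
    for ax in range(3):
        disp[..., ax] = -_central_gradient(sm, ax) / cost.spacing[ax]
    return DeformationField(disp, cost.spacing, eta=None,
                            sigma_reg=float(sigma_reg), method="neg_gradient")


def normalize_deformation(D: DeformationField,
                          spacing: tuple[float, float, float] | None = None
                          ) -> DeformationField:
    """Scale the field by one global factor so the maximum per-axis
    displacement relative to the voxel size is exactly half a voxel.

    ``eta = 0.5 / max_p max_a |D_a(p)| / spacing_a``; an identically zero
    field is returned unchanged with ``eta = 1``.  A per-component clamp to
    ``+-0.5 * spacing_a`` guards against floating-point overshoot.
    """
    spacing = tuple(spacing) if spacing is not None else D.spacing
    rel_max = float(np.abs(D.displacement / np.asarray(spacing)).max())
    if rel_max == 0.0:
        return DeformationField(D.displacement.copy(), spacing, eta=1.0,
                                sigma_reg=D.sigma_reg, method=D.method,
                                meta=dict(D.meta))
    eta = 0.5 / rel_max
    disp = D.displacement * eta
    lim = 0.5 * np.asarray(spacing)
    disp = np.clip(disp, -lim, lim)
    # pin the extremal components to exactly +-0.5*spacing: scaling by
    # 0.5/rel_max can land an ulp off in floating point, and the maximum
    # relative displacement must equal one half exactly
    rel0 = np.abs(D.displacement) / np.asarray(spacing)
    at_max = rel0 == rel_max
    disp[at_max] = np.sign(D.displacement[at_max]) * np.broadcast_to(
        lim, disp.shape)[at_max]
    return DeformationField(disp, spacing, eta=eta, sigma_reg=D.sigma_reg,
                            method=D.method, meta=dict(D.meta))


def gvf_deformation(cost: CostVolume, mu: float = 0.1, n_iter: int = 200,
                    tol: float = 1e-4,
                    sigma_reg: float = 0.3) -> DeformationField:
    """Gradient vector flow field of the (negated, smoothed) cost.

    Minimizes ``integral mu*|grad v|^2 + |grad f|^2 |v - grad f|^2`` with
    ``f = G_sigma_reg * (-c)`` by explicit-Euler diffusion iterations,
    stopping when the largest component update falls below ``tol`` or after
    ``n_iter`` sweeps.  The output is un-normalized.
    """
    if mu <= 0:
        raise ValueError("mu must be > 0")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    f = -cost.values
    if sigma_reg > 0:
        g = gaussian_kernel(sigma_reg)
        for ax in range(3):
            f = correlate1d(f, g, axis=ax, mode="reflect")
    grad_f = np.stack([_central_gradient(f, ax) for ax in range(3)], axis=-1)
    gmag2 = np.sum(grad_f**2, axis=-1, keepdims=True)
    # explicit Euler step bounded by diffusion and data-term stiffness
    dt = 1.0 / (6.0 * mu + float(gmag2.max()) + 1e-12)
    v = grad_f.copy()
    lap_kernel = np.array([1.0, -2.0, 1.0])
    for it in range(n_iter):
        lap = np.zeros_like(v)
        for ax in range(3):
            lap += correlate1d(v, lap_kernel, axis=ax, mode="reflect")
        update = dt * (mu * lap - gmag2 * (v - grad_f))
        v += update
        if not np.isfinite(v).all():
            raise FloatingPointError(f"GVF iteration diverged at step {it}")
        if float(np.abs(update).max()) < tol:
            break
    disp = v / np.asarray(cost.spacing)
    return DeformationField(disp, cost.spacing, eta=None,
                            sigma_reg=float(sigma_reg), method="gvf",
                            meta={"gvf_mu": mu, "gvf_iterations": it + 1})


def apply_deformation(node_centers: np.ndarray, D: DeformationField
                      ) -> np.ndarray:
    """Displace voxel-center node positions: ``p' = p + D(p)``.

    ``node_centers`` is ``(X, Y, Z, 3)`` in physical units (or None-like
    integer grid is built by callers).  Because every normalized component
    stays within half a voxel, the z-order along each column is preserved;
    this is asserted.
    """
    if not D.is_normalized:
        raise ValueError("deformation must be normalized before application")
    pos = np.asarray(node_centers, dtype=np.float64) + D.displacement
    dz = np.diff(pos[..., 2], axis=2)
    if (dz <= 0).any():
        raise AssertionError("deformed column z-order violated")
    return pos
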