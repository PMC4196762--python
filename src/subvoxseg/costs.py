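"""On-surface cost volumes from image intensities, and cost warping.

The standard edge cost for a layered-tissue boundary is the z-component of
the Gaussian-regularized intensity gradient with the orientation flipped so
the sought transition (dark-to-bright or bright-to-dark along +z) yields
the most negative cost: ``c = -s * d/dz (G_sigma * I)``, with ``s = +1``
for dark-to-bright and ``s = -1`` for bright-to-dark.  Lower cost means
higher likelihood that a voxel lies on the surface.

After a deformation field has moved graph nodes off the voxel centers, the
costs are re-sampled at the displaced positions (trilinear interpolation),
so each node carries the cost of its updated location.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate1d, map_coordinates

from .volume import Volume

__all__ = ["CostVolume", "gaussian_derivative_cost", "warp_costs",
           "gaussian_kernel", "gaussian_derivative_kernel"]

TRANSITIONS = ("dark_to_bright", "bright_to_dark")


def _kernel_radius(sigma: float) -> int:
    # truncation radius; sigma = 0.3 deliberately yields a sharp 3-tap kernel
    return max(1, int(round(4.0 * sigma)))


def gaussian_kernel(sigma: float) -> np.ndarray:
    """Discrete sampled Gaussian, normalized to unit sum."""
    r = _kernel_radius(sigma)
    x = np.arange(-r, r + 1, dtype=np.float64)
    g = np.exp(-0.5 * (x / sigma) ** 2)
    return g / g.sum()


def gaussian_derivative_kernel(sigma: float) -> np.ndarray:
    """Sampled first derivative of a Gaussian, scaled to be exact on ramps.

    The taps are rescaled so that correlating a unit ramp gives slope 1
    (i.e. ``sum(-k * g'(k)) = 1``), which keeps the cost magnitude
    comparable across sigma.
    """
    r = _kernel_radius(sigma)
    x = np.arange(-r, r + 1, dtype=np.float64)
    dg = -(x / sigma**2) * np.exp(-0.5 * (x / sigma) ** 2)
    norm = float(np.sum(-x * dg))
    return dg / norm


@dataclass
class CostVolume:
    """Per-voxel on-surface cost on the analysis grid.

    ``provenance`` is ``"raw"`` for costs at voxel centers and ``"warped"``
    after re-sampling at deformed node positions.
    """

    values: np.ndarray
    sigma: float
    transition: str
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    provenance: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.transition not in TRANSITIONS:
            raise ValueError(f"transition must be one of {TRANSITIONS}")
        if not np.isfinite(self.values).all():
            raise ValueError("cost volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def as_volume(self) -> Volume:
        return Volume(self.values.copy(), self.spacing, dict(self.meta))


def gaussian_derivative_cost(vol: Volume, sigma: float | tuple[float, float, float],
                             transition: str) -> CostVolume:
    """Oriented Gaussian-derivative edge cost along z.

    ``sigma`` may be a scalar (same scale in all three dimensions, the
    usual choice) or a per-axis triple.  Convolution uses reflect padding.
    """
    if np.isscalar(sigma):
        sx = sy = sz = float(sigma)
    else:
        sx, sy, sz = (float(s) for s in sigma)
    if min(sx, sy, sz) <= 0:
        raise ValueError("sigma must be positive")
    if transition not in TRANSITIONS:
        raise ValueError(f"transition must be one of {TRANSITIONS}")
    vol.validate_finite()
    s = 1.0 if transition == "dark_to_bright" else -1.0
    c = vol.data
    c = correlate1d(c, gaussian_kernel(sx), axis=0, mode="reflect")
    c = correlate1d(c, gaussian_kernel(sy), axis=1, mode="reflect")
    # correlate1d computes sum_k w[k]*f[x+k-origin]; flip for convolution
    c = correlate1d(c, gaussian_derivative_kernel(sz)[::-1], axis=2,
                    mode="reflect")
    return CostVolume(-s * c, float(np.mean([sx, sy, sz])), transition,
                      vol.spacing, "raw")


def warp_costs(cost: CostVolume, deformation) -> CostVolume:
    """Re-sample costs at deformed node positions: ``c'(p) = c(p + D(p))``.

    ``deformation`` is a :class:`~subvoxseg.deformation.DeformationField`
    on the same grid, already normalized (no component may exceed half a
    voxel).  Sample positions outside the grid are clamped to the boundary.
    """
    disp = deformation.displacement  # physical units, (X, Y, Z, 3)
    if disp.shape[:3] != cost.shape:
        raise ValueError(
            f"deformation grid {disp.shape[:3]} != cost grid {cost.shape}")
    rel = np.abs(disp) / np.asarray(cost.spacing)
    if (rel > 0.5 + 1e-9).any():
        raise ValueError(
            "deformation is not normalized: max relative displacement "
            f"{rel.max():.6g} exceeds half a voxel")
    if not disp.any():
        return CostVolume(cost.values.copy(), cost.sigma, cost.transition,
                          cost.spacing, "warped", dict(cost.meta))
    grids = np.meshgrid(*[np.arange(n) for n in cost.shape], indexing="ij")
    coords = [g + disp[..., a] / cost.spacing[a]
              for a, g in enumerate(grids)]
    warped = map_coordinates(cost.values,
                             np.stack([c.ravel() for c in coords]),
                             order=1, mode="nearest").reshape(cost.shape)
    return CostVolume(warped, cost.sigma, cost.transition, cost.spacing,
                      "warped", dict(cost.meta))
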