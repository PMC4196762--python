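"""Surface extraction, resampling, thickness maps, and a smoothed baseline.

The upper envelope of the minimum closed set — per column, the top-most
member node — is the optimal surface.  In the deformed (non-Euclidean)
graph the envelope height is the node's deformed coordinate
``z' = k + D_z``, which is where subvoxel accuracy enters; the
conventional graph yields integer heights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import gaussian_filter

from .graph import SegGraph
from .solver import ClosedSet

__all__ = ["SurfaceSet", "ThicknessMap", "extract_surfaces",
           "resample_surface", "thickness_map", "smooth_surface"]

MODES = ("conventional", "non_euclidean", "smoothed_conventional")

#: FWHM-to-sd conversion for the lateral smoothing kernel.
_FWHM_TO_SD = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class SurfaceSet:
    """Real-valued surface heights ``z_s(x, y)`` in analysis-grid voxels."""

    heights: np.ndarray  # (n_surfaces, nx, ny)
    mode: str = "non_euclidean"
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=np.float64)
        if self.heights.ndim != 3:
            raise ValueError("heights must be (n_surfaces, nx, ny)")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    @property
    def n_surfaces(self) -> int:
        return self.heights.shape[0]

    def to_tsv(self, path) -> None:
        from .heights_io import write_heights_tsv

        write_heights_tsv(self.heights, path)

    @classmethod
    def from_tsv(cls, path, mode: str = "non_euclidean") -> "SurfaceSet":
        from .heights_io import read_heights_tsv

        return cls(read_heights_tsv(path), mode)


@dataclass
class ThicknessMap:
    """Per-column thickness ``S(x, y) = z_upper - z_lower`` (NaN = masked)."""

    values: np.ndarray
    pair: tuple[int, int] = (0, 1)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("x\ty\tthickness\n")
            nx, ny = self.values.shape
            for x in range(nx):
                for y in range(ny):
                    v = self.values[x, y]
                    fh.write(f"{x}\t{y}\t"
                             f"{'NA' if not np.isfinite(v) else f'{v:.9g}'}\n")


def extract_surfaces(cs: ClosedSet, g: SegGraph) -> SurfaceSet:
    """Upper envelope of a closed set as real-valued heights.

    Non-Euclidean graphs give the deformed coordinate of the top member
    node; conventional graphs give its integer index.
    """
    X, Y, _ = g.shape
    heights = np.empty((g.n_surfaces, X, Y))
    gx, gy = np.meshgrid(np.arange(X), np.arange(Y), indexing="ij")
    for s in range(g.n_surfaces):
        heights[s] = g.zprime[gx, gy, cs.tops[s]]
    mode = "non_euclidean" if g.deformed else "conventional"
    return SurfaceSet(heights, mode, meta={"total_cost": cs.total_weight})


def resample_surface(s: SurfaceSet, target_grid: tuple[np.ndarray, np.ndarray]
                     ) -> SurfaceSet:
    """Bilinear resampling of the height fields at target column centers.

    ``target_grid`` is ``(x_positions, y_positions)`` in source voxel
    coordinates (centers at integers).  Positions outside the lateral
    extent are clamped to the border (logged upstream by callers).
    """
    tx, ty = (np.asarray(t, dtype=np.float64) for t in target_grid)
    n_surf, nx, ny = s.heights.shape
    tx = np.clip(tx, 0, nx - 1)
    ty = np.clip(ty, 0, ny - 1)
    out = np.empty((n_surf, tx.size, ty.size))
    gx, gy = np.meshgrid(tx, ty, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel()], axis=-1)
    for i in range(n_surf):
        interp = RegularGridInterpolator(
            (np.arange(nx), np.arange(ny)), s.heights[i], method="linear")
        out[i] = interp(pts).reshape(tx.size, ty.size)
    return SurfaceSet(out, s.mode, s.spacing, dict(s.meta))


def thickness_map(s: SurfaceSet, pair: tuple[int, int] = (0, 1),
                  mask: np.ndarray | None = None) -> ThicknessMap:
    """Thickness of the layer bounded by two surfaces, per column."""
    lower, upper = pair
    values = s.heights[upper] - s.heights[lower]
    if np.nanmin(values) < 0:
        raise ValueError("negative thickness: surface ordering violated")
    if mask is not None:
        values = values.copy()
        values[np.asarray(mask, dtype=bool)] = np.nan
    return ThicknessMap(values, pair, s.spacing)


def smooth_surface(s: SurfaceSet, fwhm: float = 2.3548) -> SurfaceSet:
    """Lateral Gaussian smoothing of each height field (baseline method).

    Default FWHM corresponds to an sd of one column.  The mode tag becomes
    ``smoothed_conventional``; smoothing a subvoxel result is permitted but
    not meaningful for the intended baseline comparison.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    sd = fwhm * _FWHM_TO_SD
    sm = np.stack([gaussian_filter(h, sd, mode="nearest")
                   for h in s.heights])
    return SurfaceSet(sm, "smoothed_conventional", s.spacing, dict(s.meta))


def plot_thickness(tm: ThicknessMap, path, title: str = "thickness (voxels)"):
    """Render a thickness heat map to a PNG file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(tm.values.T, origin="lower", aspect="auto", cmap="viridis")
    fig.colorbar(im, ax=ax, label=title)
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_bscan_overlay(volume_slice: np.ndarray, surfaces: list[SurfaceSet],
                       y: int, path, labels: list[str] | None = None):
    """Overlay surface cross-sections on one B-scan image (x along rows)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.imshow(volume_slice.T, origin="lower", aspect="auto", cmap="gray")
    for i, ss in enumerate(surfaces):
        lab = labels[i] if labels else ss.mode
        for s in range(ss.n_surfaces):
            ax.plot(np.arange(ss.heights.shape[1]), ss.heights[s, :, y],
                    label=f"{lab} s{s}")
    ax.set_xlabel("x")
    ax.set_ylabel("z")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
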