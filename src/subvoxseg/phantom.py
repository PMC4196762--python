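"""Synthetic layered-tissue phantoms with continuous ground-truth boundaries.

A phantom is a stack of layers separated by continuous terrain-like
boundary surfaces z_s(x, y), each parameterized as a plane plus a sum of
sinusoids.  Rendering voxelizes the piecewise-constant intensity field
exactly: every voxel takes the analytic average of the layer intensities
over its z-extent, so boundary voxels carry the partial-volume mixture that
subvoxel segmentation exploits.  Additive Gaussian noise is the only noise
model (no speckle or bias fields).

Coordinate convention (used package-wide): voxel centers at integer
coordinates, voxel ``k`` covering ``[k - 0.5, k + 0.5)``; heights are
real-valued z in this frame.

The module also provides the acquisition-emulation chain used for
evaluation: reconstruct the discrete volume with the Keys bicubic kernel,
anti-alias with a Gaussian low-pass, resample at a coarser rate, and map
the continuous reference boundaries into the resampled grid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d, map_coordinates

from .volume import Volume

__all__ = [
    "SurfaceModel",
    "PhantomSpec",
    "GroundTruth",
    "render_phantom",
    "downsample_volume",
    "map_surface_to_grid",
    "unwrap_cylindrical",
    "rewrap_surface",
    "keys_interp1d",
    "preset_spec",
    "PRESET_NAMES",
]

log = logging.getLogger(__name__)

#: Keys bicubic kernel parameter (the standard choice).
KEYS_A = -0.5

#: Anti-alias Gaussian standard deviation, in fine voxels per unit factor.
ANTIALIAS_SD_PER_FACTOR = 0.4


@dataclass
class SurfaceModel:
    """Continuous boundary height ``z(x, y) = offset + tx*x + ty*y + sum_i
    amp_i * sin(2*pi*(fx_i*x + fy_i*y) + phase_i)``."""

    offset: float
    tilt: tuple[float, float] = (0.0, 0.0)
    sinusoids: tuple[tuple[float, float, float, float], ...] = ()
    # each sinusoid: (amplitude, freq_x, freq_y, phase)

    def heights(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        z = self.offset + self.tilt[0] * x + self.tilt[1] * y
        for amp, fx, fy, ph in self.sinusoids:
            z = z + amp * np.sin(2 * np.pi * (fx * x + fy * y) + ph)
        return z


@dataclass
class PhantomSpec:
    """Full description of a synthetic layered volume.

    ``layer_intensities`` has one entry per layer, i.e. ``len(surfaces)+1``;
    layer 0 lies below (smaller z than) the first surface.
    """

    nx: int
    ny: int
    nz: int
    surfaces: tuple[SurfaceModel, ...]
    layer_intensities: tuple[float, ...]
    noise_sd: float = 0.0
    seed: int = 0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    min_margin: float = 0.5

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("voxel counts must be positive")
        if len(self.layer_intensities) != len(self.surfaces) + 1:
            raise ValueError(
                f"need {len(self.surfaces) + 1} layer intensities, "
                f"got {len(self.layer_intensities)}")
        if not all(np.isfinite(self.layer_intensities)):
            raise ValueError("layer intensities must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def height_stack(self) -> np.ndarray:
        """Evaluate all surfaces on the lateral grid -> (n_surf, nx, ny)."""
        x, y = np.meshgrid(np.arange(self.nx), np.arange(self.ny), indexing="ij")
        return np.stack([s.heights(x, y) for s in self.surfaces])

    def validate(self) -> np.ndarray:
        h = self.height_stack()
        if h.size and ((h < 0).any() or (h >= self.nz).any()):
            bad = np.argwhere((h < 0) | (h >= self.nz))[0]
            raise ValueError(
                f"surface {bad[0]} leaves [0, nz) at column "
                f"(x={bad[1]}, y={bad[2]})")
        for s in range(len(self.surfaces) - 1):
            gap = h[s + 1] - h[s]
            if (gap < self.min_margin).any():
                x, y = np.argwhere(gap < self.min_margin)[0]
                raise ValueError(
                    f"surfaces {s} and {s + 1} closer than margin "
                    f"{self.min_margin} at column (x={x}, y={y})")
        return h


@dataclass
class GroundTruth:
    """Continuous reference heights ("reference standard"), one real z per
    surface per lateral column."""

    heights: np.ndarray  # (n_surfaces, nx, ny)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=np.float64)
        if self.heights.ndim != 3:
            raise ValueError("heights must be (n_surfaces, nx, ny)")

    @property
    def n_surfaces(self) -> int:
        return self.heights.shape[0]

    def to_tsv(self, path) -> None:
        from .heights_io import write_heights_tsv

        write_heights_tsv(self.heights, path)

    @classmethod
    def from_tsv(cls, path) -> "GroundTruth":
        from .heights_io import read_heights_tsv

        return cls(read_heights_tsv(path))


def render_phantom(spec: PhantomSpec) -> tuple[Volume, GroundTruth]:
    """Voxelize the layer field exactly and add Gaussian noise.

    Each voxel value is the exact z-average of the piecewise-constant layer
    intensity field over the voxel extent ``[k-0.5, k+0.5)``: with F_s(k)
    the clipped fraction of the voxel below surface s, the value is
    ``sum_l I_l * (F_{l+1} - F_l)`` (F_0 = 0, F_{S+1} = 1), which handles
    single- and multi-crossing voxels alike.
    """
    h = spec.validate()  # (S, nx, ny)
    intens = np.asarray(spec.layer_intensities, dtype=np.float64)
    k = np.arange(spec.nz)
    # frac_below[s, x, y, k]: fraction of voxel k lying below surface s
    frac_below = np.clip(h[..., None] - (k - 0.5), 0.0, 1.0)
    stack = np.concatenate(
        [np.zeros((1, spec.nx, spec.ny, spec.nz)),
         frac_below,
         np.ones((1, spec.nx, spec.ny, spec.nz))], axis=0)
    layer_frac = np.diff(stack, axis=0)  # (S+1, nx, ny, nz)
    data = np.tensordot(intens, layer_frac, axes=(0, 0))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    vol = Volume(data, spec.spacing, {"phantom_seed": spec.seed})
    return vol, GroundTruth(h.copy(), spec.spacing)


# ---------------------------------------------------------------------------
# Keys bicubic reconstruction + anti-aliased resampling


def _keys_weights(u: np.ndarray, a: float = KEYS_A) -> np.ndarray:
    """4-tap Keys cubic weights for fractional offset u in [0, 1)."""
    # taps at offsets (-1-u is distance for tap i-1), order: i-1, i, i+1, i+2
    d = np.stack([u + 1.0, u, 1.0 - u, 2.0 - u])
    w = np.where(
        d <= 1.0,
        (a + 2.0) * d**3 - (a + 3.0) * d**2 + 1.0,
        a * d**3 - 5.0 * a * d**2 + 8.0 * a * d - 4.0 * a,
    )
    return np.where(d < 2.0, w, 0.0)


def keys_interp1d(arr: np.ndarray, positions: np.ndarray, axis: int = 0,
                  a: float = KEYS_A) -> np.ndarray:
    """Evaluate the Keys cubic reconstruction of discrete samples.

    Reflect boundary handling; exact for polynomials up to degree 2
    (degree 1 for any a), and reproduces the samples at integer positions.
    """
    arr = np.moveaxis(np.asarray(arr, dtype=np.float64), axis, -1)
    n = arr.shape[-1]
    pos = np.asarray(positions, dtype=np.float64)
    i0 = np.floor(pos).astype(int)
    u = pos - i0
    w = _keys_weights(u, a)  # (4, m)
    out = np.zeros(arr.shape[:-1] + pos.shape)
    for t in range(4):
        idx = i0 + (t - 1)
        # reflect about edge samples (mirror without repeating the edge)
        idx = np.abs(idx)
        idx = np.where(idx >= n, 2 * (n - 1) - idx, idx)
        idx = np.clip(idx, 0, n - 1)
        out += w[t] * arr[..., idx]
    return np.moveaxis(out, -1, axis)


def coarse_center_positions(n_fine: int, factor: int) -> np.ndarray:
    """Fine-grid coordinates of coarse voxel centers.

    Coarse voxel k covers fine voxels ``[k*f, (k+1)*f)``; with voxel centers
    at integers its center maps to fine coordinate ``k*f + (f-1)/2``.
    Trailing fine voxels that do not fill a coarse voxel are dropped.
    """
    n_coarse = n_fine // factor
    if n_coarse < 1:
        raise ValueError(f"factor {factor} larger than axis length {n_fine}")
    return np.arange(n_coarse) * factor + (factor - 1) / 2.0


def downsample_volume(vol: Volume, factors: tuple[int, int, int],
                      antialias: bool = True) -> Volume:
    """Downsample by integer factors: reconstruct (Keys bicubic) ->
    Gaussian anti-alias (sd = 0.4*factor per decimated axis) -> resample at
    coarse voxel centers.

    The Gaussian is applied to the discrete samples, which by commutation of
    convolutions equals low-pass filtering the continuous reconstruction
    before resampling.  Non-divisible trailing samples are dropped (logged).
    """
    factors = tuple(int(f) for f in factors)
    if any(f < 1 for f in factors):
        raise ValueError(f"factors must be >= 1, got {factors}")
    data = vol.data
    for ax, f in enumerate(factors):
        if data.shape[ax] % f:
            log.warning("axis %d length %d not divisible by %d; dropping "
                        "trailing samples", ax, data.shape[ax], f)
        if antialias and f > 1:
            data = gaussian_filter1d(data, ANTIALIAS_SD_PER_FACTOR * f,
                                     axis=ax, mode="reflect")
        pos = coarse_center_positions(vol.shape[ax], f)
        if f == 1 and float(pos[0]) == 0.0:
            data = np.take(data, np.arange(len(pos)), axis=ax)
        else:
            data = keys_interp1d(data, pos, axis=ax)
    spacing = tuple(s * f for s, f in zip(vol.spacing, factors))
    return Volume(data, spacing, dict(vol.meta, downsampled_by=factors))


def map_surface_to_grid(gt: GroundTruth, factors: tuple[int, int, int],
                        offset_convention: str | tuple = "center") -> GroundTruth:
    """Map high-resolution reference heights onto the resampled grid.

    Lateral: heights are sampled by bilinear interpolation at the fine-grid
    positions of coarse column centers.  Axial: ``z_coarse =
    (z_fine - off_z) / f_z`` with ``off = (f - 1)/2`` per axis under the
    voxel-center convention (an explicit 3-tuple of offsets may be passed
    instead).
    """
    fx, fy, fz = (int(f) for f in factors)
    if offset_convention == "center":
        off = tuple((f - 1) / 2.0 for f in (fx, fy, fz))
    else:
        off = tuple(float(o) for o in offset_convention)
    n_surf, nx, ny = gt.heights.shape
    px = coarse_center_positions(nx, fx)
    py = coarse_center_positions(ny, fy)
    gx, gy = np.meshgrid(px, py, indexing="ij")
    coords = np.stack([gx.ravel(), gy.ravel()])
    mapped = np.empty((n_surf, len(px), len(py)))
    for s in range(n_surf):
        vals = map_coordinates(gt.heights[s], coords, order=1, mode="nearest")
        mapped[s] = vals.reshape(len(px), len(py))
    mapped = (mapped - off[2]) / fz
    spacing = tuple(s * f for s, f in zip(gt.spacing, (fx, fy, fz)))
    return GroundTruth(mapped, spacing, dict(gt.meta, mapped_by=(fx, fy, fz)))


# ---------------------------------------------------------------------------
# Cylindrical unwrapping (vessel-wall style volumes)


def unwrap_cylindrical(vol: Volume, center_xy: tuple[float, float],
                       n_angles: int, max_radius: float) -> Volume:
    """Unwrap a volume around a lateral center into (angle, z, radius) axes.

    Rays leave ``center_xy`` in the (x, y) plane at ``n_angles`` evenly
    spaced angles; values are bilinearly interpolated at unit radius steps.
    A closed, star-shaped contour per z-slice becomes a terrain-like surface
    radius(angle, z) in the output, which the standard pipeline can segment;
    :func:`rewrap_surface` maps such a surface back to lateral contours.
    """
    cx, cy = center_xy
    nx, ny, nz = vol.shape
    if not (0 <= cx <= nx - 1 and 0 <= cy <= ny - 1):
        raise ValueError(f"center {center_xy} outside lateral field of view")
    limit = min(cx, nx - 1 - cx, cy, ny - 1 - cy)
    if max_radius > limit:
        log.warning("max_radius %.3g exceeds volume; clipped to %.3g",
                    max_radius, limit)
        max_radius = limit
    n_r = int(math.floor(max_radius)) + 1
    theta = np.linspace(0.0, 2 * np.pi, n_angles, endpoint=False)
    r = np.arange(n_r, dtype=np.float64)
    tt, rr = np.meshgrid(theta, r, indexing="ij")
    px = cx + rr * np.cos(tt)
    py = cy + rr * np.sin(tt)
    out = np.empty((n_angles, nz, n_r))
    for z in range(nz):
        out[:, z, :] = map_coordinates(
            vol.data[:, :, z], np.stack([px.ravel(), py.ravel()]),
            order=1, mode="nearest").reshape(n_angles, n_r)
    meta = dict(vol.meta, unwrap_center=(cx, cy), unwrap_n_angles=n_angles)
    return Volume(out, (1.0, vol.spacing[2], 1.0), meta)


def rewrap_surface(radii: np.ndarray, center_xy: tuple[float, float]
                   ) -> np.ndarray:
    """Map an unwrapped surface radius(angle, z) back to lateral contours.

    Returns an array ``(n_angles, nz, 2)`` of (x, y) contour points.
    """
    radii = np.asarray(radii, dtype=np.float64)
    n_angles = radii.shape[0]
    theta = np.linspace(0.0, 2 * np.pi, n_angles, endpoint=False)
    cx, cy = center_xy
    x = cx + radii * np.cos(theta)[:, None]
    y = cy + radii * np.sin(theta)[:, None]
    return np.stack([x, y], axis=-1)


# ---------------------------------------------------------------------------
# Presets

PRESET_NAMES = ("flat", "sinusoid", "two_layer")


def preset_spec(name: str, seed: int = 0, highres: bool = False) -> PhantomSpec:
    """Benchmark phantom presets.

    ``flat``: single flat boundary with a seed-dependent subvoxel phase.
    ``sinusoid``: single gently curved boundary.
    ``two_layer``: two coupled boundaries (both dark-to-bright transitions,
    separation within [3, 8] analysis voxels) emulating a thin bright tissue
    layer; random subvoxel phase and sinusoid phases per seed.

    With ``highres=True`` the same geometry is rendered at 10x z-sampling,
    suitable for the reconstruct/anti-alias/resample chain with z factor 10.
    """
    rng = np.random.default_rng(seed)
    zf = 10 if highres else 1
    if name == "flat":
        phase = rng.uniform(0.0, 1.0)
        return PhantomSpec(
            nx=16, ny=8, nz=24 * zf,
            surfaces=(SurfaceModel(offset=(10.0 + phase) * zf),),
            layer_intensities=(0.0, 1.0),
            noise_sd=0.0, seed=seed,
        )
    if name == "sinusoid":
        phase = rng.uniform(0.0, 1.0)
        ph1 = rng.uniform(0, 2 * np.pi)
        return PhantomSpec(
            nx=24, ny=8, nz=28 * zf,
            surfaces=(SurfaceModel(
                offset=(12.0 + phase) * zf, tilt=(0.0, 0.0),
                sinusoids=(((1.5 * zf), 1 / 24.0, 0.0, ph1),)),),
            layer_intensities=(0.05, 0.95),
            noise_sd=0.02, seed=seed,
        )
    if name == "two_layer":
        phase = rng.uniform(0.0, 1.0)
        ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
        top = SurfaceModel(
            offset=(11.0 + phase) * zf, tilt=(0.04 * zf, 0.03 * zf),
            sinusoids=((1.2 * zf, 1 / 16.0, 0.0, ph1),))
        bottom = SurfaceModel(
            offset=(16.5 + phase) * zf, tilt=(0.04 * zf, 0.03 * zf),
            sinusoids=((1.2 * zf, 1 / 16.0, 0.0, ph1),
                       (0.7 * zf, 1 / 20.0, 0.0, ph2)))
        return PhantomSpec(
            nx=20, ny=8, nz=32 * zf,
            surfaces=(top, bottom),
            layer_intensities=(0.0, 0.5, 1.0),
            noise_sd=0.02, seed=seed,
        )
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
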