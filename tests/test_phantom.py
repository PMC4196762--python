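"""Phantom rendering, downsampling chain, surface mapping, unwrapping."""

import numpy as np
import pytest

from subvoxseg.phantom import (GroundTruth, PhantomSpec, SurfaceModel,
                               coarse_center_positions, downsample_volume,
                               keys_interp1d, map_surface_to_grid,
                               preset_spec, render_phantom, rewrap_surface,
                               unwrap_cylindrical)
from subvoxseg.volume import Volume


def flat_spec(offset, nz=8, nx=4, ny=3, intensities=(0.0, 1.0)):
    return PhantomSpec(nx=nx, ny=ny, nz=nz,
                       surfaces=(SurfaceModel(offset=offset),),
                       layer_intensities=intensities, noise_sd=0.0)


class TestRenderPhantom:
    def test_boundary_on_voxel_edge_no_partial_volume(self):
        # boundary at 2.5 is the edge between voxels 2 and 3 (centers at
        # integers): values are exactly 0 below index 3 and 1 from 3 up
        vol, gt = render_phantom(flat_spec(2.5))
        assert np.array_equal(vol.data[..., :3], np.zeros((4, 3, 3)))
        assert np.array_equal(vol.data[..., 3:], np.ones((4, 3, 5)))
        assert np.all(gt.heights == 2.5)

    def test_single_crossing_partial_volume_fraction(self):
        # boundary at 1.8 inside voxel 2 ([1.5, 2.5)): fraction below is
        # 0.3, so the voxel value is 0.3*0 + 0.7*1 = 0.7; neighbors pure
        vol, _ = render_phantom(flat_spec(1.8))
        assert np.allclose(vol.data[..., 2], 0.7, atol=1e-12)
        assert np.all(vol.data[..., 1] == 0.0)
        assert np.all(vol.data[..., 3] == 1.0)

    def test_supersampling_oracle_sinusoid(self):
        spec = PhantomSpec(
            nx=6, ny=4, nz=10,
            surfaces=(SurfaceModel(offset=4.2,
                                   sinusoids=((1.1, 0.15, 0.07, 0.5),)),),
            layer_intensities=(0.1, 0.9), noise_sd=0.0)
        vol, gt = render_phantom(spec)
        ss = 4096
        sub = (np.arange(ss) + 0.5) / ss - 0.5
        zs = np.arange(10)[:, None] + sub  # (nz, ss) subsample positions
        h = gt.heights[0][..., None, None]  # (nx, ny, 1, 1)
        oracle = np.where(zs < h, 0.1, 0.9).mean(axis=-1)
        assert np.abs(oracle - vol.data).max() < 1e-3

    def test_mean_conservation(self):
        spec = flat_spec(3.7, nz=10)
        vol, _ = render_phantom(spec)
        # column integral: layer 0 spans [-0.5, 3.7), layer 1 [3.7, 9.5)
        expected = (0.0 * (3.7 + 0.5) + 1.0 * (9.5 - 3.7)) / 10
        assert np.allclose(vol.data.mean(axis=2), expected, atol=1e-9)

    def test_determinism(self):
        spec = preset_spec("two_layer", 42)
        v1, g1 = render_phantom(spec)
        v2, g2 = render_phantom(preset_spec("two_layer", 42))
        assert np.array_equal(v1.data, v2.data)
        assert np.array_equal(g1.heights, g2.heights)

    def test_surface_order_validation_names_column(self):
        spec = PhantomSpec(
            nx=3, ny=2, nz=10,
            surfaces=(SurfaceModel(offset=5.0), SurfaceModel(offset=4.0)),
            layer_intensities=(0.0, 0.5, 1.0), noise_sd=0.0)
        with pytest.raises(ValueError, match="closer than margin"):
            render_phantom(spec)

    def test_out_of_bounds_validation(self):
        with pytest.raises(ValueError, match="leaves"):
            render_phantom(flat_spec(9.0, nz=8))


class TestKeysInterpolation:
    def test_reproduces_samples_at_integers(self):
        rng = np.random.default_rng(0)
        arr = rng.normal(size=20)
        out = keys_interp1d(arr, np.arange(20))
        assert np.allclose(out, arr, atol=1e-12)

    def test_exact_on_linear_ramp(self):
        arr = 0.7 * np.arange(30) - 2.0
        pos = np.linspace(2.0, 27.0, 40)
        out = keys_interp1d(arr, pos)
        assert np.allclose(out, 0.7 * pos - 2.0, atol=1e-10)


class TestDownsample:
    def test_identity_factors(self):
        rng = np.random.default_rng(1)
        vol = Volume(rng.normal(size=(5, 4, 6)))
        out = downsample_volume(vol, (1, 1, 1), antialias=False)
        assert np.array_equal(out.data, vol.data)

    def test_constant_preserved(self):
        vol = Volume(np.full((8, 6, 20), 3.25))
        out = downsample_volume(vol, (2, 3, 10))
        assert np.allclose(out.data, 3.25, atol=1e-10)
        assert out.shape == (4, 2, 2)
        assert out.spacing == (2.0, 3.0, 10.0)

    def test_ramp_oracle(self):
        # a linear ramp is invariant under the whole chain away from the
        # borders: symmetric normalized anti-alias kernel and the Keys
        # kernel both reproduce linear functions exactly
        n, f = 200, 10
        a, b = 0.37, 2.0
        vol = Volume((a * np.arange(n) + b).reshape(1, 1, n))
        out = downsample_volume(vol, (1, 1, f))
        pos = coarse_center_positions(n, f)
        expected = a * pos + b
        # anti-alias radius is 4 * (0.4 * f) = 16 fine voxels; skip coarse
        # samples whose stencil reaches a border
        interior = slice(2, -2)
        err = np.abs(out.data[0, 0] - expected)
        assert err[interior].max() < 1e-6

    def test_nondivisible_drops_trailing(self):
        vol = Volume(np.zeros((7, 3, 4)))
        out = downsample_volume(vol, (2, 1, 1))
        assert out.shape == (3, 3, 4)

    def test_invalid_factor(self):
        with pytest.raises(ValueError, match="factors"):
            downsample_volume(Volume(np.zeros((4, 4, 4))), (0, 1, 1))


class TestMapSurfaceToGrid:
    def test_identity(self):
        gt = GroundTruth(np.full((1, 4, 3), 2.25))
        out = map_surface_to_grid(gt, (1, 1, 1))
        assert np.allclose(out.heights, gt.heights)

    def test_center_phase_offset(self):
        # flat height 23.0, z-factor 10, voxel-center convention:
        # (23.0 - 4.5) / 10 = 1.85
        gt = GroundTruth(np.full((1, 10, 10), 23.0))
        out = map_surface_to_grid(gt, (1, 1, 10))
        assert np.allclose(out.heights, 1.85, atol=1e-12)

    def test_plane_stays_plane(self):
        x, y = np.meshgrid(np.arange(12), np.arange(8), indexing="ij")
        gt = GroundTruth((30.0 + 1.5 * x - 0.8 * y)[None])
        out = map_surface_to_grid(gt, (2, 2, 10))
        h = out.heights[0]
        # second differences of a plane vanish
        assert np.allclose(np.diff(h, n=2, axis=0), 0.0, atol=1e-9)
        assert np.allclose(np.diff(h, n=2, axis=1), 0.0, atol=1e-9)


class TestUnwrapCylindrical:
    nx = ny = 33
    cx = cy = 16.0
    r = 6.3

    def _crossings(self, unwrapped, level, rising=False):
        vals = unwrapped.data[:, 1, :]
        out = []
        for v in vals:
            j = (np.where(v > level)[0] if rising else np.where(v < level)[0])
            j0 = j[j > 0].min()
            t = (level - v[j0 - 1]) / (v[j0] - v[j0 - 1])
            out.append(j0 - 1 + t)
        return np.array(out)

    def test_concentric_cylinder_flat_surface(self):
        xx, yy = np.meshgrid(np.arange(self.nx), np.arange(self.ny),
                             indexing="ij")
        inside = ((xx - self.cx) ** 2 + (yy - self.cy) ** 2) < self.r ** 2
        vol = Volume(np.repeat(inside[..., None] * 1.0, 3, axis=2))
        u = unwrap_cylindrical(vol, (self.cx, self.cy), 64, 12.0)
        cross = self._crossings(u, 0.5)
        assert np.abs(cross - self.r).max() < 0.5

    def test_rewrap_roundtrip_circle(self):
        xx, yy = np.meshgrid(np.arange(self.nx), np.arange(self.ny),
                             indexing="ij")
        inside = ((xx - self.cx) ** 2 + (yy - self.cy) ** 2) < self.r ** 2
        vol = Volume(np.repeat(inside[..., None] * 1.0, 3, axis=2))
        u = unwrap_cylindrical(vol, (self.cx, self.cy), 64, 12.0)
        cross = self._crossings(u, 0.5)
        pts = rewrap_surface(cross, (self.cx, self.cy))
        dev = np.abs(np.hypot(pts[:, 0, 0] - self.cx,
                              pts[:, 0, 1] - self.cy) - self.r)
        assert dev.max() < 0.5

    def test_off_center_circle_polar_equation(self):
        d = 2.0
        xx, yy = np.meshgrid(np.arange(self.nx), np.arange(self.ny),
                             indexing="ij")
        dist = np.hypot(xx - (self.cx + d), yy - self.cy)
        vol = Volume(np.repeat(dist[..., None], 3, axis=2))
        u = unwrap_cylindrical(vol, (self.cx, self.cy), 64, 12.0)
        cross = self._crossings(u, self.r, rising=True)
        theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        rho = d * np.cos(theta) + np.sqrt(
            self.r ** 2 - d ** 2 * np.sin(theta) ** 2)
        assert np.abs(cross - rho).max() < 0.1

    def test_center_outside_error_and_radius_clip(self):
        vol = Volume(np.zeros((9, 9, 2)))
        with pytest.raises(ValueError, match="center"):
            unwrap_cylindrical(vol, (20.0, 4.0), 16, 3.0)
        u = unwrap_cylindrical(vol, (4.0, 4.0), 16, 100.0)  # clipped
        assert u.shape[2] <= 5


def test_preset_unknown_name():
    with pytest.raises(ValueError, match="unknown preset"):
        preset_spec("nope")
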