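"""3D scalar volume container and file I/O.

The canonical in-memory layout is a float array indexed ``(x, y, z)`` with
per-axis physical spacing.  ``z`` is the column ("A-scan") axis along which
surfaces are single-valued; "below" means smaller ``z``.  Voxel centers sit
at integer coordinates, so voxel ``k`` covers the half-open interval
``[k - 0.5, k + 0.5)`` along each axis.

Supported formats: NIfTI (``.nii``/``.nii.gz``) via nibabel, multi-page TIFF
via tifffile (pages are z-slices), and raw binary with a JSON sidecar
describing dtype/shape/spacing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Volume", "read_volume", "write_volume"]


@dataclass
class Volume:
    """A 3D scalar grid with per-axis physical spacing.

    Parameters
    ----------
    data
        Array of shape ``(nx, ny, nz)``; converted to float64.
    spacing
        Physical size of one voxel along (x, y, z). Defaults to isotropic 1.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive scalars, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def validate_finite(self) -> None:
        bad = ~np.isfinite(self.data)
        if bad.any():
            idx = tuple(int(i) for i in np.argwhere(bad)[0])
            raise ValueError(
                f"volume contains {int(bad.sum())} non-finite voxels; first at {idx}"
            )

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.spacing, dict(self.meta))


def read_volume(path: str | Path) -> Volume:
    """Read a volume from NIfTI, TIFF, or raw+JSON sidecar."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        zooms = img.header.get_zooms()[:3]
        return Volume(data, tuple(float(z) for z in zooms), {"source": str(path)})
    if name.endswith((".tif", ".tiff")):
        import tifffile

        pages = tifffile.imread(str(path))  # (z, y, x) by TIFF convention
        if pages.ndim == 2:
            pages = pages[None]
        data = np.transpose(pages, (2, 1, 0)).astype(np.float64)
        return Volume(data, (1.0, 1.0, 1.0), {"source": str(path)})
    if name.endswith(".raw"):
        sidecar = path.with_suffix(".json")
        with open(sidecar) as fh:
            info = json.load(fh)
        data = np.fromfile(path, dtype=np.dtype(info["dtype"]))
        data = data.reshape(tuple(info["shape"]))  # stored (x, y, z) C-order
        return Volume(data, tuple(info.get("spacing", (1.0, 1.0, 1.0))),
                      {"source": str(path)})
    raise ValueError(f"unsupported volume format: {path}")


def write_volume(vol: Volume, path: str | Path) -> None:
    """Write a volume; format chosen by extension (see :func:`read_volume`)."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag(list(vol.spacing) + [1.0])
        nib.save(nib.Nifti1Image(vol.data, affine), str(path))
    elif name.endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(str(path), np.transpose(vol.data, (2, 1, 0)).astype(np.float32))
    elif name.endswith(".raw"):
        vol.data.astype(np.float64).tofile(path)
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(
                {"dtype": "float64", "shape": list(vol.shape),
                 "spacing": list(vol.spacing)}, fh, indent=2)
    else:
        raise ValueError(f"unsupported volume format: {path}")
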