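"""TSV serialization shared by ground-truth and segmented surface heights.

Format: comment header lines ``#surface_id<TAB><id>`` (one per surface),
then rows ``x<TAB>y<TAB>surface_id<TAB>z`` with real-valued z. Missing
values are written as ``NA``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_heights_tsv", "read_heights_tsv"]


def write_heights_tsv(heights: np.ndarray, path: str | Path) -> None:
    """Write a ``(n_surfaces, nx, ny)`` height stack to TSV."""
    heights = np.asarray(heights, dtype=np.float64)
    n_surf, nx, ny = heights.shape
    with open(path, "w") as fh:
        for s in range(n_surf):
            fh.write(f"#surface_id\t{s}\n")
        fh.write("x\ty\tsurface_id\tz\n")
        for s in range(n_surf):
            for x in range(nx):
                for y in range(ny):
                    z = heights[s, x, y]
                    zs = "NA" if not np.isfinite(z) else f"{z:.9g}"
                    fh.write(f"{x}\t{y}\t{s}\t{zs}\n")


def read_heights_tsv(path: str | Path) -> np.ndarray:
    """Read a height stack written by :func:`write_heights_tsv`."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("x\t"):
                continue
            x, y, s, z = line.split("\t")
            rows.append((int(x), int(y), int(s), np.nan if z == "NA" else float(z)))
    if not rows:
        raise ValueError(f"no height rows in {path}")
    arr = np.array(rows, dtype=object)
    nx = int(max(r[0] for r in rows)) + 1
    ny = int(max(r[1] for r in rows)) + 1
    ns = int(max(r[2] for r in rows)) + 1
    out = np.full((ns, nx, ny), np.nan)
    for x, y, s, z in rows:
        out[s, x, y] = z
    return out
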