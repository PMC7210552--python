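"""Plain-text readers/writers for the pipeline's exchange formats.

Formats: legacy ASCII VTK polydata (surfaces + per-cell/per-point data),
contour CSV (slice_index, point_index, x_px, y_px), waveform CSV, and
numbered PNG image stacks.
"""

from __future__ import annotations

import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "write_vtk_polydata",
    "write_contours_csv",
    "read_contours_csv",
    "write_image_stack",
    "read_image_stack",
]


def write_vtk_polydata(
    path,
    vertices: np.ndarray,
    faces: np.ndarray,
    cell_data: dict[str, np.ndarray] | None = None,
    point_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write a triangle surface as legacy ASCII VTK polydata."""
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("eecp-hemoflow surface\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(vertices)} float\n")
        for p in vertices:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        fh.write(f"POLYGONS {len(faces)} {4 * len(faces)}\n")
        for tri in faces:
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
        if cell_data:
            fh.write(f"CELL_DATA {len(faces)}\n")
            for name, arr in cell_data.items():
                arr = np.asarray(arr)
                kind = "int" if np.issubdtype(arr.dtype, np.integer) else "float"
                fh.write(f"SCALARS {name} {kind} 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{v:.9g}" if kind == "float" else str(int(v)) for v in arr))
                fh.write("\n")
        if point_data:
            fh.write(f"POINT_DATA {len(vertices)}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr, dtype=float)
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{v:.9g}" for v in arr))
                fh.write("\n")


def write_contours_csv(path, contours) -> None:
    """Write a list of closed contours, one row per vertex.

    Columns: slice_index, point_index, x_px, y_px.
    """
    rows = []
    for s, c in enumerate(contours):
        xy = np.asarray(c, dtype=float)
        for i, (x, y) in enumerate(xy):
            rows.append((s, i, x, y))
    pd.DataFrame(rows, columns=["slice_index", "point_index", "x_px", "y_px"]).to_csv(
        path, index=False
    )


def read_contours_csv(path) -> list[np.ndarray]:
    df = pd.read_csv(path)
    out = []
    for s in sorted(df["slice_index"].unique()):
        sub = df[df["slice_index"] == s].sort_values("point_index")
        out.append(sub[["x_px", "y_px"]].to_numpy(dtype=float))
    return out


def write_image_stack(directory, stack: np.ndarray) -> list[Path]:
    """Write a (n_slices, h, w) float stack as zero-padded 8-bit PNGs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    lo, hi = float(stack.min()), float(stack.max())
    scale = 255.0 / (hi - lo) if hi > lo else 1.0
    for i, sl in enumerate(stack):
        img = np.clip((sl - lo) * scale, 0, 255).astype(np.uint8)
        p = directory / f"slice_{i:04d}.png"
        iio.imwrite(p, img)
        paths.append(p)
    return paths


def read_image_stack(directory) -> np.ndarray:
    paths = sorted(Path(directory).glob("slice_*.png"))
    if not paths:
        raise FileNotFoundError(f"no slice_*.png files under {directory}")
    return np.stack([iio.imread(p).astype(float) for p in paths])
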