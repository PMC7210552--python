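"""Triangulated lumen-wall surfaces with boundary labels.

``SurfaceMesh`` is the common container for every wall surface in the
pipeline: the synthetic bifurcation solid, lofted contour tubes, and the
combined/extended geometry handed to post-processing.  Faces carry an
integer boundary label (wall / inlet / outlet / inlet extension) matching
the ``boundary_id`` cell data written to VTK.

Heavy mesh queries (areas, volume, watertightness, plane sections) are
delegated to :mod:`trimesh`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

__all__ = [
    "SurfaceMesh",
    "LABEL_WALL",
    "LABEL_INLET",
    "LABEL_OUTLET",
    "LABEL_EXTENSION",
    "boundary_loops",
    "zipper_loops",
    "ring_radius",
]

LABEL_WALL = 0
LABEL_INLET = 1
LABEL_OUTLET = 2
LABEL_EXTENSION = 3


@dataclass
class SurfaceMesh:
    """Triangle surface with per-face boundary labels.

    Attributes
    ----------
    vertices : (n, 3) float array, metres
    faces : (m, 3) int array, consistently wound (outward normals)
    face_labels : (m,) int array of LABEL_* codes
    rings : optional ordered vertex-id loops (axial cross-section rings) kept
        for structured tube meshes; ``rings[0]`` is the proximal (inlet-side)
        ring.  ``None`` for unstructured meshes.
    """

    vertices: np.ndarray
    faces: np.ndarray
    face_labels: np.ndarray | None = None
    rings: list[np.ndarray] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.face_labels is None:
            self.face_labels = np.full(len(self.faces), LABEL_WALL, dtype=np.int64)
        else:
            self.face_labels = np.asarray(self.face_labels, dtype=np.int64)
        if len(self.face_labels) != len(self.faces):
            raise ValueError("face_labels must have one entry per face")

    # -- conversions ---------------------------------------------------

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(
            self.vertices.copy(),
            self.faces.copy(),
            self.face_labels.copy(),
            None if self.rings is None else [r.copy() for r in self.rings],
            dict(self.meta),
        )

    # -- measures ------------------------------------------------------

    def area(self, label: int | None = None) -> float:
        tm = self.as_trimesh()
        if label is None:
            return float(tm.area)
        return float(tm.area_faces[self.face_labels == label].sum())

    def euler_characteristic(self) -> int:
        tm = self.as_trimesh()
        tm.merge_vertices()
        return int(tm.euler_number)

    def is_watertight(self) -> bool:
        tm = self.as_trimesh()
        tm.merge_vertices()
        return bool(tm.is_watertight)

    def face_normals(self) -> np.ndarray:
        return self.as_trimesh().face_normals

    def vertex_normals(self) -> np.ndarray:
        return self.as_trimesh().vertex_normals

    # -- boundary handling ---------------------------------------------

    def boundary_loops(self) -> list[np.ndarray]:
        return boundary_loops(self.faces)

    def capped(self, cap_label: int = LABEL_INLET) -> "SurfaceMesh":
        """Close every boundary loop with a centroid fan.

        Cap faces inherit ``cap_label``; the original faces keep theirs.
        """
        verts = [self.vertices]
        faces = [self.faces]
        labels = [self.face_labels]
        n = len(self.vertices)
        for loop in self.boundary_loops():
            centroid = self.vertices[loop].mean(axis=0)
            verts.append(centroid[None, :])
            cid = n
            n += 1
            # boundary edge (a, b) is traversed as (a, b) by its owning face;
            # the cap triangle (b, a, c) keeps the outward winding
            fan = np.array(
                [[loop[(i + 1) % len(loop)], loop[i], cid] for i in range(len(loop))]
            )
            faces.append(fan)
            labels.append(np.full(len(fan), cap_label, dtype=np.int64))
        return SurfaceMesh(
            np.vstack(verts), np.vstack(faces), np.concatenate(labels)
        )

    # -- IO ------------------------------------------------------------

    def save_stl(self, path) -> None:
        self.as_trimesh().export(path, file_type="stl_ascii")

    def save_vtk(self, path) -> None:
        from .io import write_vtk_polydata

        write_vtk_polydata(
            path, self.vertices, self.faces, cell_data={"boundary_id": self.face_labels}
        )


def boundary_loops(faces: np.ndarray) -> list[np.ndarray]:
    """Ordered vertex loops of the open boundary of a triangle mesh.

    A boundary edge is one used by exactly one face; loops follow the faces'
    winding direction.
    """
    edge_count: dict[tuple[int, int], int] = {}
    directed: dict[int, int] = {}
    for tri in faces:
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            key = (min(a, b), max(a, b))
            edge_count[key] = edge_count.get(key, 0) + 1
    for tri in faces:
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            if edge_count[(min(a, b), max(a, b))] == 1:
                directed[int(a)] = int(b)
    loops = []
    visited: set[int] = set()
    for start in list(directed):
        if start in visited:
            continue
        loop = [start]
        visited.add(start)
        nxt = directed[start]
        while nxt != start:
            loop.append(nxt)
            visited.add(nxt)
            nxt = directed[nxt]
        loops.append(np.array(loop, dtype=np.int64))
    return loops


def zipper_loops(
    pts_a: np.ndarray, pts_b: np.ndarray, ids_a: np.ndarray, ids_b: np.ndarray
) -> np.ndarray:
    """Triangulate the band between two closed 3D loops (greedy zipper).

    Classic contour-stitching: start from the closest vertex pair, then at
    each step advance along whichever loop yields the shorter new diagonal.
    Loops may have different vertex counts but must run in the same
    direction around the tube axis.  Returns (k, 3) triangles of vertex ids
    wound as (a, a_next, b) so that, for loop A proximal and loop B distal
    with both counter-clockwise viewed from distal, normals point outward.
    """
    na, nb = len(pts_a), len(pts_b)
    d = np.linalg.norm(pts_a[:, None, :] - pts_b[None, :, :], axis=2)
    ia0, ib0 = np.unravel_index(np.argmin(d), d.shape)
    tris = []
    ia, ib = 0, 0  # steps taken along each loop
    while ia < na or ib < nb:
        a_cur = (ia0 + ia) % na
        b_cur = (ib0 + ib) % nb
        a_nxt = (ia0 + ia + 1) % na
        b_nxt = (ib0 + ib + 1) % nb
        adv_a = d[a_nxt, b_cur] if ia < na else np.inf
        adv_b = d[a_cur, b_nxt] if ib < nb else np.inf
        if adv_a <= adv_b:
            tris.append((ids_a[a_cur], ids_a[a_nxt], ids_b[b_cur]))
            ia += 1
        else:
            tris.append((ids_a[a_cur], ids_b[b_nxt], ids_b[b_cur]))
            ib += 1
    return np.array(tris, dtype=np.int64)


def ring_radius(points: np.ndarray) -> float:
    """Mean distance of ring points to their centroid (the 'averaged radius')."""
    c = points.mean(axis=0)
    return float(np.linalg.norm(points - c, axis=1).mean())
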