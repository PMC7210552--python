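"""3D wall reconstruction from contour stacks.

Lofting joins per-slice endothelial contours into a structured tube
surface: adjacent rings are resampled to a common uniform-arclength
vertex count, rotationally aligned by minimizing the summed squared
inter-ring distance over cyclic shifts, and stitched with triangle
strips.  Bifurcation branch tubes are merged at a Y-junction with a
pants-style triangulation (the trunk's distal ring is split at two saddle
vertices and each half, closed by a shared seam, is zippered to one
branch ring).  The inlet is extruded outward along its mean normal by
five times its averaged radius so the prescribed inlet waveform can
develop before reaching the region of interest.

A simplified surface-of-revolution flattening maps single-branch tubes
to an (angle, axial-arclength) chart with a radius channel, used for
plaque localization and for painting wall fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .mesh import (
    LABEL_EXTENSION,
    LABEL_INLET,
    LABEL_OUTLET,
    LABEL_WALL,
    SurfaceMesh,
    ring_radius,
    zipper_loops,
)
from .segment import resample_closed

__all__ = [
    "FlatMap",
    "loft_contours",
    "combine_branches",
    "extend_inlet",
    "flatten_surface",
]


# ---------------------------------------------------------------------------
# lofting
# ---------------------------------------------------------------------------


def _ensure_ccw(xy: np.ndarray) -> np.ndarray:
    area2 = np.sum(xy[:, 0] * np.roll(xy[:, 1], -1) - np.roll(xy[:, 0], -1) * xy[:, 1])
    return xy[::-1] if area2 < 0 else xy


def _best_shift(prev: np.ndarray, ring: np.ndarray) -> int:
    """Cyclic shift of ``ring`` minimizing summed squared distance to ``prev``."""
    n = len(ring)
    costs = [
        np.sum((np.roll(ring, -k, axis=0) - prev) ** 2) for k in range(n)
    ]
    return int(np.argmin(costs))


def loft_contours(
    contours,
    slice_spacing: float,
    pixel_size: float = 1.0,
    center_px: tuple[float, float] = (0.0, 0.0),
    z0: float = 0.0,
    n_ring: int = 128,
) -> SurfaceMesh:
    """Loft a stack of closed planar contours into an open tube surface.

    Contours are (x_px, y_px) vertex arrays in slice pixel coordinates;
    physical coordinates are ``(xy - center_px) * pixel_size`` with slice k
    at ``z = z0 + k * slice_spacing``.  Pass ``pixel_size=1`` to loft
    contours already expressed in metres.  The returned mesh keeps its
    cross-section rings (``rings[0]`` proximal) and is all wall faces.
    """
    if len(contours) < 3:
        raise ValueError("need at least 3 contours to loft")
    rings_xy = []
    for c in contours:
        xy = resample_closed(np.asarray(c, dtype=float), n_ring)
        rings_xy.append(_ensure_ccw(xy))
    verts = []
    ring_ids = []
    prev3 = None
    for k, xy in enumerate(rings_xy):
        phys = (xy - np.asarray(center_px)) * pixel_size
        ring3 = np.column_stack(
            [phys[:, 0], phys[:, 1], np.full(n_ring, z0 + k * slice_spacing)]
        )
        if prev3 is not None:
            # rotational correspondence against the previous (already
            # aligned) ring, compared in-plane
            shift = _best_shift(prev3[:, :2], ring3[:, :2])
            ring3 = np.roll(ring3, -shift, axis=0)
            if _rings_cross(prev3, ring3):
                raise ValueError(f"contours {k-1} and {k} cross after alignment")
        ids = np.arange(k * n_ring, (k + 1) * n_ring, dtype=np.int64)
        verts.append(ring3)
        ring_ids.append(ids)
        prev3 = ring3
    faces = []
    for k in range(len(rings_xy) - 1):
        a, b = ring_ids[k], ring_ids[k + 1]
        for i in range(n_ring):
            j = (i + 1) % n_ring
            faces.append((a[i], a[j], b[i]))
            faces.append((a[j], b[j], b[i]))
    return SurfaceMesh(
        np.vstack(verts),
        np.array(faces, dtype=np.int64),
        np.full(2 * n_ring * (len(rings_xy) - 1), LABEL_WALL, dtype=np.int64),
        rings=ring_ids,
    )


def _rings_cross(a: np.ndarray, b: np.ndarray) -> bool:
    """Aligned-ring sanity check: corresponding vertices should not swap
    sides of each other's centroids grossly (a cheap crossing screen)."""
    ca, cb = a[:, :2].mean(axis=0), b[:, :2].mean(axis=0)
    ra = np.linalg.norm(a[:, :2] - ca, axis=1)
    rb = np.linalg.norm(b[:, :2] - cb, axis=1)
    d = np.linalg.norm(a[:, :2] - b[:, :2], axis=1)
    return bool(np.any(d > (ra + rb)))


# ---------------------------------------------------------------------------
# branch combination
# ---------------------------------------------------------------------------


def _loop_normal(pts: np.ndarray) -> np.ndarray:
    """Newell polygon normal."""
    nxt = np.roll(pts, -1, axis=0)
    n = np.sum(np.cross(pts, nxt), axis=0)
    return n / np.linalg.norm(n)


def combine_branches(
    trunk: SurfaceMesh,
    branch_a: SurfaceMesh,
    branch_b: SurfaceMesh,
    merge_tol: float | None = None,
) -> SurfaceMesh:
    """Join two branch tubes onto the trunk's distal ring (Y-junction).

    The trunk's distal ring is split into two arcs at the saddle vertices
    where the ring changes sides of the inter-branch plane; each arc is
    closed by a straight seam between the saddles and zippered to one
    branch's proximal ring.  Output winding is re-oriented globally so
    normals point outward.  Branch order does not matter.
    """
    for m in (trunk, branch_a, branch_b):
        if m.rings is None:
            raise ValueError("combine_branches requires structured (ringed) tubes")
    t_ring = trunk.rings[-1]
    t_pts = trunk.vertices[t_ring]
    t_cen = t_pts.mean(axis=0)
    if merge_tol is None:
        merge_tol = 4.0 * ring_radius(t_pts)
    cen_a = branch_a.vertices[branch_a.rings[0]].mean(axis=0)
    cen_b = branch_b.vertices[branch_b.rings[0]].mean(axis=0)
    if (
        np.linalg.norm(cen_a - t_cen) > merge_tol
        or np.linalg.norm(cen_b - t_cen) > merge_tol
    ):
        raise ValueError("branches not adjacent to the trunk's distal ring")

    # deterministic side split: project trunk-ring vertices on the
    # inter-branch direction — taken from the branch bodies (the proximal
    # rings coincide at the junction) and flattened into the ring plane
    w = branch_b.vertices.mean(axis=0) - branch_a.vertices.mean(axis=0)
    t_norm = _loop_normal(t_pts)
    w = w - np.dot(w, t_norm) * t_norm
    if np.linalg.norm(w) < 1e-12:
        raise ValueError("branches are not separated across the trunk ring plane")
    w = w / np.linalg.norm(w)
    proj = (t_pts - t_cen) @ w
    sides = proj >= 0  # True = branch-b side
    flips = np.nonzero(sides != np.roll(sides, 1))[0]
    if len(flips) != 2:
        raise ValueError("trunk ring does not split into two arcs cleanly")

    n_t = len(t_ring)
    # arcs as index runs of the cyclic trunk ring, sharing their end
    # (saddle) vertices
    i0, i1 = int(flips[0]), int(flips[1])  # first index of each run
    run1 = [(i0 + k) % n_t for k in range((i1 - i0) % n_t + 1)]  # ends at i1
    run2 = [(i1 + k) % n_t for k in range((i0 - i1) % n_t + 1)]  # ends at i0
    arc_b_idx = run1 if sides[i0] else run2
    arc_a_idx = run2 if sides[i0] else run1
    saddle_start_a = t_ring[arc_a_idx[0]]
    saddle_end_a = t_ring[arc_a_idx[-1]]

    # assemble combined vertex array
    verts = [trunk.vertices, branch_a.vertices, branch_b.vertices]
    off_a = len(trunk.vertices)
    off_b = off_a + len(branch_a.vertices)
    n_seam = 3
    s0 = trunk.vertices[saddle_end_a]
    s1 = trunk.vertices[saddle_start_a]
    # seam bows slightly toward the junction midpoint between the branches
    mid = 0.5 * (cen_a + cen_b)
    ts = np.linspace(0, 1, n_seam + 2)[1:-1]
    seam_pts = (1 - ts)[:, None] * s0 + ts[:, None] * s1
    seam_pts = 0.7 * seam_pts + 0.3 * mid
    off_s = off_b + len(branch_b.vertices)
    verts.append(seam_pts)
    seam_ids = np.arange(off_s, off_s + n_seam, dtype=np.int64)

    # closed junction loops, each ending where the seam carries it back
    loop_a_ids = np.concatenate([t_ring[arc_a_idx], seam_ids[::-1]])
    loop_b_ids = np.concatenate([t_ring[arc_b_idx], seam_ids])
    all_verts = np.vstack(verts)

    faces = [trunk.faces, branch_a.faces + off_a, branch_b.faces + off_b]
    labels = [trunk.face_labels, branch_a.face_labels, branch_b.face_labels]
    for loop_ids, branch, off in (
        (loop_a_ids, branch_a, off_a),
        (loop_b_ids, branch_b, off_b),
    ):
        ring_ids = branch.rings[0] + off
        loop_pts = all_verts[loop_ids]
        ring_pts = all_verts[ring_ids]
        if np.dot(_loop_normal(loop_pts), _loop_normal(ring_pts)) < 0:
            ring_ids = ring_ids[::-1]
        band = zipper_loops(loop_pts, all_verts[ring_ids], loop_ids, ring_ids)
        faces.append(band)
        labels.append(np.full(len(band), LABEL_WALL, dtype=np.int64))

    out = SurfaceMesh(
        all_verts,
        np.vstack(faces),
        np.concatenate(labels),
        rings=[r.copy() for r in trunk.rings],
    )
    out.meta["branch_rings"] = {
        "a": [r + off_a for r in branch_a.rings],
        "b": [r + off_b for r in branch_b.rings],
    }
    return _orient_outward(out)


def _orient_outward(mesh: SurfaceMesh) -> SurfaceMesh:
    """Make winding consistent and outward (decided on the capped surface)."""
    tm = mesh.as_trimesh()
    trimesh.repair.fix_winding(tm)
    fixed = SurfaceMesh(
        np.asarray(tm.vertices),
        np.asarray(tm.faces),
        mesh.face_labels,
        rings=mesh.rings,
        meta=mesh.meta,
    )
    capped = fixed.capped()
    if capped.as_trimesh().volume < 0:
        fixed.faces = fixed.faces[:, ::-1].copy()
    return fixed


# ---------------------------------------------------------------------------
# inlet extension
# ---------------------------------------------------------------------------


def extend_inlet(mesh: SurfaceMesh, factor: float = 5.0, n_axial: int = 8) -> SurfaceMesh:
    """Extrude the inlet cross-section outward by ``factor`` times the
    averaged inlet radius (mean vertex distance to the ring centroid).

    The extension is prismatic — the inlet shape is preserved exactly —
    and labelled separately; the free end of the extension becomes the new
    inlet.  Calling again replaces (never stacks) a previous extension.
    """
    if mesh.rings is None:
        raise ValueError("extend_inlet requires a mesh with a proximal ring")
    base = mesh.meta.get("pre_extension_base", mesh).copy()
    ring = base.rings[0]
    pts = base.vertices[ring]
    cen = pts.mean(axis=0)
    rbar = ring_radius(pts)
    length = factor * rbar
    normal = _loop_normal(pts)
    # orient away from the mesh body
    body_dir = base.vertices.mean(axis=0) - cen
    if np.dot(normal, body_dir) > 0:
        normal = -normal
    planarity = np.abs((pts - cen) @ normal)
    if planarity.max() > 0.05 * rbar:
        import warnings

        warnings.warn("inlet ring is not planar; extruding along its mean normal")

    n_ring = len(ring)
    offsets = np.linspace(length / n_axial, length, n_axial)
    new_verts = [base.vertices]
    ring_prev = ring
    faces = [base.faces]
    labels = [base.face_labels]
    rings = [r.copy() for r in base.rings]
    vid = len(base.vertices)
    for off in offsets:
        ring_new_pts = pts + off * normal
        ids = np.arange(vid, vid + n_ring, dtype=np.int64)
        vid += n_ring
        new_verts.append(ring_new_pts)
        strip = []
        for i in range(n_ring):
            j = (i + 1) % n_ring
            # winding mirrored vs loft strips: extension grows opposite to
            # the tube's axial direction
            strip.append((ring_prev[i], ids[i], ring_prev[j]))
            strip.append((ring_prev[j], ids[i], ids[j]))
        faces.append(np.array(strip, dtype=np.int64))
        labels.append(np.full(2 * n_ring, LABEL_EXTENSION, dtype=np.int64))
        ring_prev = ids
    rings.insert(0, ring_prev)  # new inlet ring at the extension's free end
    out = SurfaceMesh(
        np.vstack(new_verts), np.vstack(faces), np.concatenate(labels), rings=rings
    )
    out.meta = dict(base.meta)
    out.meta["pre_extension_base"] = base
    out.meta["extension_length"] = float(length)
    return _orient_outward(out)


# ---------------------------------------------------------------------------
# flattening
# ---------------------------------------------------------------------------


@dataclass
class FlatMap:
    """Cylindrical (angle, axial arclength) chart of a single-branch tube.

    theta in [0, 2 pi) about the centroid axis, u = cumulative centreline
    arclength (m), radius = vertex distance to its ring centroid (m);
    ``vertex_ids`` maps chart rows back to mesh vertices.
    """

    theta: np.ndarray
    u: np.ndarray
    radius: np.ndarray
    vertex_ids: np.ndarray
    ring_index: np.ndarray


def flatten_surface(mesh: SurfaceMesh) -> FlatMap:
    """Flatten a structured tube to its surface-of-revolution chart."""
    if mesh.rings is None:
        raise ValueError(
            "flatten_surface needs a single-branch structured tube; split the "
            "bifurcation into branches first"
        )
    cents = np.array([mesh.vertices[r].mean(axis=0) for r in mesh.rings])
    seg = np.linalg.norm(np.diff(cents, axis=0), axis=1)
    u_rings = np.concatenate([[0.0], np.cumsum(seg)])
    axis = cents[-1] - cents[0]
    axis = axis / np.linalg.norm(axis)
    # fixed global reference frame perpendicular to the axis, so rotating
    # the mesh about the axis shifts theta by the same angle
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - np.dot(ref, axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    theta, u, radius, vids, ring_idx = [], [], [], [], []
    for k, r in enumerate(mesh.rings):
        rel = mesh.vertices[r] - cents[k]
        th = np.mod(np.arctan2(rel @ e2, rel @ e1), 2 * np.pi)
        theta.append(th)
        u.append(np.full(len(r), u_rings[k]))
        radius.append(np.linalg.norm(rel, axis=1))
        vids.append(r)
        ring_idx.append(np.full(len(r), k))
    return FlatMap(
        theta=np.concatenate(theta),
        u=np.concatenate(u),
        radius=np.concatenate(radius),
        vertex_ids=np.concatenate(vids),
        ring_index=np.concatenate(ring_idx),
    )
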