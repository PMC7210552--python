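"""Synthetic carotid bifurcation geometry.

The lumen solid is defined implicitly as the union of three frustum-like
tubes — common carotid (CCA) trunk along +z, internal (ICA) and external
(ECA) branches splayed in the x–z plane — and triangulated by marching
cubes, which yields a watertight genus-0 surface with flat inlet/outlet
discs (the ends are slab-clamped planes of the implicit solid).

A mild atheromatous plaque is realized as a smooth axisymmetric Gaussian
narrowing of the ICA radius, so the diameter stenosis measured from any
cross-section equals ``plaque_depth_frac`` by construction (the subject
class this emulates has diameter stenosis below 20%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from skimage.measure import marching_cubes

from ..mesh import LABEL_INLET, LABEL_OUTLET, LABEL_WALL, SurfaceMesh

__all__ = [
    "GeometrySpec",
    "generate_bifurcation_geometry",
    "signed_distance",
    "branch_frames",
    "measure_branch_radius",
    "measure_stenosis",
]


@dataclass(frozen=True)
class GeometrySpec:
    """Parameters of the synthetic bifurcation (metres, degrees).

    Defaults are typical adult carotid dimensions: CCA radius 3.1 mm, ICA
    2.4 mm, ECA 1.9 mm, 50 degree bifurcation angle, and a 15% diameter
    stenosis centred 8 mm along the ICA.
    """

    cca_radius: float = 3.1e-3
    ica_radius: float = 2.4e-3
    eca_radius: float = 1.9e-3
    bifurcation_angle: float = 50.0  # full angle between ICA and ECA, degrees
    cca_length: float = 25e-3
    branch_length: float = 20e-3
    plaque_depth_frac: float = 0.15  # diameter stenosis fraction, in [0, 0.2]
    plaque_center: float = 8e-3  # arclength along ICA from the branch origin
    plaque_extent: float = 6e-3  # full width of the narrowed region
    voxel: float = 0.25e-3  # marching-cubes sampling pitch
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cca_radius", "ica_radius", "eca_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.plaque_depth_frac <= 0.2:
            raise ValueError("plaque_depth_frac must lie in [0, 0.2]")
        if self.cca_length <= 0 or self.branch_length <= 0:
            raise ValueError("lengths must be positive")
        # branches must separate before their outlets, else the two outlet
        # discs merge into one opening (self-intersecting parameterization)
        spread = 2 * self.branch_length * np.sin(np.radians(self.bifurcation_angle / 2))
        if spread < 1.2 * (self.ica_radius + self.eca_radius):
            raise ValueError(
                "branch overlap: bifurcation angle/branch length too small to "
                "separate the ICA and ECA outlets"
            )


def branch_frames(spec: GeometrySpec) -> dict:
    """Origins and unit axes of the three vessel segments."""
    half = np.radians(spec.bifurcation_angle / 2)
    # branches originate one CCA radius before the trunk's distal plane so
    # the union is connected through the apex
    origin = np.array([0.0, 0.0, spec.cca_length - spec.cca_radius])
    return {
        "cca": (np.zeros(3), np.array([0.0, 0.0, 1.0]), spec.cca_length),
        "ica": (
            origin,
            np.array([np.sin(half), 0.0, np.cos(half)]),
            spec.branch_length + spec.cca_radius,
        ),
        "eca": (
            origin,
            np.array([-np.sin(half), 0.0, np.cos(half)]),
            spec.branch_length + spec.cca_radius,
        ),
    }


def _tube_field(
    pts: np.ndarray, p0: np.ndarray, d: np.ndarray, length: float, radius
) -> np.ndarray:
    """Implicit field of a slab-capped tube; negative inside.

    ``radius`` is either a scalar or a callable of the axial coordinate s.
    """
    rel = pts - p0
    s = rel @ d
    radial = np.linalg.norm(rel - s[:, None] * d[None, :], axis=1)
    r = radius(s) if callable(radius) else radius
    return np.maximum(radial - r, np.maximum(-s, s - length))


def _ica_radius_profile(spec: GeometrySpec):
    sc = spec.plaque_center + spec.cca_radius  # s measured from branch origin
    sig = spec.plaque_extent / 2.0

    def radius(s):
        return spec.ica_radius * (
            1.0 - spec.plaque_depth_frac * np.exp(-0.5 * ((s - sc) / sig) ** 2)
        )

    return radius


def signed_distance(spec: GeometrySpec, pts: np.ndarray) -> np.ndarray:
    """Implicit lumen field at points (negative inside the lumen)."""
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    frames = branch_frames(spec)
    f_cca = _tube_field(pts, *frames["cca"], spec.cca_radius)
    f_ica = _tube_field(pts, *frames["ica"], _ica_radius_profile(spec))
    f_eca = _tube_field(pts, *frames["eca"], spec.eca_radius)
    return np.minimum(f_cca, np.minimum(f_ica, f_eca))


def generate_bifurcation_geometry(spec: GeometrySpec) -> SurfaceMesh:
    """Triangulate the bifurcation lumen wall with labelled openings.

    Returns a watertight surface (Euler characteristic 2) whose flat end
    discs are labelled inlet (CCA proximal plane) and outlet (branch distal
    planes); everything else is wall.  Down-stream stages that need an open
    tube drop the disc faces.
    """
    frames = branch_frames(spec)
    half = np.radians(spec.bifurcation_angle / 2)
    v = spec.voxel
    margin = 4 * v
    xmax = spec.branch_length * np.sin(half) + max(spec.ica_radius, spec.eca_radius)
    zmax = frames["ica"][0][2] + frames["ica"][2] * np.cos(half) + spec.ica_radius
    # the 0.37-voxel offset keeps the flat end planes off the grid planes,
    # avoiding degenerate (node-exact) zero crossings in marching cubes
    lo = np.array([-(xmax + margin), -(spec.cca_radius + margin), -margin]) - 0.37 * v
    hi = np.array([xmax + margin, spec.cca_radius + margin, zmax + margin])
    shape = np.ceil((hi - lo) / v).astype(int) + 1
    axes = [lo[i] + v * np.arange(shape[i]) for i in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    F = signed_distance(spec, pts).reshape(shape)
    verts, faces, _, _ = marching_cubes(F, level=0.0, spacing=(v, v, v))
    verts += lo
    # drop degenerate slivers and stray zero-volume fragments
    tm = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    tm.merge_vertices()
    tm.update_faces(tm.area_faces > 1e-16)
    parts = tm.split(only_watertight=False)
    tm = max(parts, key=lambda p: len(p.faces))
    verts, faces = np.asarray(tm.vertices), np.asarray(tm.faces)

    labels = np.full(len(faces), LABEL_WALL, dtype=np.int64)
    centroids = verts[faces].mean(axis=1)
    normals = tm.face_normals
    planes = [
        (LABEL_INLET, np.zeros(3), np.array([0.0, 0.0, -1.0])),
    ]
    for name in ("ica", "eca"):
        p0, d, length = frames[name]
        planes.append((LABEL_OUTLET, p0 + length * d, d))
    for lab, pt, n in planes:
        on_plane = np.abs((centroids - pt) @ n) < 0.45 * v
        aligned = normals @ n > 0.9
        labels[on_plane & aligned] = lab
    return SurfaceMesh(verts, faces, labels)


def measure_branch_radius(
    mesh: SurfaceMesh,
    p0: np.ndarray,
    direction: np.ndarray,
    s: float,
    r_max: float,
) -> float:
    """Effective lumen radius of a cross-section perpendicular to an axis.

    Slices the wall with the plane through ``p0 + s*direction``, keeps the
    intersection points within ``r_max`` of the axis point, and returns
    their mean distance to their own centroid (circle-fit radius for a
    near-circular section).
    """
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    origin = np.asarray(p0, dtype=float) + s * d
    tm = mesh.as_trimesh()
    segs = trimesh.intersections.mesh_plane(tm, plane_normal=d, plane_origin=origin)
    if len(segs) == 0:
        raise ValueError("plane does not intersect the mesh")
    pts = segs.reshape(-1, 3)
    pts = pts[np.linalg.norm(pts - origin, axis=1) < r_max]
    if len(pts) < 8:
        raise ValueError("cross-section not found near the axis point")
    c = pts.mean(axis=0)
    return float(np.linalg.norm(pts - c, axis=1).mean())


def measure_stenosis(mesh: SurfaceMesh, spec: GeometrySpec) -> float:
    """Diameter stenosis of the ICA recovered from the mesh.

    Scans cross-sections along the ICA, takes the minimal radius, and
    references it to the radius far from the plaque:
    ``stenosis = 1 - r_min / r_ref``.
    """
    p0, d, _ = branch_frames(spec)["ica"]
    s_lo = spec.cca_radius + max(2e-3, spec.plaque_center - spec.plaque_extent)
    s_hi = spec.cca_radius + spec.plaque_center + spec.plaque_extent
    radii = [
        measure_branch_radius(mesh, p0, d, s, 2.5 * spec.ica_radius)
        for s in np.linspace(s_lo, s_hi, 15)
    ]
    r_ref = measure_branch_radius(
        mesh, p0, d, spec.cca_radius + spec.branch_length - 2e-3, 2.5 * spec.ica_radius
    )
    return float(1.0 - min(radii) / r_ref)
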