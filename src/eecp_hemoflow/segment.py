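"""Endothelial boundary extraction from MR-like slice stacks.

Per slice: morphological denoising (opening-by-reconstruction followed by
closing-by-reconstruction), automatic binarization (Otsu), an edge map
built from the binary boundary, and a closed active contour (snake)
minimizing

    E[c] = closed-integral ( alpha |dc/ds|^2 + beta |d^2c/ds^2|^2
                             + gamma (1 - E(x(s), y(s))) ) ds

evolved from the previous slice's result — the first slice's contour is
supplied externally, standing in for a manual trace.

Numerics: vertices are resampled to uniform arclength every iteration;
the internal (elasticity/rigidity) terms use the classic periodic
pentadiagonal system solved semi-implicitly; the external force is the
gradient vector flow (GVF) diffusion of grad E, which extends the pull of
the sigma = 2 px edge ridge across homogeneous regions while agreeing
with grad E near the ridge.  An iteration is accepted only if the
discrete energy does not increase (with step backtracking), so the
energy is non-increasing along the evolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage import draw
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import dilation, disk, erosion, reconstruction

__all__ = [
    "SnakeParams",
    "denoise_morphological",
    "binarize",
    "edge_map",
    "gradient_vector_flow",
    "evolve_contour",
    "segment_stack",
    "contour_energy",
    "contour_iou",
    "circle_contour",
    "resample_closed",
]


@dataclass(frozen=True)
class SnakeParams:
    """Weights and numerics of the snake evolution.

    alpha (elasticity), beta (rigidity) and gamma (image attraction) are
    the balance scalars of the three energy terms; step_size is the
    artificial-time step of the semi-implicit update; convergence is
    declared when the largest vertex displacement drops below
    convergence_tol pixels.
    """

    alpha: float = 0.01
    beta: float = 0.1
    gamma: float = 1.0
    step_size: float = 1.0
    max_iterations: int = 500
    convergence_tol: float = 0.05
    n_points: int = 100
    edge_sigma: float = 2.0
    gvf_iterations: int = 250

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.gamma < 0:
            raise ValueError("alpha, beta, gamma must be non-negative")
        if self.alpha == 0 and self.beta == 0 and self.gamma == 0:
            raise ValueError("at least one energy weight must be positive")


# ---------------------------------------------------------------------------
# per-slice image operators
# ---------------------------------------------------------------------------


def denoise_morphological(img: np.ndarray, radius: int) -> np.ndarray:
    """Opening-by-reconstruction then closing-by-reconstruction (disc SE).

    Removes bright clutter smaller than the structuring element and fills
    comparable dark specks while preserving the shape of structures that
    survive, unlike plain opening/closing.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if 2 * radius + 1 > min(img.shape):
        raise ValueError("structuring element larger than the image")
    img = np.asarray(img, dtype=float)
    se = disk(radius)
    opened = reconstruction(erosion(img, se), img, method="dilation")
    closed = reconstruction(dilation(opened, se), opened, method="erosion")
    return closed


def binarize(img: np.ndarray, invert: bool = False) -> np.ndarray:
    """Foreground (lumen-bright) mask via Otsu's threshold."""
    img = np.asarray(img, dtype=float)
    if np.ptp(img) == 0:
        raise ValueError("no contrast: image is constant")
    thr = threshold_otsu(img)
    fg = img > thr
    return ~fg if invert else fg


def edge_map(binary: np.ndarray, sigma: float = 2.0) -> np.ndarray:
    """Edge strength in [0, 1]: foreground boundary, Gaussian-blurred.

    Pixels on the image border are excluded from the edge set (a
    foreground region truncated by the frame is not an endothelial
    boundary).  A full-frame foreground therefore yields an all-zero map.
    """
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        raise ValueError("empty foreground: no edges to map")
    # two-pixel band straddling the region boundary, so the blurred ridge
    # is centred on the true (sub-pixel) edge rather than the inner layer
    boundary = dilation(binary, disk(1)) & ~erosion(binary, disk(1))
    boundary[0, :] = boundary[-1, :] = False
    boundary[:, 0] = boundary[:, -1] = False
    if not boundary.any():
        return np.zeros_like(binary, dtype=float)
    E = gaussian_filter(boundary.astype(float), sigma)
    E -= E.min()
    return E / E.max()


def gradient_vector_flow(
    E: np.ndarray, mu: float = 0.2, n_iter: int = 250
) -> tuple[np.ndarray, np.ndarray]:
    """GVF field (fx, fy) of an edge map (x = column, y = row axes).

    Explicit diffusion of grad E: far from edges the field relaxes to a
    smooth extension of the nearby edge pull; on the ridge it equals
    grad E.
    """
    Ey, Ex = np.gradient(E)  # np.gradient returns d/drow (y), d/dcol (x)
    u, v = Ex.copy(), Ey.copy()
    b = Ex**2 + Ey**2
    dt = 1.0  # stable: mu*dt <= 1/4 and max(b)*dt < 1 for normalized E
    for _ in range(n_iter):
        for f, g in ((u, Ex), (v, Ey)):
            lap = (
                np.roll(f, 1, 0) + np.roll(f, -1, 0)
                + np.roll(f, 1, 1) + np.roll(f, -1, 1) - 4 * f
            )
            f += dt * (mu * lap - b * (f - g))
    return u, v


# ---------------------------------------------------------------------------
# contour utilities
# ---------------------------------------------------------------------------


def circle_contour(center: tuple[float, float], radius: float, n: int = 100) -> np.ndarray:
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)]
    )


def resample_closed(xy: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline to n uniform-arclength vertices."""
    xy = np.asarray(xy, dtype=float)
    closed = np.vstack([xy, xy[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return np.repeat(xy[:1], n, axis=0)
    si = np.linspace(0, total, n, endpoint=False)
    x = np.interp(si, s, closed[:, 0])
    y = np.interp(si, s, closed[:, 1])
    return np.column_stack([x, y])


def perimeter(xy: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(np.vstack([xy, xy[:1]]), axis=0), axis=1).sum())


def _interp_field(field: np.ndarray, xy: np.ndarray) -> np.ndarray:
    # map_coordinates indexes (row, col) = (y, x)
    return map_coordinates(field, [xy[:, 1], xy[:, 0]], order=1, mode="nearest")


def contour_energy(xy: np.ndarray, E: np.ndarray, params: SnakeParams) -> float:
    """Discrete snake energy of a closed contour on an edge map."""
    d1 = np.roll(xy, -1, axis=0) - xy
    d2 = np.roll(xy, -1, axis=0) - 2 * xy + np.roll(xy, 1, axis=0)
    ds = np.linalg.norm(d1, axis=1)
    internal = params.alpha * (d1**2).sum() + params.beta * (d2**2).sum()
    external = params.gamma * float(((1.0 - _interp_field(E, xy)) * ds).sum())
    return float(internal) + external


def _internal_matrix(n: int, params: SnakeParams, tau: float) -> np.ndarray:
    """(I + tau K) for the periodic pentadiagonal internal-energy operator."""
    a, b = params.alpha, params.beta
    row = np.zeros(n)
    row[0] = 2 * a + 6 * b
    row[1] = row[-1] = -(a + 4 * b)
    row[2] = row[-2] = b
    K = sla.circulant(row)
    return np.eye(n) + tau * K


def evolve_contour(
    init: np.ndarray,
    E: np.ndarray,
    params: SnakeParams = SnakeParams(),
    force: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Evolve a closed contour to a local minimum of the snake energy.

    Stops when the maximum vertex displacement falls below
    ``convergence_tol`` or after ``max_iterations``; iterations that would
    increase the discrete energy are retried with a halved step and the
    evolution stops once no decreasing step exists.  Vertices leaving the
    image domain are clamped (with a warning).
    """
    if np.isnan(init).any():
        raise ValueError("initial contour contains NaN")
    ny, nx = E.shape
    xy = resample_closed(np.asarray(init, dtype=float), params.n_points)
    if force is None:
        fx, fy = gradient_vector_flow(E, n_iter=params.gvf_iterations)
    else:
        fx, fy = force
    energy = contour_energy(xy, E, params)
    if np.isnan(energy):
        raise ValueError("NaN snake energy on the initial contour")
    clamped = False
    for _ in range(params.max_iterations):
        tau = params.step_size
        accepted = False
        for _try in range(10):
            A = _internal_matrix(params.n_points, params, tau)
            fext = np.column_stack(
                [_interp_field(fx, xy), _interp_field(fy, xy)]
            )
            new = np.linalg.solve(A, xy + tau * params.gamma * fext)
            lo, hi = 0.0, np.array([nx - 1.0, ny - 1.0])
            if np.any(new < lo) or np.any(new > hi):
                new = np.clip(new, lo, hi)
                clamped = True
            new = resample_closed(new, params.n_points)
            e_new = contour_energy(new, E, params)
            if np.isnan(e_new):
                raise ValueError("NaN snake energy during evolution")
            if e_new <= energy * (1 + 1e-12) + 1e-15:
                accepted = True
                break
            tau *= 0.5
        if not accepted:
            break
        disp = np.max(np.linalg.norm(new - xy, axis=1))
        xy, energy = new, e_new
        if disp < params.convergence_tol:
            break
    if clamped:
        warnings.warn("contour clamped to the image domain", stacklevel=2)
    return xy


# ---------------------------------------------------------------------------
# stack propagation
# ---------------------------------------------------------------------------


def _select_component(binary: np.ndarray, prev_contour: np.ndarray | None) -> np.ndarray:
    """Keep the foreground component overlapping the previous contour's
    interior (largest component on the first slice)."""
    lab = cc_label(binary)
    if lab.max() == 0:
        raise ValueError("empty foreground after binarization")
    if prev_contour is None:
        best = np.argmax(np.bincount(lab.ravel())[1:]) + 1
        return lab == best
    rr, cc = draw.polygon(prev_contour[:, 1], prev_contour[:, 0], binary.shape)
    interior = np.zeros_like(binary)
    interior[rr, cc] = True
    overlaps = [
        np.logical_and(lab == k, interior).sum() for k in range(1, lab.max() + 1)
    ]
    if max(overlaps) == 0:
        best = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    else:
        best = int(np.argmax(overlaps)) + 1
    return lab == best


def _is_simple(xy: np.ndarray) -> bool:
    """Cheap self-intersection screen: positive polygon area and sane
    perimeter-to-area ratio."""
    x, y = xy[:, 0], xy[:, 1]
    area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    if area < 1.0:
        return False
    return perimeter(xy) ** 2 <= 4 * np.pi * area * 10.0


def segment_stack(
    stack: np.ndarray,
    first_contour: np.ndarray,
    params: SnakeParams = SnakeParams(),
    denoise_radius: int = 4,
) -> list[np.ndarray]:
    """Segment every slice, propagating each result as the next init.

    The supplied ``first_contour`` stands in for the manual trace of the
    first slice and is itself refined on slice 0.  A slice whose contour
    degenerates (self-intersection screen) is flagged with a warning and
    propagation continues from the last good contour.
    """
    contours: list[np.ndarray] = []
    prev = np.asarray(first_contour, dtype=float)
    last_good = prev
    for idx, img in enumerate(stack):
        den = denoise_morphological(img, denoise_radius)
        fg = binarize(den)
        fg = _select_component(fg, None if idx == 0 else last_good)
        E = edge_map(fg, sigma=params.edge_sigma)
        init = prev if idx == 0 else last_good
        out = evolve_contour(init, E, params)
        if _is_simple(out):
            last_good = out
        else:
            warnings.warn(
                f"slice {idx}: contour degenerated; keeping previous contour",
                stacklevel=2,
            )
            out = last_good
        contours.append(out)
    return contours


def contour_iou(a: np.ndarray, b: np.ndarray, shape: tuple[int, int]) -> float:
    """Intersection-over-union of two closed contours rasterized on a grid."""
    ma = np.zeros(shape, dtype=bool)
    mb = np.zeros(shape, dtype=bool)
    rr, cc = draw.polygon(a[:, 1], a[:, 0], shape)
    ma[rr, cc] = True
    rr, cc = draw.polygon(b[:, 1], b[:, 0], shape)
    mb[rr, cc] = True
    union = np.logical_or(ma, mb).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(ma, mb).sum() / union)
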