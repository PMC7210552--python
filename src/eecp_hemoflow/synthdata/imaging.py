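"""Synthetic MR-like cross-sectional image stacks of the lumen.

Each slice is a plane orthogonal to the vessel axis (+z) through the CCA
trunk: bright lumen on a dark background, clutter as small bright blobs,
and additive Gaussian noise (an adequate stand-in for Rician magnitude
noise at the signal-to-noise ratios generated here).  Ground-truth
endothelial contours are extracted from the analytic implicit lumen field
at sub-pixel accuracy for scoring the segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .geometry import GeometrySpec, signed_distance

__all__ = ["ImageStackSpec", "generate_mr_stack", "slice_z_positions"]


@dataclass(frozen=True)
class ImageStackSpec:
    """Parameters of the synthetic slice stack.

    Intensities are on an arbitrary 8-bit-like grayscale; ``noise_sigma``
    is in the same units.  ``pixel_size`` is metres per pixel.
    """

    slice_count: int = 10
    pixel_size: float = 0.15e-3
    image_size: int = 96  # square, pixels
    slice_spacing: float = 1.8e-3  # m, matches a typical MRA slice thickness
    z_start: float = 1.0e-3
    lumen_intensity: float = 200.0
    background_intensity: float = 40.0
    noise_sigma: float = 0.0
    clutter_blob_count: int = 0
    clutter_blob_radius: float = 2.0  # px
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lumen_intensity <= self.background_intensity:
            raise ValueError("lumen_intensity must exceed background_intensity")
        if self.slice_count < 1 or self.image_size < 16:
            raise ValueError("stack too small")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def slice_z_positions(spec: ImageStackSpec) -> np.ndarray:
    return spec.z_start + spec.slice_spacing * np.arange(spec.slice_count)


def _pixel_grid(spec: ImageStackSpec) -> tuple[np.ndarray, np.ndarray]:
    """Physical (x, y) coordinates of pixel centres; image centred on the axis."""
    n = spec.image_size
    coords = (np.arange(n) - (n - 1) / 2.0) * spec.pixel_size
    return np.meshgrid(coords, coords, indexing="xy")  # X varies along columns


def generate_mr_stack(
    geom: GeometrySpec, spec: ImageStackSpec
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Render the image stack and its ground-truth contours.

    Returns ``(stack, contours)`` where ``stack`` has shape
    (slice_count, image_size, image_size) and each contour is an (N, 2)
    array of (x_px, y_px) vertices, counter-clockwise viewed from +z.
    """
    rng = np.random.default_rng(spec.seed)
    X, Y = _pixel_grid(spec)
    n = spec.image_size
    stack = np.empty((spec.slice_count, n, n), dtype=float)
    contours: list[np.ndarray] = []
    for k, z in enumerate(slice_z_positions(spec)):
        pts = np.column_stack([X.ravel(), Y.ravel(), np.full(X.size, z)])
        f = signed_distance(geom, pts).reshape(n, n)
        if not np.any(f < 0):
            raise ValueError(f"slice {k} at z={z:.4g} m lies outside the lumen")
        # 1-pixel linear ramp across the boundary for sub-pixel realism
        lumen_frac = np.clip(0.5 - f / spec.pixel_size, 0.0, 1.0)
        img = spec.background_intensity + (
            spec.lumen_intensity - spec.background_intensity
        ) * lumen_frac

        contours.append(_truth_contour(f))
        img = _add_clutter(img, f, spec, rng)
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
        stack[k] = img
    return stack, contours


def _truth_contour(f: np.ndarray) -> np.ndarray:
    """Zero level set of the implicit field as an (x_px, y_px) polyline, CCW."""
    # find_contours returns (row=y, col=x); keep the longest loop
    loops = measure.find_contours(f, 0.0)
    loop = max(loops, key=len)
    xy = np.column_stack([loop[:, 1], loop[:, 0]])
    if np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]
    area2 = np.sum(xy[:, 0] * np.roll(xy[:, 1], -1) - np.roll(xy[:, 0], -1) * xy[:, 1])
    if area2 < 0:
        xy = xy[::-1]
    return xy


def _add_clutter(
    img: np.ndarray, f: np.ndarray, spec: ImageStackSpec, rng: np.random.Generator
) -> np.ndarray:
    """Place bright blobs that never overlap each other (lumen overlap allowed)."""
    if spec.clutter_blob_count == 0:
        return img
    n = spec.image_size
    rr, cc = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    placed: list[tuple[float, float]] = []
    img = img.copy()
    attempts = 0
    while len(placed) < spec.clutter_blob_count and attempts < 1000:
        attempts += 1
        cy, cx = rng.uniform(4, n - 4, size=2)
        if any(
            np.hypot(cy - py, cx - px) < 2.0 * spec.clutter_blob_radius + 3
            for py, px in placed
        ):
            continue
        placed.append((cy, cx))
        mask = (rr - cy) ** 2 + (cc - cx) ** 2 <= spec.clutter_blob_radius**2
        img[mask] = spec.lumen_intensity
    if len(placed) < spec.clutter_blob_count:
        raise RuntimeError("could not place the requested clutter blobs")
    return img
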