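"""Denoising, binarization, edge maps and snake evolution."""

import warnings

import numpy as np
import pytest
from skimage import draw
from skimage.morphology import closing, disk, opening

from eecp_hemoflow.segment import (
    SnakeParams,
    binarize,
    circle_contour,
    contour_energy,
    contour_iou,
    denoise_morphological,
    edge_map,
    evolve_contour,
    segment_stack,
)


def disc_image(shape=(96, 96), center=(48, 48), radius=20.0, lo=40.0, hi=200.0):
    img = np.full(shape, lo)
    rr, cc = draw.disk(center, radius + 1e-3, shape=shape)
    img[rr, cc] = hi
    return img


class TestDenoise:
    def test_idempotent_on_clean_disc(self):
        img = disc_image()
        out = denoise_morphological(img, 4)
        assert np.allclose(denoise_morphological(out, 4), out)
        assert out.min() >= img.min() and out.max() <= img.max()

    def test_removes_small_bright_blobs(self):
        img = disc_image()
        clean = img.copy()
        for cy, cx in [(10, 10), (80, 20), (15, 75)]:
            rr, cc = draw.disk((cy, cx), 2.0, shape=img.shape)
            img[rr, cc] = 200.0
        out = denoise_morphological(img, 4)
        a = out > 120
        b = clean > 120
        iou = (a & b).sum() / (a | b).sum()
        assert iou > 0.98

    def test_bounded_by_plain_morphology(self):
        rng = np.random.default_rng(0)
        img = disc_image() + rng.normal(0, 5, (96, 96))
        out = denoise_morphological(img, 3)
        assert np.all(out >= opening(img, disk(3)) - 1e-9)
        assert np.all(out <= closing(img, disk(3)) + 1e-9)

    def test_bad_radius_rejected(self):
        with pytest.raises(ValueError):
            denoise_morphological(disc_image(), 0)
        with pytest.raises(ValueError):
            denoise_morphological(disc_image(), 100)


class TestBinarize:
    def test_two_level_separation(self):
        img = disc_image()
        fg = binarize(img)
        assert np.array_equal(fg, img > 120)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="contrast"):
            binarize(np.full((32, 32), 7.0))

    def test_invert_flag_complements(self):
        img = disc_image()
        assert np.array_equal(binarize(img, invert=True), ~binarize(img))


class TestEdgeMap:
    def test_ridge_on_true_circle(self):
        fg = disc_image() > 120
        E = edge_map(fg)
        # radial profile: ridge within 1 px of r=20
        th = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        for t in th[::8]:
            r = np.linspace(10, 30, 201)
            x = 48 + r * np.cos(t)
            y = 48 + r * np.sin(t)
            vals = E[np.round(y).astype(int), np.round(x).astype(int)]
            assert abs(r[np.argmax(vals)] - 20.0) <= 1.0

    def test_normalization(self):
        E = edge_map(disc_image() > 120)
        assert E.max() == pytest.approx(1.0) and E.min() == pytest.approx(0.0)

    def test_full_frame_foreground_all_zero(self):
        E = edge_map(np.ones((32, 32), dtype=bool))
        assert np.all(E == 0)

    def test_empty_foreground_rejected(self):
        with pytest.raises(ValueError):
            edge_map(np.zeros((32, 32), dtype=bool))


@pytest.fixture(scope="module")
def circle_edge_map():
    return edge_map(disc_image() > 120)


class TestEvolveContour:
    def test_fixed_point_on_own_ridge(self, circle_edge_map):
        init = circle_contour((48, 48), 20.0)
        out = evolve_contour(init, circle_edge_map, SnakeParams(step_size=0.05))
        r = np.linalg.norm(out - [48, 48], axis=1)
        assert np.sqrt(np.mean((r - 20.0) ** 2)) < 0.1

    def test_recovery_from_six_pixel_offset(self, circle_edge_map):
        out = evolve_contour(circle_contour((48, 48), 26.0), circle_edge_map, SnakeParams())
        r = np.linalg.norm(out - [48, 48], axis=1)
        assert np.abs(r - 20.0).mean() < 0.5

    def test_pure_elasticity_shrinks_perimeter(self):
        from eecp_hemoflow.segment import perimeter

        E = np.zeros((96, 96))
        params = SnakeParams(alpha=0.5, beta=0.0, gamma=0.0, max_iterations=1,
                             gvf_iterations=1)
        xy = circle_contour((48, 48), 20.0)
        peri = [perimeter(xy)]
        for _ in range(5):
            xy = evolve_contour(xy, E, params)
            peri.append(perimeter(xy))
        assert all(b < a for a, b in zip(peri, peri[1:]))

    def test_energy_non_increasing(self, circle_edge_map):
        params = SnakeParams()
        xy = circle_contour((48, 48), 25.0)
        energies = [contour_energy(xy, circle_edge_map, params)]
        for _ in range(6):
            xy = evolve_contour(
                xy, circle_edge_map, SnakeParams(max_iterations=20)
            )
            energies.append(contour_energy(xy, circle_edge_map, params))
        assert all(b <= a * (1 + 1e-9) for a, b in zip(energies, energies[1:]))

    def test_nan_contour_rejected(self, circle_edge_map):
        bad = circle_contour((48, 48), 20.0)
        bad[0] = np.nan
        with pytest.raises(ValueError):
            evolve_contour(bad, circle_edge_map, SnakeParams())


class TestSegmentStack:
    def test_identical_slices_identical_contours(self):
        img = disc_image()
        stack = np.stack([img] * 4)
        init = circle_contour((48, 48), 22.0)
        cons = segment_stack(stack, init)
        for c in cons[1:]:
            assert np.max(np.linalg.norm(c - cons[1], axis=1)) < SnakeParams().convergence_tol * 10

    def test_noiseless_stack_tracks_truth(self, clean_stack):
        stack, truth = clean_stack
        cons = segment_stack(stack, truth[0])
        for c, tr in zip(cons, truth):
            assert contour_iou(c, tr, stack[0].shape) > 0.98

    def test_noisy_cluttered_stack_iou(self, geom_spec):
        from eecp_hemoflow.synthdata import ImageStackSpec, generate_mr_stack

        contrast = 160.0
        spec = ImageStackSpec(
            noise_sigma=0.10 * contrast, clutter_blob_count=3, seed=7
        )
        stack, truth = generate_mr_stack(geom_spec, spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cons = segment_stack(stack, truth[0])
        ious = [contour_iou(c, tr, stack[0].shape) for c, tr in zip(cons, truth)]
        assert np.mean(ious) > 0.95
        assert min(ious) > 0.95

    def test_translation_equivariance(self):
        img = disc_image(center=(40, 44), radius=15.0)
        stack = np.stack([img] * 3)
        shifted = np.roll(np.roll(stack, 5, axis=1), -3, axis=2)
        init = circle_contour((44, 40), 17.0)
        cons = segment_stack(stack, init)
        cons_shifted = segment_stack(shifted, init + [-3.0, 5.0])
        for c, cs in zip(cons, cons_shifted):
            assert np.allclose(cs, c + [-3.0, 5.0], atol=0.1)
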