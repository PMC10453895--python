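"""Handcrafted descriptors against brute-force oracles and analytic cases."""

import numpy as np
import pytest
from scipy import ndimage

from hybridseg.features import (
    FeatureStack,
    HOGParams,
    compute_feature_stack,
    dense_grid,
    dsurf_descriptors,
    dsurf_to_channels,
    feature_stack,
    glcm_matrix,
    glcm_window_maps,
    hessian_responses,
    hog_features,
    hog_to_stack,
    image_gradients,
    lbp_map,
    texture_intensity_maps,
)


# ---------------------------------------------------------------------------
# oracles


def hog_oracle(image, params: HOGParams):
    """Naive per-pixel HOG: loop, bin, accumulate, normalize."""
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    padded = np.pad(image, 1, mode="edge")
    cell, bs, nb = params.cell_size, params.block_size, params.n_bins
    nyc, nxc = h // cell, w // cell
    hists = np.zeros((nyc, nxc, nb))
    span = 360.0 if params.signed else 180.0
    for y in range(nyc * cell):
        for x in range(nxc * cell):
            gx = (padded[y + 1, x + 2] - padded[y + 1, x]) / 2.0
            gy = (padded[y + 2, x + 1] - padded[y, x + 1]) / 2.0
            mag = np.hypot(gx, gy)
            ang = np.degrees(np.arctan2(gy, gx)) % span
            b = min(int(ang / (span / nb)), nb - 1)
            hists[y // cell, x // cell, b] += mag
    blocks = []
    for by in range(nyc - bs + 1):
        for bx in range(nxc - bs + 1):
            v = hists[by : by + bs, bx : bx + bs].ravel()
            blocks.append(v / np.sqrt((v**2).sum() + params.epsilon**2))
    return hists, np.concatenate(blocks)


def glcm_oracle(image, levels, offset, symmetric):
    """Enumerate every pixel pair for one offset."""
    q = np.minimum((np.asarray(image, float) * levels).astype(int), levels - 1)
    h, w = q.shape
    dy, dx = offset
    mat = np.zeros((levels, levels))
    for y in range(h):
        for x in range(w):
            y2, x2 = y + dy, x + dx
            if 0 <= y2 < h and 0 <= x2 < w:
                mat[q[y, x], q[y2, x2]] += 1
                if symmetric:
                    mat[q[y2, x2], q[y, x]] += 1
    return mat / mat.sum() if mat.sum() else mat


# ---------------------------------------------------------------------------
# dense grid


class TestDenseGrid:
    def test_regular_grid_coordinates(self):
        pts = dense_grid(32, 32, step=8)
        assert len(pts) == 16
        assert {(p.x, p.y) for p in pts} == {
            (x, y) for x in (0, 8, 16, 24) for y in (0, 8, 16, 24)
        }
        assert (pts[0].x, pts[0].y) == (0, 0)
        assert (pts[1].x, pts[1].y) == (8, 0)  # row-major: x varies first

    def test_step_one_covers_every_pixel(self):
        assert len(dense_grid(5, 4, step=1)) == 20

    def test_oversized_step_and_margin(self):
        pts = dense_grid(32, 32, step=40)
        assert [(p.x, p.y) for p in pts] == [(0, 0)]
        assert dense_grid(32, 32, step=40, margin=16) == []


# ---------------------------------------------------------------------------
# DSURF


class TestDSURF:
    def test_constant_image_gives_zero_vectors(self):
        desc = dsurf_descriptors(np.full((32, 32), 0.4), step=8)
        assert desc
        for d in desc:
            np.testing.assert_array_equal(d.vector, np.zeros(64))

    def test_descriptor_length_is_64(self):
        rng = np.random.default_rng(0)
        desc = dsurf_descriptors(rng.random((40, 40)), step=8)
        assert desc and all(d.vector.shape == (64,) for d in desc)

    def test_ramp_subregion_sums_match_brute_force(self):
        """f(x,y)=x: per sub-region sum(dx)=sum|dx|>0 and sum(dy)=0."""
        h = w = 48
        image = np.tile(np.arange(w, dtype=float), (h, 1)) / w
        sigma, window = 1.6, 16
        desc = dsurf_descriptors(image, step=16, sigma=sigma, window=window)
        # independent oracle: explicit per-pixel summation of the same
        # Gaussian-derivative responses over each sub-region
        lx = ndimage.gaussian_filter(image, sigma, order=(0, 1), mode="reflect")
        ly = ndimage.gaussian_filter(image, sigma, order=(1, 0), mode="reflect")
        for d in desc:
            x0, y0 = d.keypoint.x - 8, d.keypoint.y - 8
            expected = np.zeros(64)
            i = 0
            for sy in range(4):
                for sx in range(4):
                    sdx = sdy = adx = ady = 0.0
                    for yy in range(4):
                        for xx in range(4):
                            r, c = y0 + sy * 4 + yy, x0 + sx * 4 + xx
                            sdx += lx[r, c]
                            sdy += ly[r, c]
                            adx += abs(lx[r, c])
                            ady += abs(ly[r, c])
                    expected[i : i + 4] = (sdx, sdy, adx, ady)
                    i += 4
            expected /= np.linalg.norm(expected)
            np.testing.assert_allclose(d.vector, expected, atol=1e-12)
            for j in range(0, 64, 4):
                assert d.vector[j] == pytest.approx(d.vector[j + 2])  # sum dx = sum|dx|
                assert d.vector[j] > 0
                assert abs(d.vector[j + 1]) < 1e-9  # sum dy = 0

    def test_subregion_inequality_on_random_images(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            img = rng.random((24, 24))
            for d in dsurf_descriptors(img, step=8, window=16):
                v = d.vector.reshape(16, 4)
                assert (np.abs(v[:, 0]) <= v[:, 2] + 1e-12).all()
                assert (np.abs(v[:, 1]) <= v[:, 3] + 1e-12).all()

    def test_oriented_variant_runs_and_normalizes(self):
        rng = np.random.default_rng(2)
        desc = dsurf_descriptors(rng.random((32, 32)), step=8, oriented=True)
        for d in desc:
            assert np.isfinite(d.vector).all()
            assert np.linalg.norm(d.vector) == pytest.approx(1.0, abs=1e-9)

    def test_window_not_multiple_of_4_rejected(self):
        with pytest.raises(ValueError, match="divisible by 4"):
            dsurf_descriptors(np.zeros((32, 32)), window=10)


def test_hessian_responses_symmetric_storage():
    rng = np.random.default_rng(3)
    img = rng.random((32, 32))
    pts = dense_grid(32, 32, step=8, margin=8)
    resp = hessian_responses(img, pts)
    assert len(resp) == len(pts)
    assert all(np.isfinite([r.Lxx, r.Lxy, r.Lyy, r.determinant]).all() for r in resp)


# ---------------------------------------------------------------------------
# gradients + HOG


class TestImageGradients:
    def test_ramp(self):
        img = np.tile(np.arange(8, dtype=float), (8, 1))
        g = image_gradients(img)
        np.testing.assert_allclose(g.Gx[:, 1:-1], 1.0)
        np.testing.assert_allclose(g.Gy, 0.0)

    def test_constant(self):
        g = image_gradients(np.full((5, 5), 3.0))
        assert not g.Gx.any() and not g.Gy.any()

    def test_central_difference_at_center(self):
        img = np.zeros((3, 3))
        img[1, 2], img[1, 0] = 5.0, 1.0
        assert image_gradients(img).Gx[1, 1] == pytest.approx(2.0)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError, match="degenerate image"):
            image_gradients(np.zeros((2, 2)))


class TestHOG:
    def test_constant_image_all_zero(self):
        res = hog_features(np.full((32, 32), 0.7))
        assert not res.cell_histograms.any()
        assert not res.block_vector.any()

    def test_ramp_mass_in_zero_degree_bin(self):
        img = np.tile(np.arange(32, dtype=float), (32, 1))
        res = hog_features(img)
        hists = res.cell_histograms
        assert hists[..., 0].sum() > 0
        assert hists[..., 1:].sum() == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.random((32, 32))
        params = HOGParams()
        res = hog_features(img, params)
        hists, blocks = hog_oracle(img, params)
        assert np.abs(res.cell_histograms - hists).max() <= 1e-9
        assert np.abs(res.block_vector - blocks).max() <= 1e-9

    def test_cell_histogram_sums_equal_magnitude_sums(self):
        rng = np.random.default_rng(9)
        img = rng.random((24, 24))
        res = hog_features(img, HOGParams(cell_size=8))
        g = image_gradients(img)
        mag = np.hypot(g.Gx, g.Gy)
        for cy in range(3):
            for cx in range(3):
                block = mag[cy * 8 : (cy + 1) * 8, cx * 8 : (cx + 1) * 8]
                assert res.cell_histograms[cy, cx].sum() == pytest.approx(
                    block.sum()
                )

    def test_rotation_180_reverses_cell_grid_with_same_bins(self):
        rng = np.random.default_rng(4)
        img = rng.random((32, 32))
        a = hog_features(img).cell_histograms
        b = hog_features(np.rot90(img, 2).copy()).cell_histograms
        np.testing.assert_allclose(b, a[::-1, ::-1], atol=1e-9)

    def test_invalid_bins_rejected(self):
        with pytest.raises(ValueError, match="invalid histogram"):
            hog_features(np.zeros((32, 32)), HOGParams(n_bins=1))


# ---------------------------------------------------------------------------
# texture maps


class TestGLCM:
    def test_two_by_two_pair_enumeration(self):
        img = np.array([[0.0, 0.0], [0.9, 0.9]])
        mat = glcm_matrix(img, levels=2, offsets=((0, 1),), symmetric=True,
                          normalized=False)
        np.testing.assert_array_equal(mat, [[2.0, 0.0], [0.0, 2.0]])
        norm = glcm_matrix(img, levels=2, offsets=((0, 1),))
        np.testing.assert_allclose(norm, [[0.5, 0.0], [0.0, 0.5]])

    @pytest.mark.parametrize("offset", [(0, 1), (1, 0), (1, 1)])
    def test_matches_pair_enumeration_oracle(self, offset):
        rng = np.random.default_rng(5)
        img = rng.random((9, 9))
        got = glcm_matrix(img, levels=4, offsets=(offset,))
        want = glcm_oracle(img, 4, offset, symmetric=True)
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_normalized_sums_to_one_and_symmetric(self):
        rng = np.random.default_rng(6)
        mat = glcm_matrix(rng.random((16, 16)), levels=8)
        assert mat.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(mat, mat.T)

    def test_checkerboard_contrast_is_maximal(self):
        """Exhaustive: no 2-level 3x3 image beats the checkerboard's contrast."""
        ii, jj = np.mgrid[0:2, 0:2]
        weight = (ii - jj) ** 2

        def contrast(img):
            return (glcm_matrix(img, levels=2, offsets=((0, 1),)) * weight).sum()

        checker = np.indices((3, 3)).sum(axis=0) % 2 * 0.99
        best = contrast(checker)
        for bits in range(2**9):
            img = (np.array([(bits >> k) & 1 for k in range(9)])
                   .reshape(3, 3) * 0.99)
            assert contrast(img) <= best + 1e-12


class TestTextureMaps:
    def test_constant_image_conventions(self):
        stack = texture_intensity_maps(np.full((16, 16), 0.5), window=5)
        by_name = dict(zip(stack.names, stack.channels))
        np.testing.assert_allclose(by_name["local_mean"], 0.5)
        np.testing.assert_allclose(by_name["local_sd"], 0.0, atol=1e-12)
        np.testing.assert_allclose(by_name["glcm_energy"], 1.0)
        np.testing.assert_allclose(by_name["glcm_contrast"], 0.0)
        np.testing.assert_allclose(by_name["lbp"], 1.0)  # code 255, scaled

    def test_lbp_constant_codes_255(self):
        assert (lbp_map(np.full((8, 8), 0.3)) == 255).all()

    def test_window_glcm_matches_global_on_uniform_region(self):
        # far from borders, a window's GLCM of a periodic pattern matches the
        # global matrix of the same pattern
        img = (np.indices((32, 32)).sum(axis=0) % 2) * 0.99
        maps = glcm_window_maps(img, window=7, levels=2)
        assert maps["glcm_contrast"][16, 16] == pytest.approx(1.0)
        assert maps["glcm_homogeneity"][16, 16] == pytest.approx(0.5)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            texture_intensity_maps(np.zeros((8, 8)), window=4)

    def test_invalid_quantization_rejected(self):
        with pytest.raises(ValueError, match="invalid quantization"):
            glcm_matrix(np.zeros((4, 4)), levels=1)


# ---------------------------------------------------------------------------
# stacks


class TestFeatureStack:
    def test_hog_only_stack_has_nine_channels(self):
        rng = np.random.default_rng(7)
        img = rng.random((64, 64))
        stack = feature_stack((64, 64), hog_to_stack(hog_features(img)))
        assert stack.n_channels == 9
        assert stack.channels.shape == (9, 64, 64)

    def test_dsurf_upsampling_is_piecewise_constant(self):
        rng = np.random.default_rng(8)
        img = rng.random((64, 64))
        desc = dsurf_descriptors(img, step=8, window=16)
        stack = dsurf_to_channels(desc, (64, 64), step=8, window=16)
        assert stack.channels.shape == (64, 64, 64)
        # oracle: nearest keypoint by explicit distance minimization
        pts = [(d.keypoint.x, d.keypoint.y, d.vector) for d in desc]
        for y, x in [(0, 0), (13, 50), (31, 31), (63, 63), (40, 9)]:
            dists = [max(abs(px - x), 0) ** 2 + (py - y) ** 2 for px, py, _ in pts]
            # nearest in separable per-axis sense equals true nearest on a grid
            nearest = pts[int(np.argmin(dists))][2]
            np.testing.assert_array_equal(stack.channels[:, y, x], nearest)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="unaligned features"):
            feature_stack((32, 32))

    def test_shape_mismatch_rejected(self):
        stack = FeatureStack(channels=np.zeros((2, 16, 16)))
        with pytest.raises(ValueError, match="unaligned features"):
            feature_stack((32, 32), stack)

    def test_combined_stack_channel_bookkeeping(self):
        rng = np.random.default_rng(9)
        pixels = rng.random((4, 32, 32))
        stack = compute_feature_stack(
            pixels, features=("hog", "texture"), texture_window=5
        )
        assert stack.n_channels == 9 + 7
        assert np.isfinite(stack.channels).all()
        assert len(stack.names) == len(stack.provenance) == 16
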