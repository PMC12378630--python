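"""Preprocessing stages against brute-force oracles and invariants."""

import warnings

import numpy as np
import pytest
from mrkymo.phantom import geometry, breathing_phase
from mrkymo.preprocess import (
    binarize,
    median_denoise,
    preprocess_pipeline,
    skeletonize,
    sobel_magnitude,
    upsample,
)
from mrkymo.series import ImageSeries


def _series(frames, spacing=500 / 192, interval=0.6):
    return ImageSeries(np.asarray(frames, float), spacing, interval)


class TestUpsample:
    def test_spacing_rescaled_192_to_512(self):
        s = _series(np.zeros((2, 192, 192)))
        out = upsample(s, 512)
        assert s.pixel_spacing_mm == pytest.approx(2.604, abs=2e-3)
        assert out.pixel_spacing_mm == pytest.approx(0.977, abs=1e-3)
        assert out.shape == (512, 512)

    def test_physical_extent_conserved(self):
        s = _series(np.random.default_rng(0).random((1, 64, 64)), spacing=2.0)
        for target in (64, 100, 128, 333):
            out = upsample(s, target)
            assert out.fov_mm == pytest.approx(s.fov_mm)

    def test_constant_frame_stays_constant(self):
        s = _series(np.full((1, 32, 32), 7.5))
        out = upsample(s, 96)
        assert np.allclose(out.frames, 7.5)

    def test_identity_at_source_size(self):
        frames = np.random.default_rng(1).random((3, 32, 32))
        out = upsample(_series(frames), 32)
        assert np.array_equal(out.frames, frames)

    def test_downsampling_rejected(self):
        with pytest.raises(ValueError):
            upsample(_series(np.zeros((1, 64, 64))), 32)


class TestMedianDenoise:
    def test_constant_frame_identity(self):
        s = _series(np.full((2, 16, 16), 3.0))
        assert np.array_equal(median_denoise(s).frames, s.frames)

    def test_salt_pixel_removed(self):
        f = np.zeros((9, 9))
        f[4, 4] = 100.0
        out = median_denoise(_series(f[np.newaxis]))
        assert out.frames[0, 4, 4] == 0.0

    def test_matches_brute_force_median(self):
        rng = np.random.default_rng(2)
        f = rng.random((5, 5)) * 100
        out = median_denoise(_series(f[np.newaxis])).frames[0]
        for y in range(1, 4):
            for x in range(1, 4):
                window = sorted(f[y - 1:y + 2, x - 1:x + 2].ravel())
                assert out[y, x] == pytest.approx(window[4])

    def test_too_small_frame_rejected(self):
        with pytest.raises(ValueError):
            median_denoise(_series(np.zeros((1, 2, 2))))


def _sobel_oracle(frame: np.ndarray) -> np.ndarray:
    """Double-loop 3x3 Sobel convolution with edge replication."""
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], float)
    ky = kx.T
    h, w = frame.shape
    padded = np.pad(frame, 1, mode="edge")
    gx = np.zeros((h, w))
    gy = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            win = padded[y:y + 3, x:x + 3]
            # correlation with flipped kernel = convolution
            gx[y, x] = np.sum(win * kx[::-1, ::-1])
            gy[y, x] = np.sum(win * ky[::-1, ::-1])
    return np.sqrt(gx**2 + gy**2)


class TestSobelMagnitude:
    def test_constant_frame_zero(self):
        assert np.all(sobel_magnitude(np.full((8, 8), 5.0)) == 0)

    def test_vertical_step_magnitude_4h(self):
        h = 7.0
        f = np.zeros((8, 10))
        f[:, 5:] = h
        mag = sobel_magnitude(f)
        interior = mag[1:-1]
        assert np.allclose(interior[:, 4], 4 * h)
        assert np.allclose(interior[:, 5], 4 * h)
        assert np.allclose(interior[:, :4], 0) and np.allclose(interior[:, 6:], 0)

    def test_transpose_symmetry(self):
        f = np.random.default_rng(3).random((12, 12))
        assert np.allclose(sobel_magnitude(f.T), sobel_magnitude(f).T)

    def test_matches_direct_convolution(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            f = rng.random((16, 16)) * 200
            assert np.max(np.abs(sobel_magnitude(f) - _sobel_oracle(f))) < 1e-9


def _intermeans_fixed_point(frame: np.ndarray) -> float:
    """Brute-force iterative intermeans threshold on a 256-bin histogram."""
    lo, hi = frame.min(), frame.max()
    bins = np.clip(((frame - lo) / (hi - lo) * 255).astype(int), 0, 255)
    t = bins.mean()
    for _ in range(500):
        fg = bins > t
        t_new = (bins[fg].mean() + bins[~fg].mean()) / 2
        if abs(t_new - t) < 1e-9:
            break
        t = t_new
    return lo + t / 255 * (hi - lo)


class TestBinarize:
    def test_two_level_image_split_exactly(self):
        f = np.zeros((10, 10))
        f[3:6, 3:6] = 100.0
        mask, thr = binarize(f)
        assert np.array_equal(mask, f == 100.0)
        assert 0 < thr < 100

    def test_bimodal_threshold_matches_intermeans_fixed_point(self):
        rng = np.random.default_rng(5)
        f = np.concatenate([rng.normal(40, 6, 600), rng.normal(160, 12, 400)])
        f = np.clip(f, 0, 255).reshape(25, 40)
        _, thr = binarize(f)
        expected = _intermeans_fixed_point(f)
        gray_level = (f.max() - f.min()) / 256
        assert abs(thr - expected) <= 2 * gray_level

    def test_constant_image_empty_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            mask, thr = binarize(np.full((8, 8), 4.2))
        assert not mask.any()
        assert np.isnan(thr)


def _has_2x2_block(mask: np.ndarray) -> bool:
    return bool((mask[:-1, :-1] & mask[1:, :-1] & mask[:-1, 1:] & mask[1:, 1:]).any())


def _euler_number(mask: np.ndarray) -> int:
    from skimage.measure import euler_number

    return int(euler_number(mask, connectivity=2))


class TestSkeletonize:
    def test_thin_curve_unchanged(self):
        f = np.zeros((12, 12), bool)
        rr = np.arange(2, 10)
        f[rr, 5] = True
        assert np.array_equal(skeletonize(f), f)

    def test_thick_ring_becomes_thin_ring_same_topology(self):
        from skimage.morphology import disk

        ring = np.pad(disk(10) & ~np.pad(disk(7), 3), 2).astype(bool)
        out = skeletonize(ring)
        assert _euler_number(out) == _euler_number(ring) == 0  # one hole
        assert not _has_2x2_block(out)
        assert np.all(ring[out])  # subset of input

    def test_empty_frame(self):
        f = np.zeros((6, 6), bool)
        assert not skeletonize(f).any()

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        f = rng.random((40, 40)) > 0.6
        once = skeletonize(f)
        assert np.array_equal(skeletonize(once), once)

    def test_output_subset_of_input(self):
        rng = np.random.default_rng(7)
        f = rng.random((30, 30)) > 0.5
        out = skeletonize(f, prune_len=5)
        assert np.all(f[out])


class TestPipeline:
    def test_all_zero_series_gives_empty_contours_black_overlay(self):
        s = _series(np.zeros((2, 48, 48)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = preprocess_pipeline(s, 96)
        assert not res.contours.frames.any()
        assert np.all(res.overlay.frames == 0)

    def test_deterministic_rerun(self, noisy_coronal):
        _, series, _ = noisy_coronal
        sub = series.with_frames(series.frames[:3])
        r1 = preprocess_pipeline(sub, 256, with_overlay=False)
        r2 = preprocess_pipeline(sub, 256, with_overlay=False)
        assert np.array_equal(r1.contours.frames, r2.contours.frames)
        assert np.array_equal(r1.denoised.frames, r2.denoised.frames)

    def test_contour_fraction_below_10_percent(self, noisy_coronal):
        _, series, _ = noisy_coronal
        res = preprocess_pipeline(series.with_frames(series.frames[:3]), 512,
                                  with_overlay=False)
        for frame in res.contours.frames:
            assert frame.mean() < 0.10

    def test_overlay_offcontour_equals_denoised(self, noisy_coronal):
        _, series, _ = noisy_coronal
        res = preprocess_pipeline(series.with_frames(series.frames[:1]), 256)
        off = ~res.contours.frames[0]
        for c in range(3):
            assert np.allclose(res.overlay.frames[0, ..., c][off],
                               res.denoised.frames[0][off])

    def test_noiseless_phantom_contours_match_analytic_boundaries(self, noiseless_coronal):
        """>=99% of contour pixels lie within 1.5 px of an analytic boundary."""
        config, series, _ = noiseless_coronal
        res = preprocess_pipeline(series.with_frames(series.frames[:2]), 512,
                                  with_overlay=False)
        factor = 512 / config.matrix_size
        g = geometry(config)

        for t in range(2):
            phi = float(breathing_phase(config, t * config.frame_interval_s))
            dist = _distance_to_analytic_boundaries(config, g, phi, factor)
            ys, xs = np.nonzero(res.contours.frames[t])
            d = dist[ys, xs]
            assert np.mean(d <= 1.5) >= 0.99


def _distance_to_analytic_boundaries(config, g, phi, factor):
    """Distance map (px) to densely sampled analytic phantom boundary curves."""
    from scipy.ndimage import distance_transform_edt

    n = int(config.matrix_size * factor)
    spacing = config.fov_mm / n
    shift = config.amplitude_rl_mm / 2 * phi
    pts = []

    theta = np.linspace(0, 2 * np.pi, 8000)
    pts.append(np.column_stack([g.a * np.cos(theta), g.body_cy + g.b * np.sin(theta)]))

    for sign, amp in ((-1, config.amplitude_hf_right_mm), (1, config.amplitude_hf_left_mm)):
        cx = sign * (g.lung_cx + shift)
        xs = np.linspace(-g.lung_w, g.lung_w, 4000)
        dia = g.d0 + amp * phi + g.droop * (xs / g.lung_w) ** 2
        se_y = g.lung_hv * np.sqrt(np.clip(1 - np.abs(xs / g.lung_w) ** 8, 0, 1))
        top = g.lung_cy - se_y
        bottom = np.minimum(g.lung_cy + se_y, dia)
        keep = bottom > top
        pts.append(np.column_stack([cx + xs[keep], top[keep]]))
        pts.append(np.column_stack([cx + xs[keep], bottom[keep]]))
        # lateral superellipse walls between top and bottom
        ys = np.linspace(top.min(), bottom.max(), 4000)
        u = np.clip((ys - g.lung_cy) / g.lung_hv, -1, 1)
        half = g.lung_w * np.clip(1 - u * u, 0, 1) ** (1 / 8)
        for s2 in (-1, 1):
            wall_x = cx + s2 * half
            dia_w = g.d0 + amp * phi + g.droop * (s2 * half / g.lung_w) ** 2
            keep_w = ys <= dia_w
            pts.append(np.column_stack([wall_x[keep_w], ys[keep_w]]))
        if sign == -1:  # liver lateral edges below the right diaphragm
            for s2 in (-1, 1):
                ex = cx + s2 * (g.lung_w + 10.0)
                inside = (ex / g.a) ** 2 + ((np.linspace(g.d0, g.body_cy + g.b, 2000) - g.body_cy) / g.b) ** 2 < 1
                ys_l = np.linspace(g.d0, g.body_cy + g.b, 2000)[inside]
                pts.append(np.column_stack([np.full(ys_l.shape, ex), ys_l]))

    mm = np.concatenate(pts)
    cols = np.round((mm[:, 0] + config.fov_mm / 2) / spacing - 0.5).astype(int)
    rows = np.round((mm[:, 1] + config.fov_mm / 2) / spacing - 0.5).astype(int)
    ok = (rows >= 0) & (rows < n) & (cols >= 0) & (cols < n)
    grid = np.zeros((n, n), bool)
    grid[rows[ok], cols[ok]] = True
    return distance_transform_edt(~grid)
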