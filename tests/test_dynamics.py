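"""Binning, decomposition, foci criteria and ROI counting."""

import math

import numpy as np
import pytest
from scipy import ndimage

from glut4tirf import (
    AcquisitionGeometry,
    FocusDetection,
    SimulationConfig,
    TIRFMovie,
    bin_stack,
    count_in_rois,
    decompose_bin,
    detect_foci,
    make_roi_grid,
    preprocess_stack,
    run_dynamics,
    simulate_tirf_movie,
)


GEOM_2HZ = AcquisitionGeometry(frame_interval=0.5, exposure=0.5)


def gaussian_spot(shape, cy, cx, sigma, amp):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma ** 2))


# ---------------------------------------------------------------- oracle

def oracle_detect_foci(image, peak_min, containment_radius=5.0,
                       containment_fraction=0.75, min_radius=2.0):
    """Criteria (i)-(iii) checked at every pixel by brute force, then the
    same brighter-wins merge rule."""
    img = np.asarray(image, float)
    h, w = img.shape

    def disk_sum(y, x, radius):
        s = 0.0
        r = int(math.ceil(radius))
        for dy in range(-r, r + 1):
            for dx in range(-r, r + 1):
                if dy * dy + dx * dx <= radius * radius:
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < h and 0 <= xx < w:
                        s += img[yy, xx]
        return s

    min_area = sum(1 for dy in range(-3, 4) for dx in range(-3, 4)
                   if dy * dy + dx * dx <= min_radius * min_radius)

    # (i) local maxima, plateau reduced to lexicographically smallest pixel
    cands = []
    for y in range(h):
        for x in range(w):
            v = img[y, x]
            if v < peak_min:
                continue
            neigh = [img[y + dy, x + dx]
                     for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                     if not (dy == 0 and dx == 0)
                     and 0 <= y + dy < h and 0 <= x + dx < w]
            if any(n > v for n in neigh):
                continue
            cands.append((y, x, v))
    # reduce equal-valued plateaus: keep smallest (y, x) of each connected set
    is_max = np.zeros((h, w), bool)
    for y, x, _ in cands:
        is_max[y, x] = True
    labels, n = ndimage.label(is_max, structure=np.ones((3, 3)))
    reduced = []
    for lab in range(1, n + 1):
        ys, xs = np.nonzero(labels == lab)
        order = np.lexsort((xs, ys))
        y, x = int(ys[order[0]]), int(xs[order[0]])
        reduced.append((y, x, img[y, x]))

    accepted = []
    for y, x, v in reduced:
        s_in = disk_sum(y, x, containment_radius)
        s_out = disk_sum(y, x, 2 * containment_radius)
        if s_out <= 0 or s_in / s_out < containment_fraction:
            continue
        half = img >= v / 2.0
        lab_half, _ = ndimage.label(half, structure=np.ones((3, 3)))
        if int((lab_half == lab_half[y, x]).sum()) < min_area:
            continue
        accepted.append((y, x, v))

    accepted.sort(key=lambda t: (-t[2], t[0], t[1]))
    kept = []
    for y, x, v in accepted:
        if all(math.hypot(x - kx, y - ky) >= containment_radius
               for ky, kx, _ in kept):
            kept.append((y, x, v))
    return sorted((y, x) for y, x, _ in kept)


# --------------------------------------------------------------- binning

class TestBinStack:
    def _movie(self, n_frames, interval=0.5):
        geom = AcquisitionGeometry(frame_interval=interval,
                                   exposure=min(0.5, interval))
        return TIRFMovie(np.zeros((n_frames, 4, 4)), geom, 0)

    def test_27_minutes_at_2hz_gives_27_full_bins(self):
        ranges = bin_stack(self._movie(27 * 120), 60.0)
        assert len(ranges) == 27
        assert all(z - a == 120 for a, z in ranges)

    def test_sub_bin_movie_is_single_bin(self):
        assert bin_stack(self._movie(90), 60.0) == [(0, 90)]

    def test_short_remainder_merged(self):
        assert bin_stack(self._movie(150), 60.0) == [(0, 150)]

    def test_long_remainder_kept_separate(self):
        assert bin_stack(self._movie(200), 60.0) == [(0, 120), (120, 200)]

    def test_bins_are_contiguous_and_cover_movie(self):
        ranges = bin_stack(self._movie(1234), 60.0)
        assert ranges[0][0] == 0 and ranges[-1][1] == 1234
        for (a1, z1), (a2, z2) in zip(ranges, ranges[1:]):
            assert z1 == a2

    def test_single_frame_bins_rejected(self):
        with pytest.raises(ValueError):
            bin_stack(self._movie(100), 0.5)


# ---------------------------------------------------------- decomposition

class TestDecomposeBin:
    def test_identical_frames_are_all_static(self, rng):
        frame = rng.uniform(0, 10, (6, 6))
        stack = np.repeat(frame[None], 5, axis=0)
        mobile, static, avg = decompose_bin(stack)
        # identical frames leave nothing mobile (up to float epsilon in the mean)
        assert np.allclose(mobile, 0, atol=1e-12)
        assert np.allclose(static, stack)
        assert np.allclose(avg, frame)

    def test_single_flash_splits_by_mean(self):
        N = 4
        stack = np.zeros((N, 5, 5))
        stack[2, 3, 3] = 12.0
        mobile, static, _ = decompose_bin(stack)
        assert mobile[2, 3, 3] == pytest.approx(12.0 * (1 - 1 / N))
        assert static[2, 3, 3] == pytest.approx(12.0 / N)
        other = np.ones(N, bool)
        other[2] = False
        assert np.all(mobile[other] == 0)

    def test_conservation_is_bit_exact(self, rng):
        stack = rng.uniform(0, 50, (4, 6, 6))
        mobile, static, _ = decompose_bin(stack)
        assert np.array_equal(mobile + static, stack)
        assert np.all(mobile >= 0)
        assert np.all(static >= 0)

    def test_rejects_single_frame(self):
        with pytest.raises(ValueError):
            decompose_bin(np.zeros((1, 4, 4)))


# ------------------------------------------------------------------ foci

class TestDetectFoci:
    def test_blank_image_has_no_foci(self):
        assert detect_foci(np.zeros((20, 20)), peak_min=1.0) == []

    def test_single_compact_spot_detected_once(self):
        img = gaussian_spot((31, 31), 15, 15, 2.0, 100.0)
        foci = detect_foci(img, peak_min=10.0)
        assert len(foci) == 1
        assert (foci[0].y, foci[0].x) == (15, 15)
        assert foci[0].contained_fraction >= 0.75

    def test_broad_blob_rejected_by_containment(self):
        img = gaussian_spot((61, 61), 30, 30, 8.0, 100.0)
        assert detect_foci(img, peak_min=10.0) == []

    @pytest.mark.parametrize("sigma,expected", [(2.0, 1), (8.0, 0)])
    def test_agrees_with_bruteforce_oracle_on_spots(self, sigma, expected):
        img = gaussian_spot((31, 31), 15, 15, sigma, 100.0)
        got = sorted((f.y, f.x) for f in detect_foci(img, peak_min=10.0))
        assert got == oracle_detect_foci(img, peak_min=10.0)
        assert len(got) == expected

    def test_agrees_with_bruteforce_oracle_on_random_rasters(self, rng):
        for _ in range(8):
            img = ndimage.gaussian_filter(rng.uniform(0, 1, (16, 16)), 1.2)
            img = 100 * img / img.max()
            got = sorted((f.y, f.x) for f in detect_foci(img, peak_min=30.0))
            assert got == oracle_detect_foci(img, peak_min=30.0)

    def test_close_peaks_merged_to_brighter(self):
        img = gaussian_spot((31, 31), 15, 13, 2.0, 100.0) \
            + gaussian_spot((31, 31), 15, 16, 2.0, 80.0)
        foci = detect_foci(img, peak_min=10.0)
        assert len(foci) == 1

    def test_negative_raster_rejected(self):
        with pytest.raises(ValueError):
            detect_foci(np.full((5, 5), -1.0))


# ------------------------------------------------------------------- ROIs

class TestRois:
    def test_counts_by_construction(self):
        rois = [(0, 0, 10, 10), (0, 10, 10, 20)]
        foci = [FocusDetection(x, y, 1.0, 1.0, 3.0)
                for x, y in [(2, 2), (5, 5), (9, 9), (12, 3), (15, 8), (25, 25)]]
        assert count_in_rois(foci, rois) == [3, 2]

    def test_empty_focus_list(self):
        assert count_in_rois([], [(0, 0, 5, 5)]) == [0]

    def test_shared_edge_counts_once_half_open(self):
        rois = [(0, 0, 10, 10), (0, 10, 10, 20)]
        f = FocusDetection(x=10, y=5, peak_value=1.0,
                           contained_fraction=1.0, support_radius=3.0)
        assert count_in_rois([f], rois) == [0, 1]

    def test_roi_outside_image_rejected(self):
        with pytest.raises(ValueError):
            count_in_rois([], [(0, 0, 40, 40)], image_shape=(32, 32))

    def test_grid_has_requested_area(self):
        rois = make_roi_grid((256, 256), 0.1, n_rois=4)
        assert len(rois) == 4
        for y0, x0, y1, x1 in rois:
            assert (y1 - y0) == (x1 - x0) == 100

    def test_grid_too_small_rejected(self):
        with pytest.raises(ValueError):
            make_roi_grid((128, 128), 0.1, n_rois=2)


# ------------------------------------------------------------- end to end

def _sim(seed, mobile_pre, mobile_post, static_pre=3.0, static_post=3.0,
         diffusion=3e-3, duration_post=180):
    geom = AcquisitionGeometry(frame_interval=2.0, exposure=0.5)
    cfg = SimulationConfig(field_size=(128, 128), duration_pre=60,
                           duration_post=duration_post,
                           static_density_pre=static_pre,
                           static_density_post=static_post,
                           mobile_density_pre=mobile_pre,
                           mobile_density_post=mobile_post,
                           diffusion_coeff=diffusion,
                           transition_halftime=0.5, seed=seed)
    movie, truth = simulate_tirf_movie(cfg, geom)
    return preprocess_stack(movie), truth


class TestRunDynamics:
    def test_static_only_movie_has_no_mobile_counts(self):
        clean, _ = _sim(seed=31, mobile_pre=0, mobile_post=0,
                        static_pre=5, static_post=5)
        series = run_dynamics(clean, n_rois=1)
        assert series.table["mobile_count"].mean() < 0.3

    def test_identical_input_gives_identical_counts(self):
        clean, _ = _sim(seed=32, mobile_pre=1, mobile_post=2)
        t1 = run_dynamics(clean, n_rois=1).table
        t2 = run_dynamics(clean, n_rois=1).table
        assert t1.equals(t2)

    def test_mobile_counts_monotone_in_configured_density(self):
        means = []
        for density in (0.5, 2.0, 6.0):
            clean, _ = _sim(seed=33, mobile_pre=density, mobile_post=density)
            series = run_dynamics(clean, n_rois=1)
            means.append(series.table["mobile_count"].mean())
        assert means[0] <= means[1] <= means[2]

    def test_fast_pure_mobile_gives_blank_level_static_counts(self):
        """With fast diffusers only, the average projection holds no spots,
        so static counts stay at the blank-movie false-positive level."""
        clean, _ = _sim(seed=34, mobile_pre=3, mobile_post=3,
                        static_pre=0, static_post=0, diffusion=0.05)
        blank, _ = _sim(seed=35, mobile_pre=0, mobile_post=0,
                        static_pre=0, static_post=0)
        s_mobilemovie = run_dynamics(clean, n_rois=1).table["static_count"]
        s_blank = run_dynamics(blank, n_rois=1).table["static_count"]
        assert s_mobilemovie.mean() <= s_blank.mean() + 0.5
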