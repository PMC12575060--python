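"""Image-operation contracts checked against brute-force pixel oracles."""

import numpy as np
import pytest
from scipy import ndimage

import gedikit as gk
from gedikit.imageops import LabeledMask


# ---------------------------------------------------------------------------
# brute-force oracles (pixel loops; independent of the implementation path)
# ---------------------------------------------------------------------------


def rolling_ball_oracle(img: np.ndarray, radius: float) -> np.ndarray:
    """Grayscale opening with a ball kernel by explicit min/max loops."""
    R = int(np.ceil(radius))
    yy, xx = np.mgrid[-R : R + 1, -R : R + 1]
    fp = (yy**2 + xx**2) <= radius**2
    hh = np.where(fp, np.sqrt(np.maximum(radius**2 - (yy**2 + xx**2), 0)), 0)
    h, w = img.shape
    pad = np.pad(img, R, mode="edge")
    ero = np.empty_like(img)
    for i in range(h):
        for j in range(w):
            win = pad[i : i + 2 * R + 1, j : j + 2 * R + 1]
            ero[i, j] = np.min(win[fp] - hh[fp])
    pad2 = np.pad(ero, R, mode="edge")
    bg = np.empty_like(img)
    for i in range(h):
        for j in range(w):
            win = pad2[i : i + 2 * R + 1, j : j + 2 * R + 1]
            bg[i, j] = np.max(win[fp] + hh[fp])
    return np.clip(img - bg, 0.0, None)


def flood_fill_count(binary: np.ndarray, min_area: int) -> int:
    """4-connected component count by explicit stack-based flood fill."""
    seen = np.zeros_like(binary, dtype=bool)
    h, w = binary.shape
    n = 0
    for si in range(h):
        for sj in range(w):
            if binary[si, sj] and not seen[si, sj]:
                stack, area = [(si, sj)], 0
                seen[si, sj] = True
                while stack:
                    i, j = stack.pop()
                    area += 1
                    for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        ni, nj = i + di, j + dj
                        if (
                            0 <= ni < h and 0 <= nj < w
                            and binary[ni, nj] and not seen[ni, nj]
                        ):
                            seen[ni, nj] = True
                            stack.append((ni, nj))
                if area >= min_area:
                    n += 1
    return n


def measure_oracle(labels, red, green):
    """Per-object stats by explicit pixel iteration."""
    out = {}
    h, w = labels.shape
    for i in range(h):
        for j in range(w):
            lab = labels[i, j]
            if lab == 0:
                continue
            rec = out.setdefault(lab, [0, 0.0, 0.0, 0.0, 0.0])
            rec[0] += 1
            rec[1] += i
            rec[2] += j
            rec[3] += red[i, j]
            rec[4] += green[i, j]
    return {
        lab: {
            "area": a,
            "centroid": (si / a, sj / a),
            "mean_red": sr / a,
            "mean_green": sg / a,
        }
        for lab, (a, si, sj, sr, sg) in out.items()
    }


# ---------------------------------------------------------------------------
# rolling ball
# ---------------------------------------------------------------------------


class TestRollingBall:
    def test_flat_image_removed(self):
        out = gk.subtract_background_rolling_ball(np.full((40, 40), 7.0), 10)
        np.testing.assert_allclose(out, 0.0)

    @pytest.mark.parametrize("radius", [4.0, 6.5])
    def test_matches_brute_force_oracle(self, radius):
        rng = np.random.default_rng(0)
        img = ndimage.gaussian_filter(rng.uniform(0, 100, (32, 32)), 2)
        img += np.linspace(0, 30, 32)[None, :]
        mine = gk.subtract_background_rolling_ball(img, radius)
        oracle = rolling_ball_oracle(img, radius)
        np.testing.assert_allclose(mine, oracle, atol=1e-10)

    def test_blob_on_ramp_recovered(self):
        # narrow blob survives a radius-50 ball; linear ramp is removed
        yy, xx = np.mgrid[:64, :64]
        ramp = 0.5 * xx
        blob = 50.0 * np.exp(-(((yy - 32) ** 2 + (xx - 32) ** 2) / (2 * 3.0**2)))
        out = gk.subtract_background_rolling_ball(ramp + blob, 50)
        assert abs(out.max() - 50.0) / 50.0 < 0.05

    def test_output_nonnegative_and_below_input(self):
        rng = np.random.default_rng(1)
        for _ in range(3):
            img = rng.uniform(0, 50, (24, 24))
            out = gk.subtract_background_rolling_ball(img, 3)
            assert (out >= 0).all()
            assert (out <= img + 1e-9).all()  # opening is anti-extensive

    def test_radius_bounds(self):
        img = np.zeros((32, 32))
        with pytest.raises(ValueError):
            gk.subtract_background_rolling_ball(img, 0.5)
        with pytest.raises(ValueError):
            gk.subtract_background_rolling_ball(img, 32)


class TestDeconvolve:
    def test_sharpens_point_source(self):
        img = np.zeros((41, 41))
        img[20, 20] = 100.0
        blurred = ndimage.gaussian_filter(img, 2.0) + 1.0
        sharp = gk.deconvolve_gaussian(blurred, 2.0, n_iter=10)
        assert sharp.max() > blurred.max()

    def test_flux_conserved(self):
        rng = np.random.default_rng(2)
        img = ndimage.gaussian_filter(rng.uniform(1, 10, (48, 48)), 3)
        out = gk.deconvolve_gaussian(img, 1.5, n_iter=8)
        assert abs(out.sum() - img.sum()) / img.sum() < 0.01

    def test_flat_image_is_fixed_point(self):
        img = np.full((32, 32), 5.0)
        out = gk.deconvolve_gaussian(img, 2.0, n_iter=5)
        np.testing.assert_allclose(out, img, atol=1e-6)

    def test_invalid_inputs(self):
        img = np.ones((16, 16))
        with pytest.raises(ValueError):
            gk.deconvolve_gaussian(img, 2.0, n_iter=0)
        bad = img.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            gk.deconvolve_gaussian(bad, 2.0)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


class TestSegmentation:
    def test_blank_noise_gives_no_objects(self):
        cfg = gk.SimulationConfig(seed=3, n_cells=0, fov_shape=(96, 96))
        stack, _ = gk.simulate_timelapse(cfg)
        mask = gk.segment_cells(stack.frame(0, "red"), min_area_px=20)
        assert mask.n_objects == 0

    def test_disjoint_blobs_counted(self):
        img = np.zeros((100, 100))
        centers = [(15, 15), (15, 80), (50, 50), (85, 20), (85, 85)]
        for r, c in centers:
            img[r - 3 : r + 4, c - 3 : c + 4] = 100.0
        mask = gk.segment_cells(img, method="manual", manual_threshold=50.0,
                                min_area_px=10)
        assert mask.n_objects == 5
        binary = img >= 50.0
        assert flood_fill_count(binary, 10) == 5

    def test_subthreshold_bridge_keeps_objects_separate(self):
        img = np.zeros((40, 40))
        img[10:20, 5:15] = 100.0
        img[10:20, 25:35] = 100.0
        img[14, 15:25] = 30.0  # 1-px bridge below threshold
        mask = gk.segment_cells(img, method="manual", manual_threshold=50.0,
                                min_area_px=10)
        assert mask.n_objects == 2
        assert flood_fill_count(img >= 50.0, 10) == 2
        # bridge above threshold merges them (connectivity sanity)
        assert flood_fill_count(img >= 20.0, 10) == 1

    def test_min_area_filter_and_contiguous_labels(self):
        img = np.zeros((60, 60))
        img[5:25, 5:25] = 100.0   # 400 px
        img[40:42, 40:42] = 100.0  # 4 px, removed
        img[50:58, 10:18] = 100.0  # 64 px
        mask = gk.segment_cells(img, method="manual", manual_threshold=50.0,
                                min_area_px=20)
        assert mask.n_objects == 2
        assert set(np.unique(mask.labels)) == {0, 1, 2}

    def test_manual_requires_threshold(self):
        with pytest.raises(ValueError):
            gk.segment_cells(np.ones((8, 8)), method="manual")

    def test_simulated_cells_all_found(self, timelapse_small):
        stack, truth, cfg = timelapse_small
        mask = gk.segment_cells(stack.frame(0, "red"), min_area_px=20)
        assert mask.n_objects == cfg.n_cells

    def test_translation_equivariance(self):
        cfg = gk.SimulationConfig(seed=14, n_cells=8, fov_shape=(160, 160))
        stack, _ = gk.simulate_timelapse(cfg)
        img = stack.frame(0, "red")
        big = np.full((260, 260), cfg.background_offset)
        a = big.copy()
        a[:160, :160] = img
        b = big.copy()
        b[37 : 37 + 160, 53 : 53 + 160] = img
        thr = 60.0
        ma = gk.segment_cells(a, method="manual", manual_threshold=thr, min_area_px=20)
        mb = gk.segment_cells(b, method="manual", manual_threshold=thr, min_area_px=20)
        assert ma.n_objects == mb.n_objects
        areas_a = sorted(np.bincount(ma.labels.ravel())[1:])
        areas_b = sorted(np.bincount(mb.labels.ravel())[1:])
        assert areas_a == areas_b


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------


class TestMeasurement:
    def test_hand_arithmetic_square(self):
        labels = np.zeros((8, 8), dtype=int)
        labels[2:5, 3:6] = 1
        red = np.where(labels == 1, 10.0, 0.0)
        green = np.where(labels == 1, 5.0, 0.0)
        (m,) = gk.measure_objects(LabeledMask(labels), red, green)
        assert m.area_px == 9
        assert m.gedi_ratio == pytest.approx(0.5)
        assert m.centroid == pytest.approx((3.0, 4.0))

    def test_ratio_scale_invariance(self):
        labels = np.zeros((8, 8), dtype=int)
        labels[1:4, 1:4] = 1
        rng = np.random.default_rng(4)
        red = rng.uniform(1, 10, (8, 8))
        green = rng.uniform(1, 10, (8, 8))
        (m1,) = gk.measure_objects(LabeledMask(labels), red, green)
        (m7,) = gk.measure_objects(LabeledMask(labels), 7 * red, 7 * green)
        assert m7.gedi_ratio == pytest.approx(m1.gedi_ratio)

    def test_matches_pixel_loop_oracle(self):
        rng = np.random.default_rng(5)
        labels = np.zeros((32, 32), dtype=int)
        labels[4:12, 4:14] = 1
        labels[20:29, 18:27] = 2
        red = rng.uniform(0.5, 20, (32, 32))
        green = rng.uniform(0.5, 20, (32, 32))
        ms = gk.measure_objects(LabeledMask(labels), red, green)
        oracle = measure_oracle(labels, red, green)
        for m in ms:
            o = oracle[m.cell_id]
            assert m.area_px == o["area"]
            assert m.centroid == pytest.approx(o["centroid"], abs=1e-10)
            assert m.mean_red == pytest.approx(o["mean_red"], abs=1e-10)
            assert m.gedi_ratio == pytest.approx(
                o["mean_green"] / o["mean_red"], abs=1e-10
            )

    def test_zero_red_flagged(self):
        labels = np.zeros((8, 8), dtype=int)
        labels[1:4, 1:4] = 1
        red = np.zeros((8, 8))
        green = np.ones((8, 8))
        (m,) = gk.measure_objects(LabeledMask(labels), red, green)
        assert m.flagged
        assert np.isnan(m.gedi_ratio)


# ---------------------------------------------------------------------------
# puncta detection
# ---------------------------------------------------------------------------


def disk_cell(shape=(48, 48), center=(24, 24), radius=16, value=50.0):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    inside = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
    img = np.where(inside, value, 0.0)
    labels = inside.astype(int)
    return img, LabeledMask(labels)


class TestPunctaDetection:
    def test_uniform_cell_no_puncta(self):
        img, mask = disk_cell()
        (f,) = gk.detect_puncta(img, mask)
        assert f.puncta_count == 0

    def test_bright_peaks_counted(self):
        img, mask = disk_cell()
        spots = [(16, 16), (16, 32), (32, 16), (32, 32)]
        for r, c in spots:
            img[r, c] = 600.0  # 12x background of 50
        (f,) = gk.detect_puncta(img, mask, fold_over_background=10)
        assert f.puncta_count == 4
        assert all(p >= 10 * f.cell_background for p in f.peak_intensities)

    def test_subthreshold_peaks_ignored(self):
        img, mask = disk_cell()
        for r, c in [(16, 16), (32, 32)]:
            img[r, c] = 250.0  # 5x background
        (f,) = gk.detect_puncta(img, mask, fold_over_background=10)
        assert f.puncta_count == 0

    def test_tiny_cell_recorded_missing(self):
        labels = np.zeros((16, 16), dtype=int)
        labels[2:4, 2:4] = 1  # 4 px < 9
        (f,) = gk.detect_puncta(np.ones((16, 16)), LabeledMask(labels))
        assert f.puncta_count is None

    def test_matches_neighborhood_max_oracle(self):
        # well-separated single-pixel peaks: detection equals an explicit
        # "strict maximum in its (2*sep+1)^2 window above threshold" scan
        rng = np.random.default_rng(6)
        img, mask = disk_cell(shape=(64, 64), center=(32, 32), radius=24)
        positions = [(16, 16), (16, 44), (44, 16), (44, 44), (32, 32)]
        for k, (r, c) in enumerate(positions):
            img[r, c] = 520.0 + 10 * k
        (f,) = gk.detect_puncta(img, mask, fold_over_background=10,
                                min_separation_px=3)
        # oracle: background by the same exclusion rule, explicit loops
        pix = img[mask.labels == 1]
        init = np.median(pix)
        bg = np.median(pix[pix <= 10 * init])
        thr = 10 * bg
        sep = 3
        count = 0
        for i in range(64):
            for j in range(64):
                if mask.labels[i, j] != 1 or img[i, j] < thr:
                    continue
                win = img[max(0, i - sep) : i + sep + 1,
                          max(0, j - sep) : j + sep + 1]
                if img[i, j] == win.max() and (win == img[i, j]).sum() == 1:
                    count += 1
        assert f.puncta_count == count == 5

    def test_simulator_recall_and_precision(self):
        # >= 200 cells at 12x amplitude: count-level recall/precision >= 0.95
        cfg = gk.SimulationConfig(
            seed=15, n_cells=200, fov_shape=(1200, 1200), cell_radius_px=20,
            timepoints_h=(3.0,), radiation_dose_Gy=4.0,
            puncta_amplitude_fold=12.0,
        )
        stack, truth = gk.simulate_foci_images(cfg)
        img = stack.frame(0, "red")
        sm = ndimage.median_filter(img, size=5)
        mask = gk.segment_cells(sm, min_area_px=50)
        foci = gk.detect_puncta(img, mask, 10.0, 3)
        ms = gk.measure_objects(mask, img, img)
        from scipy.spatial import cKDTree

        tr = truth.per_timepoint
        tree = cKDTree(np.c_[tr["row"], tr["col"]])
        _, idx = tree.query([m.centroid for m in ms])
        true_counts = tr["puncta_count"].to_numpy()[idx]
        det_counts = np.array([f.puncta_count for f in foci])
        tp = np.minimum(det_counts, true_counts).sum()
        recall = tp / true_counts.sum()
        precision = tp / det_counts.sum()
        assert recall >= 0.95
        assert precision >= 0.95
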