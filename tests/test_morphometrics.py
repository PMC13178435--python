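"""Segmentation and shape measurement against analytic and generated ground truth."""

import numpy as np
import pytest
from scipy import ndimage

from orgaprint import morphometrics as mm
from orgaprint import synthetic
from orgaprint.datatypes import LabelMask, MicroscopyImage
from orgaprint.synthetic import ImageSimSpec

from conftest import disk_mask


def _as_mask(bool_img, um_per_px=1.0):
    labels, _ = ndimage.label(bool_img, structure=np.ones((3, 3), int))
    return LabelMask(labels=labels.astype(np.int32), um_per_px=um_per_px)


class TestSegmentation:
    def test_printed_array_count_and_area(self, printed_array_image):
        img, truth = printed_array_image
        mask = mm.segment_organoids(img, min_area_um2=5000.0, exclude_border=False)
        assert mask.n_objects == len(truth)
        meas = sorted(r.area for r in mm.measure_organoids(mask))
        true = sorted(np.pi * truth["radius_um"] ** 2)
        for m, t in zip(meas, true):
            assert abs(m - t) / t < 0.02

    def test_size_filter_excludes_speck(self, printed_array_image):
        img, truth = printed_array_image
        # paint in a speck below the 5,000 um^2 cut (4,000 um^2 at 2 um/px)
        r_px = np.sqrt(4000.0 / np.pi) / img.um_per_px
        speck = disk_mask(img.pixels.shape, (60.0, 60.0), r_px)
        px = np.where(speck, 1.0, img.pixels)
        img2 = MicroscopyImage(pixels=px, um_per_px=img.um_per_px)
        assert mm.segment_organoids(img2, min_area_um2=5000.0, exclude_border=False).n_objects == len(truth)
        assert mm.segment_organoids(img2, min_area_um2=0.0, exclude_border=False).n_objects == len(truth) + 1

    def test_blank_image_empty_mask(self):
        img = MicroscopyImage(pixels=np.zeros((256, 256)), um_per_px=2.0)
        assert mm.segment_organoids(img).n_objects == 0

    def test_border_object_excluded_or_kept(self):
        half = disk_mask((300, 300), (0.0, 150.0), 80.0)
        img = MicroscopyImage(pixels=half.astype(float), um_per_px=1.0)
        on = mm.segment_organoids(img, blur_sigma_um=2.0, min_area_um2=0.0, exclude_border=True)
        off = mm.segment_organoids(img, blur_sigma_um=2.0, min_area_um2=0.0, exclude_border=False)
        assert on.n_objects == 0
        assert off.n_objects == 1

    def test_recall_precision_on_noisy_array(self):
        # SNR = foreground/noise_sd = 10
        spec = ImageSimSpec(
            shape_px=(900, 900), um_per_px=2.0, mode="printed", n_organoids=9,
            radius_mean_um=100.0, radius_cv=0.05, pitch_um=500.0, noise_sd=0.1,
            blur_sigma_um=4.0, seed=21,
        )
        img, truth = synthetic.gen_organoid_image(spec)
        mask = mm.segment_organoids(img, min_area_um2=5000.0, exclude_border=False)
        assert mask.n_objects == len(truth)  # recall and precision both 1
        recs = mm.measure_organoids(mask)
        found = np.array([r.centroid for r in recs])
        for _, row in truth.iterrows():
            d = np.hypot(found[:, 0] - row.centroid_row, found[:, 1] - row.centroid_col)
            assert d.min() < 5.0  # px


class TestSizeFilterBoundary:
    def test_exact_area_cut(self):
        # two squares: 70x70 = 4900 px and 71x71 = 5041 px at 1 um/px
        field = np.zeros((300, 300), dtype=np.int32)
        field[10:80, 10:80] = 1
        field[120:191, 120:191] = 2
        mask = LabelMask(labels=field, um_per_px=1.0)
        kept = mm.filter_labels(mask, min_area_um2=4900.0)
        assert kept.n_objects == 2  # area == min_area is kept
        kept = mm.filter_labels(mask, min_area_um2=4901.0)
        assert kept.n_objects == 1  # area == min_area - 1 removed


class TestMeasurement:
    def test_disk_area_and_circularity(self):
        mask = _as_mask(disk_mask((300, 300), (150.0, 150.0), 100.0))
        rec = mm.measure_organoids(mask)[0]
        assert abs(rec.area - np.pi * 1e4) / (np.pi * 1e4) < 0.02
        assert abs(rec.circularity - 1.0) < 0.03

    def test_square_circularity(self):
        field = np.zeros((200, 200), dtype=bool)
        field[50:150, 50:150] = True
        rec = mm.measure_organoids(_as_mask(field))[0]
        assert abs(rec.circularity - np.pi / 4) / (np.pi / 4) < 0.03

    def test_lobed_flower_less_circular(self):
        mask = _as_mask(disk_mask((400, 400), (200.0, 200.0), 100.0, lobes=5, lobe_amp=0.3))
        rec = mm.measure_organoids(mask)[0]
        assert rec.circularity < 0.75

    def test_circularity_scale_invariant(self):
        small = _as_mask(disk_mask((200, 200), (100.0, 100.0), 60.0), um_per_px=1.0)
        large = _as_mask(disk_mask((600, 600), (300.0, 300.0), 180.0), um_per_px=5.0)
        c1 = mm.measure_organoids(small)[0].circularity
        c2 = mm.measure_organoids(large)[0].circularity
        assert abs(c1 - c2) < 0.01

    @pytest.mark.parametrize("lobes", [3, 5])
    def test_circularity_decreases_with_lobe_amp(self, lobes):
        circs = []
        for amp in (0.0, 0.1, 0.2, 0.3):
            mask = _as_mask(disk_mask((400, 400), (200.0, 200.0), 100.0, lobes, amp))
            circs.append(mm.measure_organoids(mask)[0].circularity)
        assert np.all(np.diff(circs) < 0)


class TestCryptCounting:
    def test_disk_has_no_crypts(self):
        assert mm.count_crypts(disk_mask((300, 300), (150.0, 150.0), 100.0)) == 0

    @pytest.mark.parametrize("lobes", [3, 5, 7])
    @pytest.mark.parametrize("amp", [0.15, 0.3])
    def test_counts_match_generator_lobes(self, lobes, amp):
        mask = disk_mask((400, 400), (200.0, 200.0), 100.0, lobes, amp)
        assert mm.count_crypts(mask) == lobes

    def test_sub_threshold_lobes_count_zero(self):
        mask = disk_mask((400, 400), (200.0, 200.0), 100.0, lobes=5, lobe_amp=0.01)
        assert mm.count_crypts(mask) == 0

    def test_tiny_object_rejected(self):
        tiny = np.zeros((20, 20), dtype=bool)
        tiny[8:11, 8:11] = True
        with pytest.raises(ValueError, match="too small"):
            mm.count_crypts(tiny)


class TestTracking:
    def test_identity_across_frames(self, printed_array_image):
        img, _ = printed_array_image
        mask = mm.segment_organoids(img, min_area_um2=5000.0, exclude_border=False)
        series = mm.track_organoids([mask, mask], [0.0, 60.0])
        assert len(series.track_ids) == mask.n_objects
        for track in series.track_ids:
            assert len(series.trajectory(int(track))) == 2

    def test_vanishing_object_terminates(self):
        m1 = _as_mask(disk_mask((300, 300), (80.0, 80.0), 40.0) | disk_mask((300, 300), (220.0, 220.0), 40.0))
        m2 = _as_mask(disk_mask((300, 300), (80.0, 80.0), 40.0))
        series = mm.track_organoids([m1, m2], [0.0, 60.0])
        lengths = sorted(len(series.trajectory(int(t))) for t in series.track_ids)
        assert lengths == [1, 2]

    def test_symmetric_swap_resolved_by_lowest_label(self):
        a = disk_mask((300, 300), (150.0, 100.0), 30.0)
        b = disk_mask((300, 300), (150.0, 200.0), 30.0)
        m1 = _as_mask(a | b)
        # both objects move to midpoint-symmetric positions: equal distances
        c = disk_mask((300, 300), (150.0, 140.0), 9.0)
        d = disk_mask((300, 300), (150.0, 160.0), 9.0)
        m2 = _as_mask(c | d)
        series = mm.track_organoids([m1, m2], [0.0, 60.0], max_disp_um=100.0)
        t1 = series.trajectory(1)
        # lowest previous label claims the nearest new object first
        assert t1["centroid_col"].iloc[1] == pytest.approx(140.0, abs=1.0)

    def test_duplicate_times_rejected(self):
        m = _as_mask(disk_mask((100, 100), (50.0, 50.0), 20.0))
        with pytest.raises(ValueError, match="duplicate"):
            mm.track_organoids([m, m], [0.0, 0.0])


class TestPerimeterStrain:
    def test_scaled_mask_strain(self):
        m1 = _as_mask(disk_mask((400, 400), (200.0, 200.0), 100.0))
        m2 = _as_mask(disk_mask((400, 400), (200.0, 200.0), 110.0))
        series = mm.track_organoids([m1, m2], [0.0, 3600.0])
        strains = mm.perimeter_strain(series, 3600.0)
        assert strains[1][0] == pytest.approx(0.10, abs=0.001)

    def test_no_change_zero_strain(self):
        m = _as_mask(disk_mask((400, 400), (200.0, 200.0), 100.0))
        series = mm.track_organoids([m, m], [0.0, 3600.0])
        assert mm.perimeter_strain(series, 3600.0)[1][0] == 0.0

    def test_exponential_growth_closed_form(self):
        # P(t) = P0 e^{gt}; choose g*w = 0.0953 -> strain = e^0.0953 - 1 = 0.100
        radii = 100.0 * np.exp(0.0953 / 2 * np.arange(3))  # two windows of w
        masks = [_as_mask(disk_mask((500, 500), (250.0, 250.0), r)) for r in radii]
        series = mm.track_organoids(masks, [0.0, 1800.0, 3600.0])
        strains = mm.perimeter_strain(series, 3600.0)
        assert strains[1][0] == pytest.approx(np.exp(0.0953) - 1.0, abs=0.002)

    def test_window_longer_than_span_rejected(self):
        m = _as_mask(disk_mask((400, 400), (200.0, 200.0), 100.0))
        series = mm.track_organoids([m, m], [0.0, 100.0])
        with pytest.raises(ValueError):
            mm.perimeter_strain(series, 3600.0)


class TestTubeMetrics:
    def test_rectangle_exact_diameter(self):
        stack = np.zeros((1, 150, 1000), dtype=bool)
        stack[0, 25:125, :] = True
        df = mm.tube_metrics(stack, um_per_px=1.0, baseline_frames=np.array([True]))
        assert df["diameter_um"].iloc[0] == pytest.approx(100.0)

    def test_generated_square_wave_plateau(self):
        spec = synthetic.TubeSimSpec(baseline_diam_um=100.0, peak_strain=0.3, um_per_px=1.0)
        stack, truth = synthetic.gen_tube_series(spec)
        df = mm.tube_metrics(stack, um_per_px=1.0, baseline_frames=~truth.flow_on.to_numpy())
        peak = df.loc[truth.flow_on.to_numpy(), "strain"]
        assert np.all(np.abs(peak - 0.3) <= 0.01)  # 1 px on 100 px baseline

    def test_sinusoidal_width_mean(self):
        n, rows, cols = 40, 160, 500
        stack = np.zeros((n, rows, cols), dtype=bool)
        widths = 100.0 + 10.0 * np.sin(2 * np.pi * np.arange(n) / n)
        for k, w in enumerate(widths):
            half = w / 2.0
            rr = np.arange(rows)
            stack[k, (rr >= 80 - half) & (rr < 80 + half), :] = True
        df = mm.tube_metrics(stack, um_per_px=1.0, baseline_frames=np.ones(n, bool))
        assert df["diameter_um"].mean() == pytest.approx(100.0, rel=0.005)

    def test_empty_frame_rejected(self):
        stack = np.zeros((2, 50, 100), dtype=bool)
        stack[0, 10:20, :] = True
        with pytest.raises(ValueError):
            mm.tube_metrics(stack, um_per_px=1.0)


class TestBoundaryOccupancy:
    def test_uniform_and_alternating(self):
        occ, _ = mm.boundary_occupancy(["MEP"] * 50, "LEP")
        assert occ == 0.0
        occ, _ = mm.boundary_occupancy(["LEP", "MEP"] * 50, "LEP")
        assert occ == 0.5

    def test_random_assignment_matches_composition(self, rng):
        classes = np.where(rng.random(10_000) < 0.3, "LEP", "MEP")
        occ, expected = mm.boundary_occupancy(classes, "LEP", composition_fraction=0.3)
        assert abs(occ - 0.3) < 0.01
        assert expected == 0.3

    def test_empty_boundary_rejected(self):
        with pytest.raises(ValueError):
            mm.boundary_occupancy([], "LEP")
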