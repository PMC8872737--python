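"""Synthetic plate rendering, pore removal, detection and registration."""

import numpy as np
import pytest

from beadmap import plate_vision as pv


def simple_layout():
    return [
        ((60.0, 60.0), 10.0, "marker_A"),
        ((180.0, 70.0), 20.0, "marker_T"),
        ((300.0, 60.0), 30.0, "marker_C"),
        ((420.0, 80.0), 18.0, "cell"),
    ]


class TestSynthPlate:
    def test_empty_layout_uniform_background(self):
        img, truth = pv.synth_plate([], pore_density=0, noise_sd=0, seed=1)
        assert np.ptp(img.pixels) == 0.0
        assert len(truth.centroids) == 0

    def test_single_disk_centroid(self):
        img, _ = pv.synth_plate(
            [((100.0, 100.0), 30.0, "marker_C")],
            pore_density=0, noise_sd=0, pixel_size=2.5, shape_um=(200, 200), seed=1,
        )
        w = img.pixels - img.pixels.min()
        yy, xx = np.mgrid[: w.shape[0], : w.shape[1]]
        cy = ((yy + 0.5) * w).sum() / w.sum() * img.pixel_size
        cx = ((xx + 0.5) * w).sum() / w.sum() * img.pixel_size
        assert abs(cx - 100.0) < img.pixel_size and abs(cy - 100.0) < img.pixel_size

    def test_truth_classes_recorded(self):
        _, truth = pv.synth_plate(simple_layout(), pore_density=0, seed=1)
        assert truth.classes == ["marker_A", "marker_T", "marker_C", "cell"]

    def test_overlapping_layout_rejected(self):
        layout = [((50.0, 50.0), 30.0, "marker_C"), ((60.0, 50.0), 30.0, "marker_C")]
        with pytest.raises(ValueError):
            pv.synth_plate(layout, seed=1)
        img, _ = pv.synth_plate(layout, allow_overlap=True, seed=1)  # doublet fixture
        assert img.pixels.max() > 0.5

    def test_image_save_load_round_trip(self, tmp_path):
        img, _ = pv.synth_plate(simple_layout(), pore_density=100, seed=2)
        img.save(tmp_path / "plate.tiff")
        back = pv.PlateImage.load(tmp_path / "plate.tiff")
        assert back.pixel_size == img.pixel_size
        assert np.allclose(back.pixels, np.clip(img.pixels, 0, 1), atol=1e-6)


class TestRemovePores:
    def test_pores_only_empty_mask(self):
        img, _ = pv.synth_plate([], pore_density=300, pore_diameter=4,
                                noise_sd=0.01, shape_um=(300, 300), seed=3)
        mask = pv.remove_pores(img, max_pore_diameter=8.0)
        assert mask.sum() == 0

    def test_bead_survives_pore_removal(self):
        from skimage import measure

        img, _ = pv.synth_plate(
            [((150.0, 150.0), 20.0, "marker_T")],
            pore_density=300, pore_diameter=4, noise_sd=0.01,
            shape_um=(300, 300), seed=4,
        )
        mask = pv.remove_pores(img, max_pore_diameter=8.0)
        assert measure.label(mask).max() == 1

    def test_zero_cutoff_keeps_mask(self):
        img, _ = pv.synth_plate(simple_layout(), pore_density=0, noise_sd=0, seed=1)
        m0 = pv.remove_pores(img, max_pore_diameter=0.0)
        m8 = pv.remove_pores(img, max_pore_diameter=8.0)
        assert m0.sum() >= m8.sum() > 0

    def test_cutoff_must_stay_below_bead_size(self):
        img, _ = pv.synth_plate(simple_layout(), seed=1)
        with pytest.raises(ValueError):
            pv.remove_pores(img, max_pore_diameter=12.0)


class TestDetectClassify:
    def detect(self, seed=5, noise=0.02):
        img, truth = pv.synth_plate(
            simple_layout(), pore_density=200, pore_diameter=4,
            noise_sd=noise, pixel_size=2.5, shape_um=(150, 500), seed=seed,
        )
        mask = pv.remove_pores(img, 8.0)
        return pv.detect_objects(mask, img.pixel_size, img.pixels), truth, img

    def test_empty_mask_no_objects(self):
        assert pv.detect_objects(np.zeros((50, 50), bool), 2.5) == []

    def test_count_and_diameters(self):
        objects, truth, _ = self.detect()
        assert len(objects) == len(truth.centroids)
        for obj in objects:
            true_d = min(truth.diameters, key=lambda d: abs(d - obj.equivalent_diameter))
            assert abs(obj.equivalent_diameter - true_d) / true_d < 0.10

    def test_size_classification(self):
        objects, truth, _ = self.detect()
        objects = pv.classify_by_size(objects)
        got = {}
        for obj in objects:
            i = int(np.argmin([np.hypot(obj.centroid[0] - c[0], obj.centroid[1] - c[1])
                               for c in truth.centroids]))
            got[truth.classes[i]] = obj.object_class
        assert got["marker_A"] == "marker_A"
        assert got["marker_C"] == "marker_C"

    def test_unknown_outside_bands(self):
        obj = pv.DetectedObject((0.0, 0.0), 55.0)
        assert pv.classify_by_size([obj])[0].object_class == "unknown"

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValueError):
            pv.classify_by_size([], {"a": (5.0, 15.0), "b": (10.0, 20.0)})

    def test_classification_invariant_to_intensity_scaling(self):
        objects, _, img = self.detect()
        scaled = pv.PlateImage(img.pixels * 0.5, img.pixel_size)
        mask = pv.remove_pores(scaled, 8.0)
        objects2 = pv.detect_objects(mask, scaled.pixel_size, scaled.pixels)
        d1 = sorted(o.equivalent_diameter for o in objects)
        d2 = sorted(o.equivalent_diameter for o in objects2)
        assert np.allclose(d1, d2, rtol=0.02)


class TestRegistration:
    def test_first_marker_becomes_origin(self):
        objects = pv.classify_by_size(
            [pv.DetectedObject((500.0, 40.0), 20.0), pv.DetectedObject((120.0, 80.0), 30.0)]
        )
        registered, ref = pv.register_coordinates(objects)
        assert ref.centroid == (120.0, 80.0)
        assert registered[1].centroid == (0.0, 0.0)

    def test_translation_preserves_pairwise_distances(self):
        rng = np.random.default_rng(6)
        objects = [pv.DetectedObject((float(x), float(y)), 30.0, "marker_C")
                   for x, y in rng.uniform(0, 1000, (10, 2))]
        registered, _ = pv.register_coordinates(objects)
        before = [np.hypot(a.centroid[0] - b.centroid[0], a.centroid[1] - b.centroid[1])
                  for a in objects for b in objects]
        after = [np.hypot(a.centroid[0] - b.centroid[0], a.centroid[1] - b.centroid[1])
                 for a in registered for b in registered]
        assert np.allclose(before, after)

    def test_no_marker_is_error(self):
        with pytest.raises(ValueError):
            pv.register_coordinates([pv.DetectedObject((0.0, 0.0), 18.0, "cell")])

    def test_end_to_end_localization_within_10um(self):
        rng = np.random.default_rng(7)
        sizes = [10.0, 20.0, 30.0] * 2 + [18.0] * 10
        xs = np.arange(len(sizes)) * 120.0 + 60.0
        ys = 60.0 + 40.0 * rng.random(len(sizes))
        layout = [((float(x), float(y)), s, pv.SIZE_TO_CLASS.get(s, "cell"))
                  for x, y, s in zip(xs, ys, sizes)]
        img, truth = pv.synth_plate(layout, pore_density=200, pore_diameter=4,
                                    noise_sd=0.02, pixel_size=2.5,
                                    shape_um=(200.0, xs[-1] + 120.0), seed=8)
        mask = pv.remove_pores(img, 8.0)
        objects = pv.classify_by_size(pv.detect_objects(mask, img.pixel_size, img.pixels))
        assert len(objects) == len(layout)  # recall and precision both 100%
        registered, ref = pv.register_coordinates(objects)
        truth_xy = np.asarray(truth.centroids)
        ref_i = int(np.argmin(np.hypot(truth_xy[:, 0] - ref.centroid[0],
                                       truth_xy[:, 1] - ref.centroid[1])))
        truth_reg = truth_xy - truth_xy[ref_i]
        errs = [
            min(np.hypot(t[0] - o.centroid[0], t[1] - o.centroid[1])
                for o in registered)
            for t in truth_reg
        ]
        assert max(errs) <= 10.0
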