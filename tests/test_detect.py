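"""Spot enhancement, object identification and measurement contracts."""

import numpy as np
import pytest
import scipy.ndimage as ndi

from rcpscope import preprocess
from rcpscope.detect import (DetectionConfig, annulus_pixels, enhance_spots,
                             identify_objects, match_to_truth,
                             measure_across_channels, objects_to_frame)
from rcpscope.preprocess import ChannelImage, RegisteredImageSet
from rcpscope.synthscope import SceneConfig, render_scene


def _gauss_spot(shape, row, col, amp, sigma):
    rr, cc = np.mgrid[:shape[0], :shape[1]]
    return amp * np.exp(-((rr - row) ** 2 + (cc - col) ** 2) / (2 * sigma ** 2))


def _regset_from(images: dict) -> RegisteredImageSet:
    labels = list(images)
    return RegisteredImageSet(
        reference_label=labels[0],
        images={k: ChannelImage(k, v) for k, v in images.items()},
        shifts={k: (0.0, 0.0) for k in labels})


class TestEnhanceSpots:
    def test_flat_field_maps_to_zero(self):
        out = enhance_spots(ChannelImage("cy3", np.full((64, 64), 0.2)), 4)
        assert np.abs(out.data).max() < 1e-12

    def test_small_spot_preserved_background_removed(self):
        # 3-px-diameter plateau on a 0.2 background
        img = np.full((64, 64), 0.2)
        rr, cc = np.mgrid[:64, :64]
        img[(rr - 32) ** 2 + (cc - 32) ** 2 <= 1.5 ** 2] += 0.3
        out = enhance_spots(ChannelImage("cy3", img), 4)
        assert out.data[32, 32] == pytest.approx(0.3, rel=0.05)
        assert np.abs(out.data[:16]).max() <= 1e-6

    def test_broad_gradient_suppressed(self):
        ramp = np.tile(np.linspace(0, 0.8, 512), (64, 1))
        out = enhance_spots(ChannelImage("cy3", ramp), 5)
        assert out.data.max() < 0.1 * 0.8

    def test_bad_radius(self):
        with pytest.raises(ValueError):
            enhance_spots(ChannelImage("cy3", np.zeros((8, 8))), 0)


class TestIdentifyObjects:
    def test_ten_spots_recovered_at_truth_positions(self, rng):
        shape = (256, 256)
        img = np.zeros(shape)
        centres = [(30 + 20 * i, 40 + 17 * i) for i in range(10)]
        for i, (r, c) in enumerate(centres):
            img += _gauss_spot(shape, r, c, 0.3, 0.8 + 0.08 * i)
        objs = identify_objects(ChannelImage("cy3", img),
                                DetectionConfig(intensity_threshold=0.1))
        assert len(objs) == 10
        found = sorted(o.centroid for o in objs)
        for (fr, fc), (tr, tc) in zip(found, sorted(centres)):
            assert abs(fr - tr) <= 1 and abs(fc - tc) <= 1

    def test_single_pixel_speck_below_size_gate(self):
        img = np.zeros((32, 32))
        img[16, 16] = 0.5
        assert identify_objects(ChannelImage("cy3", img)) == []

    def test_large_blob_above_size_gate(self):
        img = np.zeros((64, 64))
        rr, cc = np.mgrid[:64, :64]
        img[(rr - 32) ** 2 + (cc - 32) ** 2 <= 6 ** 2] = 0.5  # eq diam ~12
        assert identify_objects(ChannelImage("cy3", img)) == []

    def test_threshold_monotonicity(self, rng):
        # sparse spots (no merging): raising the threshold never adds objects
        img = ndi.gaussian_filter(
            (rng.uniform(size=(128, 128)) > 0.999).astype(float), 1.0) * 3
        counts = [len(identify_objects(ChannelImage("cy3", img),
                                       DetectionConfig(intensity_threshold=t)))
                  for t in (0.05, 0.1, 0.2, 0.3, 0.5)]
        assert counts == sorted(counts, reverse=True)

    def test_deterministic_ordering(self, rng):
        img = ndi.gaussian_filter(
            (rng.uniform(size=(128, 128)) > 0.995).astype(float), 1.0) * 3
        a = identify_objects(ChannelImage("cy3", img))
        b = identify_objects(ChannelImage("cy3", img))
        assert [o.centroid for o in a] == [o.centroid for o in b]
        assert [o.object_id for o in a] == list(range(len(a)))
        assert a == sorted(a, key=lambda o: o.centroid)

    def test_adaptive_threshold_clipped_to_paper_window(self, rng):
        quiet = ChannelImage("cy3", np.abs(rng.normal(0, 1e-4, (64, 64))))
        loud = ChannelImage("cy3", np.abs(rng.normal(0, 0.2, (64, 64))))
        from rcpscope.detect import _resolve_threshold
        cfg = DetectionConfig(adaptive=True)
        assert _resolve_threshold(quiet.data, cfg) == 0.1
        assert _resolve_threshold(loud.data, cfg) == 0.4

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DetectionConfig(intensity_threshold=0.0)
        with pytest.raises(ValueError):
            DetectionConfig(min_diameter_px=8, max_diameter_px=2)


class TestMeasurement:
    def test_constant_image_stats(self):
        img = np.zeros((64, 64))
        rr, cc = np.mgrid[:64, :64]
        img[(rr - 20) ** 2 + (cc - 20) ** 2 <= 2 ** 2] = 0.5
        objs = identify_objects(ChannelImage("cy3", img))
        const = np.full((64, 64), 0.25)
        measure_across_channels(objs, _regset_from({"cy5": const}))
        st = objs[0].channel_stats["cy5"]
        assert st["mean"] == st["max"] == st["min"] == 0.25
        assert st["integrated"] == pytest.approx(0.25 * objs[0].area_px)

    def test_integrated_intensity_matches_rendered_truth(self):
        """Background-subtracted integral over detected pixels matches the
        expected filtered spot field: per-object within the photon/read noise
        (~5% s.d. here, bound at 25%), ensemble mean within 10%."""
        cfg = SceneConfig(image_height_px=256, image_width_px=256,
                          spot_density=12, channels=("cy3",), seed=17)
        stacks, truth = render_scene(cfg)
        img = preprocess.gaussian_denoise(
            preprocess.average_frames(stacks["cy3"]), 1.0)
        objs = identify_objects(img, DetectionConfig(intensity_threshold=0.1))
        regset = _regset_from({"cy3": img.data})
        measure_across_channels(objs, regset)
        _, _, matched = match_to_truth(objs, truth, tol_px=2.0)
        assert matched
        sigma = cfg.sigma_px
        sig_c = np.sqrt(sigma ** 2 + 1.0 ** 2)    # after the 1-px filter
        by_id = {o.object_id: o for o in objs}
        truth_by_id = truth.set_index("object_id")
        checked = 0
        rel_errors = []
        for oid, tid in matched:
            obj = by_id[oid]
            t = truth_by_id.loc[tid]
            amp_c = t["amp_cy3"] * sigma ** 2 / sig_c ** 2 / 65535.0

            def spot(rr, cc):
                return amp_c * np.exp(
                    -((rr - t["row"]) ** 2 + (cc - t["col"]) ** 2)
                    / (2 * sig_c ** 2))

            rr, cc = obj.pixels[:, 0], obj.pixels[:, 1]
            # the background annulus sits on the spot's own tails and its dim
            # pixels carry the sensor-floor clip lift that bright spot pixels
            # do not, so the background-subtracted oracle removes both
            ar, ac = annulus_pixels(obj.pixels, img.shape)
            from rcpscope.synthscope import (BACKGROUND_DN,
                                             expected_background_mean)
            clip_lift = (expected_background_mean(cfg) - BACKGROUND_DN) / 65535.0
            expected = (spot(rr, cc).sum()
                        - obj.area_px * (spot(ar, ac).mean() + clip_lift))
            measured = (obj.channel_stats["cy3"]["integrated"]
                        - obj.channel_stats["cy3"]["background"] * obj.area_px)
            assert measured == pytest.approx(expected, rel=0.25)
            rel_errors.append(measured / expected - 1.0)
            checked += 1
        assert checked >= 8
        assert abs(np.mean(rel_errors)) < 0.10

    def test_empty_object_list(self):
        regset = _regset_from({"cy3": np.zeros((8, 8))})
        assert measure_across_channels([], regset) == []

    def test_pixels_outside_raster_raise(self):
        img = np.zeros((32, 32))
        rr, cc = np.mgrid[:32, :32]
        img[(rr - 16) ** 2 + (cc - 16) ** 2 <= 2 ** 2] = 0.5
        objs = identify_objects(ChannelImage("cy3", img))
        small = _regset_from({"cy3": np.zeros((10, 10))})
        with pytest.raises(ValueError, match="outside"):
            measure_across_channels(objs, small)

    def test_border_object_uses_background_fallback(self):
        img = np.zeros((32, 32))
        img[0:3, 0:3] = 0.5
        objs = identify_objects(ChannelImage("cy3", img))
        assert len(objs) == 1
        rr, cc = annulus_pixels(objs[0].pixels, (32, 32))
        assert rr.size > 0  # corner object still has a partial ring here
        measure_across_channels(objs, _regset_from({"cy3": img}))
        assert "background" in objs[0].channel_stats["cy3"]

    def test_objects_to_frame_layout(self):
        img = np.zeros((32, 32))
        rr, cc = np.mgrid[:32, :32]
        img[(rr - 16) ** 2 + (cc - 16) ** 2 <= 2 ** 2] = 0.5
        objs = identify_objects(ChannelImage("cy3", img))
        measure_across_channels(objs, _regset_from({"cy3": img}))
        df = objects_to_frame(objs)
        for col in ("object_id", "row", "col", "area_px", "eq_diam_px",
                    "channel", "mean_cy3", "max_cy3", "min_cy3", "int_cy3"):
            assert col in df.columns


class TestMatchToTruth:
    def _objs_from_truth(self, truth):
        from rcpscope.detect import DetectedObject
        return [DetectedObject(i, np.array([[int(r), int(c)]]), (r, c), 1,
                               1.13, "cy3")
                for i, (r, c) in enumerate(zip(truth["row"], truth["col"]))]

    def _truth(self, n=10):
        import pandas as pd
        rng = np.random.default_rng(5)
        return pd.DataFrame({
            "object_id": range(n),
            "row": rng.uniform(10, 90, n),
            "col": rng.uniform(10, 90, n),
            "class": "rcp", "base": "G",
        })

    def test_perfect_detection(self):
        truth = self._truth()
        p, r, m = match_to_truth(self._objs_from_truth(truth), truth, 2.0)
        assert p == r == 1.0 and len(m) == 10

    def test_one_missed_object(self):
        truth = self._truth()
        objs = self._objs_from_truth(truth)[:-1]
        p, r, _ = match_to_truth(objs, truth, 2.0)
        assert p == 1.0
        assert r == pytest.approx(9 / 10)

    def test_permutation_invariance(self):
        truth = self._truth()
        objs = self._objs_from_truth(truth)
        p1, r1, m1 = match_to_truth(objs, truth, 2.0)
        p2, r2, m2 = match_to_truth(objs[::-1], truth, 2.0)
        assert (p1, r1, sorted(m1)) == (p2, r2, sorted(m2))

    def test_empty_cases(self):
        truth = self._truth()
        assert match_to_truth([], truth, 2.0)[:2] == (1.0, 0.0)


def test_detection_precision_recall_on_synthetic_scene():
    """At peak SNR >= 5 and moderate density, precision and recall >= 0.95."""
    cfg = SceneConfig(image_height_px=512, image_width_px=512,
                      spot_density=125, channels=("cy3",), peak_snr=5.0,
                      seed=23)
    stacks, truth = render_scene(cfg)
    img = preprocess.gaussian_denoise(
        preprocess.average_frames(stacks["cy3"]), 1.0)
    enhanced = enhance_spots(img, 5)
    objs = identify_objects(enhanced, DetectionConfig())
    precision, recall, _ = match_to_truth(objs, truth, tol_px=2.0)
    assert precision >= 0.95
    assert recall >= 0.95
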