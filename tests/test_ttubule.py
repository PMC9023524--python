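"""T-tubule analysis: axis estimation, segmentation, skeleton classification,
and fraction recovery against generator ground truth."""

import numpy as np
import pytest
from skimage.transform import rotate

from dyadkit.io import FluorescenceImage
from dyadkit.simulate import TTSimConfig, make_ttubule_image
from dyadkit.simulate.ttubule import _rasterize
from dyadkit.ttubule import (TTubuleSkeleton, SkeletonSegment, analyze_ttubule_image,
                             compute_tt_fractions, estimate_cell_axis,
                             segment_ttubules, skeletonize_and_classify)


def _orientation_distance(a: float, b: float) -> float:
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def _rotated(image: FluorescenceImage, deg: float) -> FluorescenceImage:
    arr = rotate(image.pixels.astype(float), deg, resize=True,
                 preserve_range=True, cval=float(np.median(image.pixels)))
    return FluorescenceImage(np.clip(arr, 0, None), image.pixel_size_um)


class TestCellAxis:
    def test_vertical_striations_give_horizontal_axis(self, striated_image):
        img, _ = striated_image
        assert _orientation_distance(estimate_cell_axis(img), 0.0) < 2.0

    def test_rotation_moves_axis_by_rotation_angle(self, striated_image):
        img, _ = striated_image
        a0 = estimate_cell_axis(img)
        a30 = estimate_cell_axis(_rotated(img, 30.0))
        assert _orientation_distance(a0, a30) == pytest.approx(30.0, abs=2.0)

    def test_pure_noise_raises(self, rng):
        noise = FluorescenceImage(rng.poisson(50, (200, 200)).astype(np.uint16), 0.1)
        with pytest.raises(ValueError, match="no structure"):
            estimate_cell_axis(noise)

    def test_constant_image_raises(self):
        flat = FluorescenceImage(np.full((64, 64), 7, dtype=np.uint16), 0.1)
        with pytest.raises(ValueError, match="no structure"):
            estimate_cell_axis(flat)


class TestSegmentation:
    def test_mask_covers_rendered_tubules(self):
        # near noise-free render; oracle = the ground-truth raster
        cfg = TTSimConfig(photons_peak=5000.0, background_photons=2.0,
                          transverse_dropout=0.2, longitudinal_density=0.1)
        img, truth = make_ttubule_image(cfg, 2)
        ideal = _rasterize(truth.segments, cfg).astype(bool)
        mask, qc = segment_ttubules(img)
        assert qc == []
        assert mask[ideal].mean() >= 0.95

    def test_all_zero_image_gives_empty_mask(self):
        img = FluorescenceImage(np.zeros((64, 64), dtype=np.uint16), 0.1)
        mask, qc = segment_ttubules(img, period_um=2.0)
        assert not mask.any()
        assert "empty_mask" in qc

    def test_inverted_contrast_flagged(self, striated_image):
        img, _ = striated_image
        inv = FluorescenceImage(
            (img.pixels.max() - img.pixels).astype(np.uint16), img.pixel_size_um)
        _mask, qc = segment_ttubules(inv, period_um=2.0)
        assert qc  # documented failure mode: empty or near-full mask is flagged


class TestSkeletonClassification:
    def test_vertical_segment_is_transverse(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:25, 15] = True
        skel = skeletonize_and_classify(mask, 0.0, 0.1)
        assert len(skel.segments) == 1
        assert skel.segments[0].cls == "transverse"
        assert skel.segments[0].angle_deg == pytest.approx(90.0, abs=1.0)

    def test_horizontal_segment_is_longitudinal(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[15, 5:25] = True
        skel = skeletonize_and_classify(mask, 0.0, 0.1)
        assert len(skel.segments) == 1
        assert skel.segments[0].cls == "longitudinal"
        assert skel.segments[0].angle_deg == pytest.approx(0.0, abs=1.0)

    def test_exact_45_degree_tie_is_transverse(self):
        mask = np.zeros((40, 40), dtype=bool)
        for i in range(5, 35):
            mask[i, i] = True
        skel = skeletonize_and_classify(mask, 0.0, 0.1)
        assert all(s.cls == "transverse" for s in skel.segments)

    def test_classified_lengths_match_ground_truth(self, mixed_image):
        cfg, _img, truth = mixed_image
        ideal = _rasterize(truth.segments, cfg).astype(bool)
        skel = skeletonize_and_classify(ideal, 0.0, cfg.pixel_size_um)
        t = sum(s.length_um for s in skel.segments if s.cls == "transverse")
        l = sum(s.length_um for s in skel.segments if s.cls == "longitudinal")
        assert t == pytest.approx(truth.transverse_length_um, rel=0.10)
        assert l == pytest.approx(truth.longitudinal_length_um, rel=0.10)


class TestFractions:
    def test_fraction_arithmetic(self):
        seg = lambda L, cls: SkeletonSegment(np.zeros((3, 2)), L, 90.0, cls)
        skel = TTubuleSkeleton([seg(30.0, "transverse"), seg(10.0, "longitudinal")])
        m = compute_tt_fractions(skel)
        assert m.transverse_fraction == pytest.approx(0.75)
        assert m.longitudinal_fraction == pytest.approx(0.25)

    def test_transverse_only(self):
        seg = SkeletonSegment(np.zeros((3, 2)), 12.0, 90.0, "transverse")
        m = compute_tt_fractions(TTubuleSkeleton([seg]))
        assert (m.transverse_fraction, m.longitudinal_fraction) == (1.0, 0.0)

    def test_empty_skeleton_flags_qc(self):
        m = compute_tt_fractions(TTubuleSkeleton([]))
        assert m.transverse_fraction == 0.0
        assert m.longitudinal_fraction == 0.0
        assert "empty_skeleton" in m.qc_flags

    def test_fractions_sum_to_one(self, mixed_image):
        _cfg, img, _truth = mixed_image
        m = analyze_ttubule_image(img)
        assert m.transverse_fraction + m.longitudinal_fraction == pytest.approx(1.0)
        assert 0.0 <= m.transverse_fraction <= 1.0

    def test_rotation_invariance(self, mixed_image):
        _cfg, img, _truth = mixed_image
        m0 = analyze_ttubule_image(img)
        m90 = analyze_ttubule_image(
            FluorescenceImage(np.ascontiguousarray(np.rot90(img.pixels)),
                              img.pixel_size_um))
        assert abs(m90.transverse_fraction - m0.transverse_fraction) <= 0.03


class TestRecovery:
    def test_longitudinal_fraction_monotone_in_density(self):
        # more generated longitudinal tubule must not read as less
        small = dict(image_size_um=(20.0, 10.0), transverse_dropout=0.2)
        means = []
        for ld in (0.05, 0.15, 0.30):
            vals = [analyze_ttubule_image(
                make_ttubule_image(TTSimConfig(longitudinal_density=ld, **small), s)[0]
            ).longitudinal_fraction for s in range(10)]
            means.append(np.mean(vals))
        assert means[0] <= means[1] <= means[2]

    def test_ko_like_config_shifts_fractions_down(self):
        # disrupted tubules: more dropout + more longitudinal remodelling
        ref = TTSimConfig(image_size_um=(20.0, 10.0), transverse_dropout=0.2,
                          longitudinal_density=0.1)
        ko = TTSimConfig(image_size_um=(20.0, 10.0), transverse_dropout=0.5,
                         longitudinal_density=0.3)
        wins = 0
        for seed in range(10):
            # axis known by construction; the contrast targets the fractions
            mr = analyze_ttubule_image(make_ttubule_image(ref, seed)[0],
                                       axis_deg=0.0)
            mk = analyze_ttubule_image(make_ttubule_image(ko, seed + 500)[0],
                                       axis_deg=0.0)
            wins += (mk.transverse_fraction < mr.transverse_fraction and
                     mk.longitudinal_fraction > mr.longitudinal_fraction)
        assert wins == 10
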