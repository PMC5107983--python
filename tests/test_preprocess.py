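"""Preprocessing chain: channel selection, QC filters, mask normalization."""

import numpy as np
import pytest

from nucleomorph.features import trace_boundary
from nucleomorph.preprocess import (
    GrayImage,
    NucleusObject,
    NucleusPreprocessor,
    binarize_otsu,
    exclude_mitotic,
    filter_border_objects,
    filter_by_area,
    filter_full_bbox,
    normalize_mask,
    normalize_orientation,
    normalize_scale,
    qc_intensity_std,
    resize_image,
    select_blue_channel,
    smooth_and_open,
)
from nucleomorph.synthetic import make_template


def make_object(mask, offset=(0, 0)):
    mask = np.asarray(mask, dtype=bool)
    r0, c0 = offset
    rr, cc = np.nonzero(mask)
    return NucleusObject(
        object_id=1,
        mask=mask,
        bbox=(r0, c0, r0 + mask.shape[0], c0 + mask.shape[1]),
        area=int(mask.sum()),
        centroid=(float(rr.mean() + r0), float(cc.mean() + c0)),
    )


def disk(radius, pad=2):
    n = 2 * radius + 1 + 2 * pad
    y, x = np.mgrid[:n, :n]
    c = (n - 1) / 2.0
    return (y - c) ** 2 + (x - c) ** 2 <= radius**2


class TestSelectBlueChannel:
    def test_constant_blue_plane_normalized_to_one(self):
        img = np.zeros((10, 10, 3))
        img[..., 2] = 0.7
        gray = select_blue_channel(img)
        np.testing.assert_array_equal(gray.pixels, np.ones((10, 10)))

    def test_single_plane_passthrough_rescaled(self):
        img = np.array([[0.0, 0.2], [0.4, 0.8]])
        gray = select_blue_channel(img)
        np.testing.assert_allclose(gray.pixels, img / 0.8)

    def test_blank_frame_rejected(self):
        with pytest.raises(ValueError, match="dynamic range"):
            select_blue_channel(np.full((5, 5), 0.3))

    def test_full_frame_dimensions_preserved(self):
        img = np.zeros((2056, 2452, 3))
        img[..., 2] = np.linspace(0, 1, 2452)[None, :]
        assert select_blue_channel(img).shape == (2056, 2452)


class TestResizeImage:
    def test_basic_and_identity(self):
        g = GrayImage(np.random.default_rng(0).random((1000, 1000)))
        assert resize_image(g, 0.3).shape == (300, 300)
        assert resize_image(g, 1.0).shape == (1000, 1000)

    def test_full_frame_rounds_half_away_from_zero(self):
        g = GrayImage(np.zeros((2056, 2452)))
        assert resize_image(g, 0.3).shape == (617, 736)

    @pytest.mark.parametrize("factor", [0.0, -0.1, 1.5])
    def test_invalid_factor_rejected(self, factor):
        with pytest.raises(ValueError):
            resize_image(GrayImage(np.zeros((10, 10))), factor)


class TestBinarizeOtsu:
    def test_two_disks_become_two_objects(self):
        img = np.full((120, 120), 0.1)
        d = disk(15, 2)
        img[5 : 5 + d.shape[0], 5 : 5 + d.shape[1]][d] = 0.9
        img[5 : 5 + d.shape[0], 70 : 70 + d.shape[1]][d] = 0.9
        objs = binarize_otsu(GrayImage(img))
        assert len(objs) == 2
        assert all(o.area == int(d.sum()) for o in objs)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            binarize_otsu(GrayImage(np.full((10, 10), 0.5)))


class TestIntensityStdQC:
    def test_constant_object_retained(self):
        d = disk(10)
        obj = make_object(d)
        img = GrayImage(np.where(d, 0.8, 0.1))
        qc_intensity_std(obj, img)
        assert obj.intensity_std == pytest.approx(0.0, abs=1e-12)
        assert obj.retained

    def test_half_and_half_hits_the_bound_and_is_kept(self):
        # population std of a 0/1 half-split is exactly 0.5, the Popoviciu
        # maximum for [0,1] data; elimination requires strictly greater
        mask = np.ones((10, 10), dtype=bool)
        vals = np.zeros((10, 10))
        vals[:, 5:] = 1.0
        obj = make_object(mask)
        qc_intensity_std(obj, GrayImage(vals))
        assert obj.intensity_std == pytest.approx(0.5)
        assert obj.retained

    def test_lowered_limit_flags_speckled_object(self):
        mask = np.ones((10, 10), dtype=bool)
        vals = np.zeros((10, 10))
        vals[:, 6:] = 1.0  # std = sqrt(0.4*0.6) ~ 0.49
        obj = make_object(mask)
        qc_intensity_std(obj, GrayImage(vals), limit=0.3)
        assert "high_std" in obj.qc_flags


class TestGeometricFilters:
    def test_border_contact_flags(self):
        inside = make_object(disk(5), offset=(10, 10))
        touching = make_object(disk(5), offset=(0, 10))
        near = make_object(disk(5), offset=(1, 10))
        filter_border_objects([inside, touching, near], (100, 100))
        assert inside.retained and near.retained
        assert "border" in touching.qc_flags

    def test_area_bounds_are_strict(self):
        small = make_object(np.ones((7, 7), dtype=bool))  # 49 px
        ok = make_object(np.ones((10, 5), dtype=bool))  # 50 px
        exact = make_object(np.ones((10, 10), dtype=bool))  # 100 px = 1 %
        big = make_object(np.ones((101, 1), dtype=bool))  # 101 px
        filter_by_area([small, ok, exact, big], (100, 100))
        assert "too_small" in small.qc_flags
        assert ok.retained and exact.retained
        assert "too_big" in big.qc_flags

    def test_full_bbox_flag_is_strict(self):
        from nucleomorph.preprocess import NormalizedNucleus

        solid = NormalizedNucleus(1, np.ones((64, 20), dtype=bool))
        assert "full_bbox" in filter_full_bbox(solid).qc_flags
        holed = np.ones((64, 20), dtype=bool)
        holed[30, 10] = False
        assert filter_full_bbox(NormalizedNucleus(2, holed)).retained
        assert filter_full_bbox(NormalizedNucleus(3, disk(20))).retained


class TestMitoticExclusion:
    def test_single_disk_retained(self):
        obj = make_object(disk(15))
        assert exclude_mitotic(obj).retained

    def test_bridged_pair_flagged(self, dumbbell_mask):
        obj = make_object(dumbbell_mask)
        assert "mitotic" in exclude_mitotic(obj).qc_flags

    def test_small_bump_not_flagged(self):
        # a 5 %-area satellite bump should stay below the 30 % basin rule
        m = disk(20, pad=8).copy()
        y, x = np.mgrid[: m.shape[0], : m.shape[1]]
        m |= (y - 4) ** 2 + (x - 24) ** 2 <= 4**2
        obj = make_object(m)
        assert exclude_mitotic(obj).retained


class TestSmoothAndOpen:
    def test_large_disk_nearly_unchanged(self):
        obj = make_object(disk(25))
        area0 = obj.area
        out = smooth_and_open(obj)
        assert out is not None
        assert abs(out.area - area0) / area0 < 0.02

    def test_thin_artifact_removed_and_perimeter_decreases(self):
        m = disk(20, pad=4).copy()
        m[2:6, 24] = True  # 1-px-wide antenna
        staircased = m.copy()
        obj = make_object(staircased)
        pts0 = trace_boundary(staircased).points
        per0 = np.linalg.norm(np.roll(pts0, -1, axis=0) - pts0, axis=1).sum()
        out = smooth_and_open(obj)
        pts1 = trace_boundary(out.mask).points
        per1 = np.linalg.norm(np.roll(pts1, -1, axis=0) - pts1, axis=1).sum()
        assert per1 < per0  # antenna gone, edges smoothed

    def test_vanishing_object_dropped(self):
        obj = make_object(np.eye(4, dtype=bool))
        assert smooth_and_open(obj) is None


class TestNormalizeOrientation:
    @staticmethod
    def ellipse(angle_deg, a=60, b=25, n=161):
        y, x = np.mgrid[:n, :n]
        c = (n - 1) / 2.0
        th = np.deg2rad(angle_deg)
        u = (x - c) * np.cos(th) + (y - c) * np.sin(th)
        v = -(x - c) * np.sin(th) + (y - c) * np.cos(th)
        return (u / a) ** 2 + (v / b) ** 2 <= 1

    @pytest.mark.parametrize("angle", [0, 30, 45, 90, 120])
    def test_major_axis_becomes_vertical(self, angle):
        nm = normalize_orientation(self.ellipse(angle))
        h, w = nm.mask.shape
        assert h > w

    def test_idempotent(self):
        nm = normalize_orientation(self.ellipse(30))
        again = normalize_orientation(nm.mask)
        np.testing.assert_array_equal(nm.mask, again.mask)

    def test_mirror_and_right_angle_rotations_identical(self):
        L = np.zeros((100, 100), dtype=bool)
        L[10:90, 10:35] = True
        L[65:90, 10:80] = True
        ref = normalize_orientation(L).mask
        for variant in [L[:, ::-1], L[::-1, :], np.rot90(L, 1), np.rot90(L, 2), np.rot90(L, 3)]:
            np.testing.assert_array_equal(ref, normalize_orientation(variant).mask)

    def test_circle_is_degenerate_no_rotation(self):
        nm = normalize_orientation(disk(30))
        assert nm.orientation_applied == 0.0

    def test_too_few_pixels_rejected(self):
        with pytest.raises(ValueError):
            normalize_orientation(np.array([[True, True]]))


class TestNormalizeScale:
    def test_aspect_preserving_dimensions(self):
        from nucleomorph.preprocess import NormalizedNucleus

        out = normalize_scale(NormalizedNucleus(1, np.ones((128, 64), dtype=bool)))
        assert out.mask.shape[0] == 64
        assert out.mask.shape[1] == pytest.approx(32, abs=1)
        up = normalize_scale(NormalizedNucleus(2, np.ones((10, 5), dtype=bool)))
        assert up.mask.shape[0] == 64  # upscaling allowed

    @pytest.mark.parametrize(
        "name", ["circle", "ellipse", "kidney", "C", "L", "T", "U", "S", "cross", "grid", "dumbbell"]
    )
    def test_every_template_normalizes_to_64(self, name):
        mask = normalize_mask(make_template(name, 128))
        assert max(mask.shape) == 64


class TestPreprocessorTransform:
    def test_small_scene_exact_recovery(self):
        from nucleomorph.synthetic import render_scene

        placements = [
            {"template": "circle", "center": (100, 100), "size": 56},
            {"template": "L", "center": (100, 280), "size": 56},
            {"template": "circle", "center": (30, 450), "qc_violation": "border"},
            {"center": (280, 100), "qc_violation": "too_small"},
        ]
        scene = render_scene(placements, image_shape=(512, 512), seed=9)
        pre = NucleusPreprocessor(resize_factor=1.0)
        nuclei = pre.transform(scene.image)
        assert len(nuclei) == 2
        assert all(max(n.mask.shape) == 64 for n in nuclei)
        assert all(not n.qc_flags for n in nuclei)
        qc = pre.qc_table_
        assert set(qc.columns) >= {"object_id", "area_px", "qc_flags", "retained"}
        assert qc["retained"].sum() == 2

    def test_speck_only_image_yields_empty_result(self):
        img = np.full((200, 200), 0.1)
        img[100:102, 100:102] = 0.9  # 4 px: below the area floor
        pre = NucleusPreprocessor(resize_factor=1.0)
        assert pre.transform(img) == []
        assert pre.qc_table_["retained"].sum() == 0

    def test_min_area_override_honored(self):
        img = np.full((200, 200), 0.1)
        img[96:104, 96:104] = 0.9  # 64 px object
        default = NucleusPreprocessor(resize_factor=1.0)
        default.transform(img)
        assert "too_small" not in default.qc_table_.loc[0, "qc_flags"]
        strict = NucleusPreprocessor(resize_factor=1.0, min_area_px=100)
        strict.transform(img)
        assert "too_small" in strict.qc_table_.loc[0, "qc_flags"]
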