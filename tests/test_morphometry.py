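"""Skeleton, diameter and area-integration checks against closed forms."""

import numpy as np
import pytest

from rhizohair import (
    HAIR,
    ROOT,
    average_root_diameter,
    classify_by_diameter,
    extract_centerlines,
    local_diameter,
    skeleton_length,
    skeletonize_mask,
    summarize_morphometry,
    trim_hair_bases,
)
from rhizohair.morphometry import RootSkeleton

from conftest import render_hairy_root


def _bar(h, w, rows, cols):
    m = np.zeros((h, w), np.uint8)
    m[rows, cols] = 255
    return m


class TestSkeletonize:
    def test_horizontal_bar_reduces_to_centerline_row(self):
        m = np.zeros((9, 15), np.uint8)
        m[3:6, 2:13] = 255
        sk = skeletonize_mask(m, scale=1.0)
        assert sk.n_pixels == 11
        assert set(sk.coords[:, 0]) == {4}
        assert skeleton_length(sk) == pytest.approx(10.0)

    def test_empty_mask_gives_empty_skeleton(self):
        sk = skeletonize_mask(np.zeros((6, 6), np.uint8), scale=2.0)
        assert sk.n_pixels == 0
        assert skeleton_length(sk) == 0.0

    def test_straight_tube_skeleton_hugs_true_centerline(self):
        mask, line = render_hairy_root(angle_deg=60.0, hair_spacing_mm=1e9,
                                       length_mm=15.0)
        scale = 1200 / 25.4
        sk = skeletonize_mask(mask, scale)
        # every skeleton pixel within 1 px of the ideal segment
        p0, p1 = line * scale
        d = p1 - p0
        t = np.clip(((sk.coords - p0) @ d) / (d @ d), 0, 1)
        dist = np.hypot(*(sk.coords - (p0 + t[:, None] * d)).T)
        assert np.quantile(dist, 0.99) <= 1.0


class TestSkeletonLength:
    def test_diagonal_chain_uses_sqrt2_steps(self):
        m = np.zeros((20, 20), np.uint8)
        for i in range(11):
            m[3 + i, 3 + i] = 255
        sk = skeletonize_mask(m, scale=1.0)
        assert skeleton_length(sk) == pytest.approx(10 * np.sqrt(2), abs=1e-9)

    def test_quarter_arc_length_within_three_percent(self):
        r = 100
        th = np.linspace(0, np.pi / 2, 4000)
        rows = np.round(r + 5 - r * np.cos(th)).astype(int)
        cols = np.round(r * np.sin(th)).astype(int) + 5
        m = np.zeros((r + 15, r + 15), np.uint8)
        m[rows, cols] = 255
        L = skeleton_length(skeletonize_mask(m, scale=1.0))
        assert L == pytest.approx(np.pi * r / 2, rel=0.03)

    def test_scale_divides_lengths(self):
        m = _bar(5, 14, 2, slice(1, 13))
        assert skeleton_length(skeletonize_mask(m, scale=4.0)) == pytest.approx(11 / 4)


class TestLocalDiameter:
    def test_disc_center_diameter_is_two_radii(self):
        yy, xx = np.mgrid[:61, :61]
        disc = ((yy - 30) ** 2 + (xx - 30) ** 2 <= 20**2).astype(np.uint8) * 255
        sk = skeletonize_mask(disc, scale=2.0)
        sk = local_diameter(sk, disc)
        assert sk.diameter_mm.max() == pytest.approx(2 * 20 / 2.0, rel=0.06)

    def test_one_pixel_line_diameter_forced_by_definition(self):
        m = _bar(7, 20, 3, slice(2, 18))
        sk = local_diameter(skeletonize_mask(m, scale=5.0), m)
        assert np.all(sk.diameter_mm == pytest.approx(2 / 5.0))

    def test_synthetic_tube_diameter_within_ten_percent(self):
        mask, _ = render_hairy_root(hair_spacing_mm=1e9, diameter_mm=0.5)
        scale = 1200 / 25.4
        sk = local_diameter(skeletonize_mask(mask, scale), mask)
        assert np.median(sk.diameter_mm) == pytest.approx(0.5, rel=0.10)


class TestClassification:
    def _skel_with_diameters(self, diam):
        n = len(diam)
        coords = np.stack([np.full(n, 3), np.arange(n) + 1], axis=1)
        edges = np.stack([np.arange(n - 1), np.arange(1, n)], axis=1)
        lens = np.ones(n - 1)
        step = np.zeros(n)
        for (a, b), l in zip(edges, lens):
            step[a] += l / 2
            step[b] += l / 2
        return RootSkeleton(coords=coords, scale=1.0, shape=(7, n + 2),
                           edges=edges, edge_len_px=lens, step_mm=step,
                           diameter_mm=np.asarray(diam, float))

    @pytest.mark.parametrize("d, expected", [
        (0.15, HAIR),   # below the class boundary: root hair
        (0.20, ROOT),   # boundary value belongs to the root class
        (0.25, ROOT),
    ])
    def test_boundary_assignment(self, d, expected):
        sk = self._skel_with_diameters([d] * 6)
        sk = classify_by_diameter(sk, threshold_mm=0.2)
        assert np.all(sk.labels == expected)

    def test_short_embedded_dip_relabelled_root(self):
        sk = self._skel_with_diameters([0.5, 0.5, 0.18, 0.5, 0.5, 0.5])
        sk = classify_by_diameter(sk, threshold_mm=0.2, bridge_px=3)
        assert np.all(sk.labels == ROOT)

    def test_long_thin_run_stays_hair(self):
        sk = self._skel_with_diameters([0.5, 0.1, 0.1, 0.1, 0.1, 0.1])
        sk = classify_by_diameter(sk, threshold_mm=0.2, bridge_px=3)
        assert np.count_nonzero(sk.labels == HAIR) == 5

    def test_raising_threshold_never_decreases_hair_area(self, demo_skeleton):
        areas = []
        for thr in (0.1, 0.2, 0.3):
            sk = classify_by_diameter(demo_skeleton, threshold_mm=thr)
            areas.append(summarize_morphometry(sk).hair_area_cm2)
        # restore the default classification for other tests
        classify_by_diameter(demo_skeleton, threshold_mm=0.2)
        assert areas[0] <= areas[1] <= areas[2]


class TestSummaries:
    def test_single_chain_closed_form_area(self):
        # root-class chain, d = 0.5 mm, total length 20 mm
        n = 21
        coords = np.stack([np.full(n, 2), np.arange(n)], axis=1)
        edges = np.stack([np.arange(n - 1), np.arange(1, n)], axis=1)
        lens = np.ones(n - 1)
        step = np.zeros(n)
        for (a, b), l in zip(edges, lens):
            step[a] += l / 2
            step[b] += l / 2
        sk = RootSkeleton(coords=coords, scale=1.0, shape=(5, n),
                          edges=edges, edge_len_px=lens, step_mm=step,
                          diameter_mm=np.full(n, 0.5),
                          labels=np.full(n, ROOT, np.int8), threshold_mm=0.2)
        s = summarize_morphometry(sk)
        assert s.naked_root_area_cm2 * 100 == pytest.approx(np.pi * 0.5 * 20)
        assert s.average_diameter_mm == pytest.approx(0.5)

    def test_partition_identity_is_exact(self, demo_skeleton):
        s = summarize_morphometry(demo_skeleton)
        assert s.total_area_cm2 == s.naked_root_area_cm2 + s.hair_area_cm2

    def test_zero_root_length_reports_missing_diameter(self):
        sk = RootSkeleton(coords=np.empty((0, 2), int), scale=1.0, shape=(4, 4),
                          edges=np.empty((0, 2), int), edge_len_px=np.empty(0),
                          step_mm=np.empty(0), diameter_mm=np.empty(0),
                          labels=np.empty(0, np.int8), threshold_mm=0.2)
        s = summarize_morphometry(sk)
        assert s.average_diameter_mm is None
        assert s.total_root_length_cm == 0.0


@pytest.mark.parametrize("area_mm2, length_mm, expected", [
    (np.pi, 1.0, 1.0),
    (15.708, 10.0, 0.5),
])
def test_average_root_diameter_formula(area_mm2, length_mm, expected):
    assert average_root_diameter(area_mm2, length_mm) == pytest.approx(expected, abs=1e-4)


def test_average_root_diameter_missing_for_zero_length():
    assert average_root_diameter(3.0, 0.0) is None


def test_scale_equivariance_of_physical_traits():
    """Same bald scene at 2x resolution: physical traits stay put."""
    from rhizohair import SceneSpec, generate_scene
    base = dict(image_height_mm=18.0, image_width_mm=12.0, seminal_count=1,
                laterals_per_seminal=0, hair_density_per_mm=0.0, rng_seed=4)
    results = []
    for scale in (20.0, 40.0):
        spec = SceneSpec(**base, scale=scale)
        _, gt = generate_scene(spec)
        mask = gt.truth_mask.astype(np.uint8) * 255
        sk = local_diameter(skeletonize_mask(mask, scale), mask)
        sk = classify_by_diameter(sk)
        results.append(summarize_morphometry(sk))
    a, b = results
    assert b.total_root_length_cm == pytest.approx(a.total_root_length_cm, rel=0.03)
    assert b.naked_root_area_cm2 == pytest.approx(a.naked_root_area_cm2, rel=0.15)


def test_hair_base_trimming_recovers_axis_length():
    """Hairs must not inflate measured root length."""
    scale = 1200 / 25.4
    mask, _ = render_hairy_root(hair_spacing_mm=0.25, length_mm=15.0)
    sk = local_diameter(skeletonize_mask(mask, scale), mask)
    sk = classify_by_diameter(sk)
    sk = trim_hair_bases(sk)
    assert skeleton_length(sk, ROOT) == pytest.approx(15.0, rel=0.05)


def test_extract_centerlines_orientation_and_length():
    mask, line = render_hairy_root(hair_spacing_mm=1e9, length_mm=18.0)
    scale = 1200 / 25.4
    sk = local_diameter(skeletonize_mask(mask, scale), mask)
    sk = classify_by_diameter(sk)
    lines = extract_centerlines(sk)
    assert len(lines) == 1
    poly = lines[0]
    length = np.sum(np.hypot(*np.diff(poly, axis=0).T))
    assert length == pytest.approx(18.0, rel=0.06)
    assert poly[-1, 0] > poly[0, 0]  # tip (deeper row) last
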