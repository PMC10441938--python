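"""Shared fixtures: one rendered demo scene reused across the suite."""

import numpy as np
import pytest

from rhizohair import (
    GrayscaleScan,
    classify_by_diameter,
    clean_mask,
    generate_scene,
    local_diameter,
    prune_root_spurs,
    segment_scan,
    skeletonize_mask,
    trim_hair_bases,
)
from rhizohair.pipeline import demo_scene_spec
from rhizohair.synthetic import _draw_capsules


@pytest.fixture(scope="session")
def demo_scene():
    """One default-parameter 1200-dpi scene with ground truth."""
    spec = demo_scene_spec(seed=1)
    image, gt = generate_scene(spec)
    return spec, image, gt


@pytest.fixture(scope="session")
def demo_mask(demo_scene):
    spec, image, _ = demo_scene
    scan = GrayscaleScan(pixels=image, scale=spec.scale)
    return clean_mask(segment_scan(scan))


@pytest.fixture(scope="session")
def demo_skeleton(demo_scene, demo_mask):
    spec, _, _ = demo_scene
    skel = skeletonize_mask(demo_mask.pixels, spec.scale)
    skel = local_diameter(skel, demo_mask.pixels)
    skel = classify_by_diameter(skel)
    skel = trim_hair_bases(skel)
    return prune_root_spurs(skel)


def render_hairy_root(
    angle_deg: float = 90.0,
    length_mm: float = 20.0,
    diameter_mm: float = 0.5,
    hair_length_mm: float = 1.5,
    hair_spacing_mm: float = 0.25,
    hair_diameter_mm: float = 0.04,
    scale: float = 1200.0 / 25.4,
    perpendicular: bool = True,
    margin_mm: float = 3.0,
):
    """Rasterize one straight root with evenly spaced equal-length hairs.

    Returns (mask uint8, centerline_mm base→tip).  ``angle_deg`` is the
    root direction in the image plane (90 = pointing down).
    """
    a = np.deg2rad(angle_deg)
    d = np.array([np.sin(a), np.cos(a)])  # (dy, dx); 90 deg -> (1, 0)
    n = np.array([-d[1], d[0]])
    p0 = np.array([margin_mm, margin_mm + (length_mm + 2) * max(0.0, -d[1])])
    p1 = p0 + d * length_mm
    segs = [(p0, p1, diameter_mm / 2)]
    s = hair_spacing_mm
    while s < length_mm - hair_spacing_mm:
        base = p0 + d * s
        for side in (-1, 1):
            start = base + n * side * diameter_mm / 2
            tip = start + n * side * hair_length_mm
            segs.append((start, tip, hair_diameter_mm / 2))
        s += hair_spacing_mm
    extent = length_mm + 2 * margin_mm
    h = int(np.ceil((abs(d[0]) * length_mm + 2 * margin_mm) * scale)) + 1
    w = int(np.ceil((abs(d[1]) * length_mm + 2 * margin_mm) * scale)) + 1
    w = max(w, int(2 * margin_mm * scale) + 1)
    canvas = np.zeros((max(h, 32), max(w, 32)), float)
    _draw_capsules(canvas, segs, scale)
    mask = (canvas >= 0.5).astype(np.uint8) * 255
    centerline = np.stack([p0, p1])
    return mask, centerline
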