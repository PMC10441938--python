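"""Synthetic rhizobox-scan generator with exact ground truth.

Renders wheat-like root systems — a few seminal axes with lateral
branches, carrying dense root hairs — as bright anti-aliased tubes on a
dark woven-fabric background, the way a flatbed scanner sees roots grown
flat against black polyester in a rhizobox.  Every scene comes with the
exact geometry used to render it (per-element centerlines, diameters and
lengths), so the whole measurement pipeline can be validated by
parameter recovery instead of against un-releasable raw scans.

Coordinate conventions
----------------------
Rasters are indexed ``(row, col)``, 0-based, with the physical frame in
millimetres anchored at the *centre* of the top-left pixel.  Polylines
are ``(N, 2)`` float arrays of ``(y_mm, x_mm)``; ``px = mm * scale``.
Roots grow downward (increasing row), so a root polyline runs base→tip.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from .morphometry import MorphometrySummary

FOREGROUND_GRAY = 255.0

__all__ = [
    "SceneSpec",
    "Element",
    "GroundTruth",
    "generate_scene",
    "render_fabric_background",
    "truth_summary",
]


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic rhizobox scan.

    Defaults emulate a 14-day wheat root-system scan at 1200 dpi
    (47.24 px/mm): 3 seminal roots of ~0.5 mm diameter with 0.3 mm
    laterals, root hairs of mean length 1.8 mm (observed sheath widths
    span roughly 1.4–2.3 mm along a seminal root) at ~4 hairs per mm of
    axis per side, hair diameter well below the 0.2 mm diameter-class
    threshold, on a woven-fabric background.  The frame is a 40 x 30 mm
    crop of a scan, not a whole rhizobox, to keep rasters tractable.
    """

    image_height_mm: float = 40.0
    image_width_mm: float = 30.0
    scale: float = 1200.0 / 25.4  # px per mm; 1200 dpi
    seminal_count: int = 3
    seminal_diameter_mm: float = 0.5
    lateral_diameter_mm: float = 0.3
    laterals_per_seminal: int = 4
    lateral_length_mm: float = 9.0
    hair_length_mm: float = 1.8
    hair_length_cv: float = 0.05
    hair_density_per_mm: float = 4.0  # hairs per mm of axis, per side
    hair_diameter_mm: float = 0.04
    hair_tilt_max_deg: float = 25.0
    hair_free_tip_mm: float = 2.0
    lateral_free_tip_mm: float = 14.0  # laterals emerge only in older zones
    background_mesh_period_px: int = 6
    noise_sd: float = 6.0
    blur_sigma_px: float = 0.7
    frame_margin_mm: float = 3.0  # fixed margin so geometry is independent of hair params
    rng_seed: int = 0

    def replace(self, **kwargs) -> "SceneSpec":
        return dataclasses.replace(self, **kwargs)

    @property
    def shape_px(self) -> tuple[int, int]:
        return (
            int(round(self.image_height_mm * self.scale)) + 1,
            int(round(self.image_width_mm * self.scale)) + 1,
        )

    def validate(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        for name in (
            "image_height_mm", "image_width_mm", "seminal_diameter_mm",
            "lateral_diameter_mm", "hair_length_mm", "hair_diameter_mm",
            "lateral_length_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (self.hair_diameter_mm < 0.2 < self.seminal_diameter_mm):
            raise ValueError(
                "diameter classes must be separable by construction: "
                "hair_diameter_mm < 0.2 mm < seminal_diameter_mm"
            )
        if self.seminal_count < 1:
            raise ValueError("seminal_count must be >= 1")
        if self.hair_density_per_mm < 0 or self.noise_sd < 0 or self.blur_sigma_px < 0:
            raise ValueError("densities, noise and blur must be >= 0")
        needed = self.hair_length_mm * (1 + 3 * self.hair_length_cv) + self.seminal_diameter_mm
        if self.frame_margin_mm < needed:
            raise ValueError(
                f"frame_margin_mm={self.frame_margin_mm} too small for the hair "
                f"sheath (needs >= {needed:.1f} mm to keep hair tips in frame)"
            )
        margin = self._margin_mm
        if self.image_height_mm < 2 * margin + 5 or self.image_width_mm < 2 * margin + 2:
            raise ValueError(
                f"frame too small: roots plus a {margin:.1f} mm hair margin do not fit"
            )

    @property
    def _margin_mm(self) -> float:
        # fixed margin keeps hair tips inside the frame while leaving the
        # root-geometry envelope identical across hair-trait conditions
        return self.frame_margin_mm


@dataclass
class Element:
    """One rendered structure: a root axis or a single root hair."""

    element_id: int
    cls: str  # 'seminal' | 'lateral' | 'hair'
    polyline_mm: np.ndarray  # (N, 2) of (y_mm, x_mm)
    diameter_mm: float
    length_mm: float
    parent_id: int | None = None
    base_s_mm: float | None = None  # hair base arc position along parent (from base)


@dataclass
class GroundTruth:
    """Exact geometry of a rendered scene plus its rasterization mask."""

    elements: list[Element]
    truth_mask: np.ndarray = field(repr=False)  # bool, coverage >= 0.5 pre-blur
    scale: float = 1.0

    # -- totals: always recomputed from element records (conservation) --
    @property
    def root_elements(self) -> list[Element]:
        return [e for e in self.elements if e.cls in ("seminal", "lateral")]

    @property
    def hair_elements(self) -> list[Element]:
        return [e for e in self.elements if e.cls == "hair"]

    @property
    def total_root_length_mm(self) -> float:
        return float(sum(e.length_mm for e in self.root_elements))

    @property
    def naked_area_mm2(self) -> float:
        return float(sum(np.pi * e.diameter_mm * e.length_mm for e in self.root_elements))

    @property
    def hair_area_mm2(self) -> float:
        return float(sum(np.pi * e.diameter_mm * e.length_mm for e in self.hair_elements))

    @property
    def hair_count(self) -> int:
        return len(self.hair_elements)

    def mean_root_diameter_mm(self) -> float:
        """Length-weighted mean diameter = naked area / (pi * length)."""
        L = self.total_root_length_mm
        return self.naked_area_mm2 / (np.pi * L) if L > 0 else float("nan")

    def roi_hair_stats(self, parent_id: int, s_lo_mm: float, s_hi_mm: float) -> dict:
        """Truth for one ROI window along a parent root.

        Returns mean hair length (mm) and hairs per mm of axis (both
        sides pooled) among hairs whose base lies in [s_lo, s_hi].
        """
        hairs = [
            h for h in self.hair_elements
            if h.parent_id == parent_id and h.base_s_mm is not None
            and s_lo_mm <= h.base_s_mm <= s_hi_mm
        ]
        span = s_hi_mm - s_lo_mm
        return {
            "hair_mean_length_mm": float(np.mean([h.length_mm for h in hairs])) if hairs else 0.0,
            "hairs_per_mm": len(hairs) / span if span > 0 else float("nan"),
            "n_hairs": len(hairs),
        }

    # -- plumbing: tabular export --
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.elements:
            rows.append({
                "element_id": e.element_id,
                "class": e.cls,
                "diameter_mm": e.diameter_mm,
                "length_mm": e.length_mm,
                "parent_id": e.parent_id,
                "base_s_mm": e.base_s_mm,
                "polyline": ";".join(f"{y:.4f},{x:.4f}" for y, x in e.polyline_mm),
            })
        return pd.DataFrame(rows)

    def totals_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "total_root_length_mm": self.total_root_length_mm,
            "naked_area_mm2": self.naked_area_mm2,
            "hair_area_mm2": self.hair_area_mm2,
            "hair_count": self.hair_count,
        }])

    def write_csv(self, elements_path, totals_path=None) -> None:
        self.to_frame().to_csv(elements_path, index=False)
        if totals_path is not None:
            self.totals_frame().to_csv(totals_path, index=False)


def _polyline_length(poly: np.ndarray) -> float:
    return float(np.sum(np.hypot(*np.diff(poly, axis=0).T)))


def _random_walk(rng, start_yx, heading_rad, step_mm, n_max, bounds, wobble_deg=4.0):
    """Smooth random-walk polyline steered to stay inside ``bounds``.

    ``bounds`` is (y_lo, y_hi, x_lo, x_hi) in mm; ``heading`` is measured
    from the +y axis (downward), positive toward +x.  Stops when the next
    step would cross y_hi (roots stop at the lower margin).
    """
    y_lo, y_hi, x_lo, x_hi = bounds
    pts = [np.asarray(start_yx, float)]
    h0 = float(heading_rad)
    h = h0
    for _ in range(n_max):
        # wobble with mean reversion: roots keep their gravitropic
        # set-point direction instead of drifting into neighbours
        h += np.deg2rad(rng.normal(0.0, wobble_deg)) + 0.2 * (h0 - h)
        h = float(np.clip(h, -np.pi / 3, np.pi / 3))
        y, x = pts[-1]
        # steer back toward the interior near lateral margins
        if x < x_lo + 2 and h < 0:
            h = abs(h) * 0.5
        elif x > x_hi - 2 and h > 0:
            h = -abs(h) * 0.5
        ny = y + step_mm * np.cos(h)
        nx = x + step_mm * np.sin(h)
        if ny > y_hi:
            break
        nx = float(np.clip(nx, x_lo, x_hi))
        pts.append(np.array([ny, nx]))
    return np.asarray(pts)


def _resample_polyline(poly: np.ndarray, ds: float) -> tuple[np.ndarray, np.ndarray]:
    """Arc-length resampling; returns (points, arc positions)."""
    seg = np.hypot(*np.diff(poly, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    si = np.arange(0.0, total, ds)
    si = np.append(si, total)
    y = np.interp(si, s, poly[:, 0])
    x = np.interp(si, s, poly[:, 1])
    return np.stack([y, x], axis=1), si


def _point_and_normal(poly: np.ndarray, s_query: float) -> tuple[np.ndarray, np.ndarray]:
    seg = np.hypot(*np.diff(poly, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    s_query = float(np.clip(s_query, 0, s[-1]))
    i = int(np.searchsorted(s, s_query, side="right") - 1)
    i = min(i, len(seg) - 1)
    t = (s_query - s[i]) / seg[i] if seg[i] > 0 else 0.0
    p = poly[i] * (1 - t) + poly[i + 1] * t
    d = poly[i + 1] - poly[i]
    d = d / np.hypot(*d)
    normal = np.array([-d[1], d[0]])  # rotate tangent by +90 deg
    return p, normal


def _draw_capsules(canvas: np.ndarray, segments, scale: float) -> None:
    """Accumulate anti-aliased capsule coverage (max-composited).

    ``segments`` yields (p0_mm, p1_mm, radius_mm).  Coverage per pixel is
    approximated as clip(r_px + 0.5 - distance_to_segment, 0, 1), which
    is exact in the limit of an edge crossing a pixel face and accurate
    enough for sub-pixel filaments.
    """
    H, W = canvas.shape
    for p0, p1, r_mm in segments:
        a = np.asarray(p0) * scale
        b = np.asarray(p1) * scale
        r = r_mm * scale
        pad = r + 1.5
        r0 = max(int(np.floor(min(a[0], b[0]) - pad)), 0)
        r1 = min(int(np.ceil(max(a[0], b[0]) + pad)) + 1, H)
        c0 = max(int(np.floor(min(a[1], b[1]) - pad)), 0)
        c1 = min(int(np.ceil(max(a[1], b[1]) + pad)) + 1, W)
        if r0 >= r1 or c0 >= c1:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        py = yy - a[0]
        px = xx - a[1]
        vy, vx = b - a
        vv = vy * vy + vx * vx
        if vv > 0:
            t = np.clip((py * vy + px * vx) / vv, 0.0, 1.0)
        else:
            t = 0.0
        dy = py - t * vy
        dx = px - t * vx
        dist = np.hypot(dy, dx)
        cov = np.clip(r + 0.5 - dist, 0.0, 1.0)
        np.maximum(canvas[r0:r1, c0:c1], cov, out=canvas[r0:r1, c0:c1])


def render_fabric_background(
    height_px: int, width_px: int, mesh_period_px: int, rng_seed: int = 0
) -> np.ndarray:
    """Periodic woven-fabric texture in a low gray band (uint8).

    A separable squared-sine weave of the given period over a dark base,
    with mild stochastic thread variation.  ``mesh_period_px = 0`` gives
    a uniform background.  Values stay far below the foreground white so
    roots remain separable by construction.
    """
    if height_px <= 0 or width_px <= 0:
        raise ValueError("background dimensions must be > 0")
    rng = np.random.default_rng(rng_seed)
    base = 25.0
    if mesh_period_px <= 0:
        img = np.full((height_px, width_px), base + 10.0)
    else:
        r = np.arange(height_px)[:, None]
        c = np.arange(width_px)[None, :]
        weave = (
            np.sin(np.pi * r / mesh_period_px) ** 2
            * np.sin(np.pi * c / mesh_period_px) ** 2
        )
        img = base + 30.0 * weave
        img = img + rng.normal(0.0, 2.0, size=img.shape)
    return np.clip(img, 0, 90).astype(np.uint8)


def _build_geometry(spec: SceneSpec, rng) -> list[Element]:
    m = spec._margin_mm
    H, W = spec.image_height_mm, spec.image_width_mm
    bounds = (m, H - m, m, W - m)
    elements: list[Element] = []
    eid = 0

    # seminal roots fan out downward from a crown near the top margin
    crown_x = np.linspace(0.30 * W, 0.70 * W, spec.seminal_count)
    headings = np.linspace(-0.35, 0.35, spec.seminal_count)
    step = 1.0
    seminals = []
    for i in range(spec.seminal_count):
        start = (m, crown_x[i] + rng.normal(0, 0.5))
        poly = _random_walk(rng, start, headings[i] + rng.normal(0, 0.05),
                            step, int(2 * H), bounds)
        if len(poly) < 6:
            raise ValueError("seminal root does not fit in the image frame")
        d = spec.seminal_diameter_mm * (1 + rng.uniform(-0.06, 0.06))
        elements.append(Element(eid, "seminal", poly, d, _polyline_length(poly)))
        seminals.append(elements[-1])
        eid += 1

    # laterals branch off each seminal at mid positions
    for parent in seminals:
        L = parent.length_mm
        n_lat = spec.laterals_per_seminal
        if L < 5.0 + spec.lateral_free_tip_mm + 2.0 or n_lat == 0:
            continue
        s_positions = rng.uniform(5.0, L - spec.lateral_free_tip_mm, size=n_lat)
        for s0 in s_positions:
            p, nrm = _point_and_normal(parent.polyline_mm, s0)
            side = rng.choice([-1.0, 1.0])
            length = spec.lateral_length_mm * (1 + rng.uniform(-0.3, 0.3))
            npts = int(max(4, length / 0.8))
            pts = [np.asarray(p)]
            # laterals emerge near-perpendicular to the parent, then curve
            # downward (gravitropism) — they diverge instead of hugging
            # the parent's subapical zone
            h = side * np.deg2rad(75.0 + rng.normal(0, 8.0))
            for _ in range(npts):
                h = 0.90 * h + rng.normal(0, np.deg2rad(5.0))
                y, x = pts[-1]
                nx = x + 0.8 * np.sin(h)
                ny = y + 0.8 * abs(np.cos(h))
                if not (bounds[0] <= ny <= bounds[1] and bounds[2] <= nx <= bounds[3]):
                    break
                pts.append(np.array([ny, nx]))
            if len(pts) < 4:
                continue
            poly = np.asarray(pts)
            d = spec.lateral_diameter_mm * (1 + rng.uniform(-0.08, 0.08))
            elements.append(Element(eid, "lateral", poly, d,
                                    _polyline_length(poly), parent_id=parent.element_id))
            eid += 1

    # root hairs: Poisson process along each root axis, per side
    roots = list(elements)
    for root in roots:
        hairable = root.length_mm - spec.hair_free_tip_mm
        if hairable <= 0 or spec.hair_density_per_mm <= 0:
            continue
        for side in (-1.0, 1.0):
            n = rng.poisson(spec.hair_density_per_mm * hairable)
            s_pos = np.sort(rng.uniform(0.0, hairable, size=n))
            for s0 in s_pos:
                p, nrm = _point_and_normal(root.polyline_mm, s0)
                tilt = np.deg2rad(rng.uniform(-spec.hair_tilt_max_deg,
                                              spec.hair_tilt_max_deg))
                direction = _rotate(nrm * side, tilt)
                length = rng.normal(spec.hair_length_mm,
                                    spec.hair_length_cv * spec.hair_length_mm)
                length = float(max(length, 0.2 * spec.hair_length_mm))
                base = p + nrm * side * (root.diameter_mm / 2)
                tip = base + direction * length
                poly = np.stack([base, tip])
                elements.append(Element(eid, "hair", poly, spec.hair_diameter_mm,
                                        length, parent_id=root.element_id,
                                        base_s_mm=float(s0)))
                eid += 1
    return elements


def _rotate(v: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _render_coverage(shape_px, elements, scale) -> np.ndarray:
    canvas = np.zeros(shape_px, dtype=float)
    segs = []
    for e in elements:
        poly = e.polyline_mm
        r = e.diameter_mm / 2
        for i in range(len(poly) - 1):
            segs.append((poly[i], poly[i + 1], r))
    _draw_capsules(canvas, segs, scale)
    return canvas


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic rhizobox scan.

    Returns the 8-bit grayscale image (bright roots on a dark woven
    background, Gaussian-blurred then noise-corrupted) and the exact
    :class:`GroundTruth` geometry used to render it.  Identical specs
    (including ``rng_seed``) produce bit-identical rasters.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    elements = _build_geometry(spec, rng)
    shape = spec.shape_px
    coverage = _render_coverage(shape, elements, spec.scale)
    truth_mask = coverage >= 0.5

    bg = render_fabric_background(shape[0], shape[1],
                                  spec.background_mesh_period_px,
                                  rng_seed=spec.rng_seed + 1).astype(float)
    img = np.maximum(bg, coverage * FOREGROUND_GRAY)
    if spec.blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma_px)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return img, GroundTruth(elements=elements, truth_mask=truth_mask, scale=spec.scale)


def truth_summary(gt: GroundTruth, threshold_mm: float = 0.2) -> MorphometrySummary:
    """Exact trait totals in the pipeline's output schema.

    Naked root area = Σ π·d·ℓ over root elements, hair area = Σ π·d·ℓ
    over hairs, converted to the cm-based reporting units, enabling
    field-by-field recovery comparisons against measured summaries.
    """
    length_cm = gt.total_root_length_mm / 10.0
    naked_cm2 = gt.naked_area_mm2 / 100.0
    hair_cm2 = gt.hair_area_mm2 / 100.0
    total_cm2 = naked_cm2 + hair_cm2
    avg_d = gt.mean_root_diameter_mm() if length_cm > 0 else None
    return MorphometrySummary(
        total_root_length_cm=length_cm,
        naked_root_area_cm2=naked_cm2,
        hair_area_cm2=hair_cm2,
        total_area_cm2=total_cm2,
        average_diameter_mm=avg_d,
        hair_area_per_root_length_cm2_per_cm=(hair_cm2 / length_cm) if length_cm > 0 else 0.0,
        diameter_class_threshold_mm=threshold_mm,
    )


def write_scene(path, image: np.ndarray) -> None:
    """Write an 8-bit grayscale scene to PNG/TIFF."""
    iio.imwrite(path, image)


def write_spec(path, spec: SceneSpec) -> None:
    """Flat key=value serialization of a SceneSpec."""
    with open(path, "w") as fh:
        for f in dataclasses.fields(spec):
            fh.write(f"{f.name}={getattr(spec, f.name)}\n")


def read_spec(path) -> SceneSpec:
    kwargs = {}
    types = {f.name: f.type for f in dataclasses.fields(SceneSpec)}
    defaults = SceneSpec()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, v = line.split("=", 1)
            k = k.strip()
            cur = getattr(defaults, k)
            kwargs[k] = type(cur)(v.strip()) if not isinstance(cur, bool) else v.strip() == "True"
    return SceneSpec(**kwargs)
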