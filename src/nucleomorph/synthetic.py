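"""Procedural synthetic nucleus shapes and test micrographs.

Deformed nuclei on dense micropillar arrays range from circles and mild
ellipses through bent and branched silhouettes ("C", "L", "T", "U", "S",
"+") up to grid-like "#" extremes.  This module rasterizes an 11-template
vocabulary spanning that range, produces randomized variants (random
orientation and scale plus pinch / twirl / wave / ripple coordinate
distortions standing in for the interactive filters used to build the
original test database), and composites variants into synthetic
micrographs with known ground truth so every QC filter of the
preprocessing chain can be exercised without real data.

Template geometry is defined by closed-form occupancy functions on the
unit box; rasterization samples pixel centers, so variants at any size or
under any distortion are produced analytically rather than by resampling
a reference raster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from ._util import crop_to_bbox, round_half_away

__all__ = [
    "TEMPLATE_NAMES",
    "TEMPLATE_GROUPS",
    "DistortionParams",
    "SyntheticScene",
    "make_template",
    "sample_distortion",
    "distort",
    "make_variant",
    "generate_database",
    "render_scene",
]

# template ids 1..11 in fixed order; "compact" templates should gate to
# R1/R2 after the pipeline, "deformed" ones to R3-R5
TEMPLATE_NAMES = (
    "circle",
    "ellipse",
    "kidney",
    "C",
    "L",
    "T",
    "U",
    "S",
    "cross",
    "grid",
    "dumbbell",
)
TEMPLATE_GROUPS = {
    "compact": ("circle", "ellipse"),
    "deformed": ("C", "L", "T", "U", "S", "cross", "grid"),
    "other": ("kidney", "dumbbell"),
}

# Half-width of letter strokes in unit-box coordinates.  Letter templates
# fill their bounding box, which the pipeline maps to exactly 64 px, so a
# stroke of 0.625 units is exactly 20 px in the normalized frame; integer
# stroke widths avoid +-1 px quantization flicker at the 0.5 threshold.
_BAR = 0.3125


def _occ_circle(x, y):
    return x**2 + y**2 <= 1.0


def _occ_ellipse(x, y):
    # 1.5:1 axis ratio, major axis vertical: mild compact elongation
    return (1.5 * x) ** 2 + y**2 <= 1.0


def _occ_kidney(x, y):
    body = (x / 0.95) ** 2 + (y / 0.95) ** 2 <= 1.0
    bite = x**2 + (y - 0.95) ** 2 <= 0.55**2
    return body & ~bite


def _occ_c(x, y):
    r = np.hypot(x, y)
    ring = (r >= 0.52) & (r <= 1.0)
    gap = (np.abs(np.arctan2(y, x)) < np.radians(40)) & (x > 0)
    return ring & ~gap


def _occ_l(x, y):
    # letter-like L: long vertical stroke with a shorter foot, so the
    # principal axis is near-vertical rather than diagonal
    bar_v = (x >= -1) & (x <= -1 + 2 * _BAR)
    foot = (y >= -1) & (y <= -1 + 2 * _BAR) & (x <= 0.5)
    return (bar_v | foot) & (np.abs(x) <= 1) & (np.abs(y) <= 1)


def _occ_t(x, y):
    top = y >= 1 - 2 * _BAR
    stem = np.abs(x) <= _BAR
    return (top | stem) & (np.abs(x) <= 1) & (np.abs(y) <= 1)


def _occ_u(x, y):
    left = x <= -1 + 2 * _BAR
    right = x >= 1 - 2 * _BAR
    bottom = y <= -1 + 2 * _BAR
    return (left | right | bottom) & (np.abs(x) <= 1) & (np.abs(y) <= 1)


def _occ_s(x, y):
    w = 0.4375  # stroke width: 14 px in the 64-px normalized frame
    top = y >= 1 - w
    mid = np.abs(y) <= w / 2
    bot = y <= -1 + w
    left = (x <= -1 + w) & (y >= 0)
    right = (x >= 1 - w) & (y <= 0)
    box = (np.abs(x) <= 1) & (np.abs(y) <= 1)
    return (top | mid | bot | left | right) & box


def _occ_cross(x, y):
    return ((np.abs(x) <= _BAR) | (np.abs(y) <= _BAR)) & (np.abs(x) <= 1) & (np.abs(y) <= 1)


def _occ_grid(x, y):
    w = 0.175
    bars_v = (np.abs(x - 0.5) <= w) | (np.abs(x + 0.5) <= w)
    bars_h = (np.abs(y - 0.5) <= w) | (np.abs(y + 0.5) <= w)
    return (bars_v | bars_h) & (np.abs(x) <= 1) & (np.abs(y) <= 1)


def _occ_dumbbell(x, y):
    lobe1 = (x + 0.5) ** 2 + y**2 <= 0.5**2
    lobe2 = (x - 0.5) ** 2 + y**2 <= 0.5**2
    neck = (np.abs(y) <= 0.09) & (np.abs(x) <= 0.5)
    return lobe1 | lobe2 | neck


_OCCUPANCY = {
    "circle": _occ_circle,
    "ellipse": _occ_ellipse,
    "kidney": _occ_kidney,
    "C": _occ_c,
    "L": _occ_l,
    "T": _occ_t,
    "U": _occ_u,
    "S": _occ_s,
    "cross": _occ_cross,
    "grid": _occ_grid,
    "dumbbell": _occ_dumbbell,
}


@dataclass
class DistortionParams:
    """Random variant parameters; identical seed gives identical output."""

    rotation_deg: float = 0.0
    scale: float = 1.0
    pinch: float = 0.0  # radial pinch strength, 0..~0.3
    twirl_deg: float = 0.0  # angular twist at the center, degrees
    wave_amp: float = 0.0  # horizontal sine displacement, unit-box units
    wave_wavelength: float = 0.5
    ripple_amp: float = 0.0  # radial sine modulation, unit-box units
    ripple_freq: int = 3
    seed: int = 0


@dataclass
class SyntheticScene:
    """Composite synthetic micrograph with per-object ground truth."""

    image: np.ndarray
    truth: list = field(default_factory=list)  # dicts: object_id, template, qc_violation, ...
    seed: int = 0

    @property
    def n_clean(self) -> int:
        return sum(1 for t in self.truth if t["qc_violation"] == "none")


def _pixel_grid(size: int):
    """Pixel-center coordinates mapping the raster onto [-1, 1]^2.

    Coordinates are normalized by size/2 so the nominal shape boundary
    falls half a pixel inside the raster edge; a unit circle then fills
    its bounding box at the exact pi/4 ratio in expectation.
    """
    half = size / 2.0
    idx = np.arange(size) - (size - 1) / 2.0
    y = -(idx / half)[:, None]  # +y up
    x = (idx / half)[None, :]
    return x, y


def _rasterize(template: str, size: int) -> np.ndarray:
    x, y = _pixel_grid(size)
    mask = _OCCUPANCY[template](x + np.zeros_like(y), y + np.zeros_like(x))
    return crop_to_bbox(mask)


def make_template(template: int | str, base_size: int = 128) -> np.ndarray:
    """Rasterize a named (or 1-based numbered) template at ``base_size`` px."""
    if isinstance(template, (int, np.integer)):
        if not 1 <= template <= len(TEMPLATE_NAMES):
            raise ValueError(f"template_id must be 1..{len(TEMPLATE_NAMES)}")
        template = TEMPLATE_NAMES[template - 1]
    if template not in _OCCUPANCY:
        raise ValueError(f"unknown template {template!r}")
    if base_size < 64:
        raise ValueError("base_size must be >= 64")
    return _rasterize(template, base_size)


def sample_distortion(
    rng: np.random.Generator,
    seed: int = 0,
    scale_range: tuple[float, float] = (0.5, 1.5),
    pinch_max: float = 0.15,
    twirl_max_deg: float = 25.0,
    wave_amp_max: float = 0.06,
    ripple_amp_max: float = 0.03,
    apply_prob: float = 0.5,
) -> DistortionParams:
    """Draw variant parameters: random orientation and scale always, each
    distortion filter applied with probability ``apply_prob``."""

    def maybe(value):
        return value if rng.random() < apply_prob else 0.0

    return DistortionParams(
        rotation_deg=float(rng.uniform(0.0, 360.0)),
        scale=float(rng.uniform(*scale_range)),
        pinch=float(maybe(rng.uniform(0.3, 1.0) * pinch_max)),
        twirl_deg=float(maybe(rng.uniform(0.3, 1.0) * twirl_max_deg)),
        wave_amp=float(maybe(rng.uniform(0.3, 1.0) * wave_amp_max)),
        wave_wavelength=float(rng.uniform(0.35, 0.7)),
        ripple_amp=float(maybe(rng.uniform(0.3, 1.0) * ripple_amp_max)),
        ripple_freq=int(rng.integers(2, 6)),
        seed=seed,
    )


def _distorted_coords(x, y, p: DistortionParams):
    """Map output pixel coordinates back to template coordinates.

    The four effects are polar/Cartesian remaps applied to the sampling
    grid (ripple, wave, twirl, pinch), followed by the inverse rotation;
    scale is absorbed into the raster size.
    """
    # ripple: radial sine modulation, f lobes around the full turn
    r = np.hypot(x, y)
    th = np.arctan2(y, x)
    r = r + p.ripple_amp * np.sin(p.ripple_freq * th)
    # wave: horizontal sine displacement as a function of y
    x = r * np.cos(th)
    y = r * np.sin(th)
    x = x + p.wave_amp * np.sin(2.0 * np.pi * y / p.wave_wavelength)
    # twirl: rotate by an angle decaying with radius
    r = np.hypot(x, y)
    th = np.arctan2(y, x)
    rmax = 1.0
    th = th + np.radians(p.twirl_deg) * np.clip(1.0 - r / rmax, 0.0, 1.0)
    # pinch: radial contraction strongest at the center
    r = r * (1.0 - p.pinch * np.clip(1.0 - r / rmax, 0.0, 1.0))
    # inverse rotation
    th = th - np.radians(p.rotation_deg)
    return r * np.cos(th), r * np.sin(th)


def distort(template: int | str, params: DistortionParams, base_size: int = 128) -> np.ndarray:
    """Rasterize one distorted variant of a template.

    The output raster is evaluated analytically: every output pixel center
    is mapped through the distortion chain into template coordinates and
    tested against the occupancy function, so masks stay crisp at any
    scale.  If the distortions disconnect the shape (or shrink it below
    50 px) the strengths are attenuated and the variant is retried, at
    most five times.
    """
    if isinstance(template, (int, np.integer)):
        template = TEMPLATE_NAMES[template - 1]
    occ = _OCCUPANCY[template]
    # canvas oversized by 1.5x so rotated/displaced shapes are never clipped
    nominal = max(16.0, base_size * params.scale)
    size = int(np.ceil(nominal * 1.5))
    half = nominal / 2.0
    idx = np.arange(size) - (size - 1) / 2.0
    p = params
    for attempt in range(6):
        yy = -(idx / half)[:, None] + np.zeros((1, size))
        xx = (idx / half)[None, :] + np.zeros((size, 1))
        u, v = _distorted_coords(xx, yy, p)
        mask = occ(u, v)
        if mask.any():
            mask = crop_to_bbox(mask)
            labels, n = ndi.label(mask, structure=np.ones((3, 3)))
            if n == 1 and mask.sum() >= 50:
                return mask
            if n > 1:
                sizes = np.bincount(labels.ravel())[1:]
                if sizes.max() >= 0.98 * sizes.sum() and sizes.max() >= 50:
                    # negligible satellite specks: keep the main component
                    return crop_to_bbox(labels == (1 + int(np.argmax(sizes))))
        p = DistortionParams(
            rotation_deg=p.rotation_deg,
            scale=p.scale,
            pinch=p.pinch * 0.5,
            twirl_deg=p.twirl_deg * 0.5,
            wave_amp=p.wave_amp * 0.5,
            wave_wavelength=p.wave_wavelength,
            ripple_amp=p.ripple_amp * 0.5,
            ripple_freq=p.ripple_freq,
            seed=p.seed,
        )
    raise RuntimeError(f"variant generation failed for {template} (seed {params.seed})")


def make_variant(template: int | str, master_seed: int, variant_index: int, base_size: int = 128):
    """One deterministic variant; the per-variant stream is derived from
    (master_seed, template_id, variant_index)."""
    if isinstance(template, str):
        template_id = TEMPLATE_NAMES.index(template) + 1
    else:
        template_id = int(template)
    ss = np.random.SeedSequence([int(master_seed), template_id, int(variant_index)])
    rng = np.random.default_rng(ss)
    params = sample_distortion(rng, seed=int(master_seed))
    return distort(template_id, params, base_size=base_size), params


def generate_database(
    n_per_template: int = 50, seed: int = 0, base_size: int = 128
) -> list[tuple[np.ndarray, int]]:
    """The synthetic test database: 11 templates x ``n_per_template`` variants.

    Returns (mask, template_id) pairs, template-major order; defaults give
    550 masks.  Bit-reproducible for a fixed master seed.
    """
    if n_per_template < 1:
        raise ValueError("n_per_template must be >= 1")
    out = []
    for tid in range(1, len(TEMPLATE_NAMES) + 1):
        for k in range(n_per_template):
            mask, _ = make_variant(tid, seed, k, base_size=base_size)
            out.append((mask, tid))
    return out


# ---------------------------------------------------------------------------
# scene compositing


def _violation_mask(kind: str, rng: np.random.Generator, image_shape) -> np.ndarray:
    h, w = image_shape
    if kind == "too_small":
        y, x = np.mgrid[-3:4, -3:4]
        return x * x + y * y <= 9  # 29 px, under the 50 px floor
    if kind == "too_big":
        # > 1 % of the scene area
        side = int(np.sqrt(0.011 * h * w / (np.pi / 4)) + 2)
        return make_template("circle", base_size=max(side, 64))
    if kind == "mitotic_pair":
        return make_template("dumbbell", base_size=72)
    if kind == "full_bbox":
        # tall thin solid bar: survives corner rounding after the 64-px
        # downscale and then fills its bounding box exactly
        return np.ones((150, 16), dtype=bool)
    raise ValueError(f"no synthetic mask for violation {kind!r}")


def render_scene(
    placements: list[dict],
    image_shape: tuple[int, int] = (640, 640),
    seed: int = 0,
    fg: float = 0.8,
    bg: float = 0.1,
    noise_sigma: float = 0.02,
) -> SyntheticScene:
    """Composite a synthetic micrograph from placement specs.

    Each placement is a dict with keys ``template`` (name or id, used for
    clean objects), ``center`` (row, col), optional ``size`` (px, default
    56) and optional ``qc_violation`` in {none, border, too_small,
    too_big, mitotic_pair, full_bbox}.  Objects are bright (``fg``) on a
    dim background (``bg``) with additive Gaussian noise.  Non-pair
    overlapping placements are rejected.

    A ``high_std`` violation is not offered: the population standard
    deviation of [0, 1] intensities is bounded by 0.5, so no renderable
    object can exceed the default intensity-std limit.
    """
    rng = np.random.default_rng(seed)
    h, w = image_shape
    canvas = np.zeros((h, w), dtype=bool)
    image = np.full((h, w), bg)
    truth = []
    for i, spec in enumerate(placements):
        kind = spec.get("qc_violation", "none")
        size = int(spec.get("size", 56))
        if kind in ("none", "border"):
            tpl = spec.get("template", "circle")
            if "variant_seed" in spec:
                mask, _ = make_variant(tpl, int(spec["variant_seed"]), i, base_size=size)
            else:
                if isinstance(tpl, (int, np.integer)):
                    tpl = TEMPLATE_NAMES[int(tpl) - 1]
                mask = _rasterize(tpl, size)
        else:
            mask = _violation_mask(kind, rng, image_shape)
        mh, mw = mask.shape
        r, c = spec["center"]
        r0, c0 = int(r - mh // 2), int(c - mw // 2)
        if kind == "border":
            # push the object past its nearest image edge so it is clipped
            nearest = min((r, "top"), (h - r, "bottom"), (c, "left"), (w - c, "right"))[1]
            if nearest == "top":
                r0 = -(mh // 3)
            elif nearest == "bottom":
                r0 = h - mh + mh // 3
            elif nearest == "left":
                c0 = -(mw // 3)
            else:
                c0 = w - mw + mw // 3
        rs, cs = max(r0, 0), max(c0, 0)
        re, ce = min(r0 + mh, h), min(c0 + mw, w)
        if rs >= re or cs >= ce:
            raise ValueError(f"placement {i} is entirely outside the image")
        sub = mask[rs - r0 : re - r0, cs - c0 : ce - c0]
        if kind != "border" and (rs != r0 or cs != c0 or re != r0 + mh or ce != c0 + mw):
            raise ValueError(f"placement {i} crosses the border without a border violation")
        if (canvas[rs:re, cs:ce] & sub).any():
            raise ValueError(f"placement {i} overlaps an earlier object")
        canvas[rs:re, cs:ce] |= sub
        image[rs:re, cs:ce][sub] = fg
        truth.append(
            {
                "object_id": i,
                "template": spec.get("template", ""),
                "qc_violation": kind,
                "bbox": (rs, cs, re, ce),
                "area_px": int(sub.sum()),
            }
        )
    image = image + rng.normal(0.0, noise_sigma, size=image.shape)
    return SyntheticScene(image=np.clip(image, 0.0, 1.0), truth=truth, seed=seed)
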