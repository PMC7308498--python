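"""Synthetic vascular phantoms with exact ground truth.

Generates randomly branching 2D vessel trees — varying widths, bifurcation
angles and orientations — rendered the way vessels appear on angiographic
maximum-intensity projections, together with the exact mask, centerline,
per-pixel radii and bifurcation count.  A resize-and-erode degradation
emulates the resolution loss of TOF-MRA acquisition, and two further
degradations reproduce common angiographic artifacts: column-wise Gaussian
noise (8-bit levels 50-200) and a horizontal background ramp that mimics
imperfect background suppression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import line as _draw_line
from skimage.transform import downscale_local_mean, resize

NOISE_LEVELS = (0, 50, 100, 150, 200)


@dataclass(frozen=True)
class Segment:
    """A straight tube: endpoints in (row, col) float pixels and a radius in px."""

    p0: tuple[float, float]
    p1: tuple[float, float]
    radius: float

    @property
    def length(self) -> float:
        return float(np.hypot(self.p1[0] - self.p0[0], self.p1[1] - self.p0[1]))


@dataclass
class PhantomSpec:
    """Conditions of one synthetic tree.

    Radii span root_radius down to min_radius with child radius =
    parent x radius_decay (+/-10% jitter); branch length is proportional to
    radius (length_scale px per px of radius); bifurcation angles are drawn
    from branch_angle_range degrees.
    """

    image_size: int = 512
    n_branch_target: int = 48
    root_radius: float = 6.0
    radius_decay: float = 0.75
    branch_angle_range: tuple[float, float] = (20.0, 50.0)
    min_radius: float = 1.0
    intensity_profile: str = "uniform"
    length_scale: float = 16.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        if not (0 < self.radius_decay < 1):
            raise ValueError("radius_decay must lie in (0, 1)")
        if self.min_radius >= self.root_radius:
            raise ValueError("min_radius must be smaller than root_radius")
        if self.intensity_profile not in ("uniform", "gaussian-cross-section"):
            raise ValueError(f"unknown intensity profile {self.intensity_profile!r}")


@dataclass
class Phantom:
    """A rendered phantom plus its exact ground truth."""

    image: np.ndarray
    truth_mask: np.ndarray
    truth_centerline: np.ndarray
    truth_radii: np.ndarray
    truth_bifurcations: int
    n_branches: int
    segments: list[Segment]
    spec: PhantomSpec


def generate_tree(spec: PhantomSpec) -> list[Segment]:
    """Recursive binary branching from a root segment; deterministic per seed.

    Each branch runs for length proportional to its radius, then splits into
    two children rotated by angles drawn from ``branch_angle_range`` with
    child radii = parent x decay x (1 +/- 10%).  Growth stops at
    ``min_radius``, at the image bounds, or once the branch target is
    reached; a tree that cannot reach 80% of the target emits a warning.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    margin = spec.root_radius + 2.0

    def clip_point(p):
        return (float(np.clip(p[0], margin, size - 1 - margin)),
                float(np.clip(p[1], margin, size - 1 - margin)))

    root_start = (size * 0.92, size * 0.5)
    root_dir = np.array([-1.0, 0.0]) + rng.normal(0, 0.1, 2)
    root_dir /= np.linalg.norm(root_dir)

    segments: list[Segment] = []
    # queue entries: (start point, unit direction, radius)
    queue: list[tuple[tuple[float, float], np.ndarray, float]] = [
        (root_start, root_dir, float(spec.root_radius))
    ]
    while queue:
        start, direction, radius = queue.pop(0)
        length = spec.length_scale * radius * rng.uniform(0.85, 1.15)
        raw_end = (start[0] + direction[0] * length, start[1] + direction[1] * length)
        end = clip_point(raw_end)
        hit_border = end != tuple(np.round(raw_end, 10)) and (
            abs(end[0] - raw_end[0]) > 1e-6 or abs(end[1] - raw_end[1]) > 1e-6
        )
        if np.hypot(end[0] - start[0], end[1] - start[1]) < 2.0:
            continue  # degenerate stub against the border
        segments.append(Segment(p0=start, p1=end, radius=radius))
        # queued branches will all become segments: count them against the target
        if hit_border or len(segments) + len(queue) >= spec.n_branch_target:
            continue
        base = np.arctan2(direction[1], direction[0])
        lo, hi = spec.branch_angle_range
        children = []
        for sign in (+1, -1):
            angle = base + sign * np.deg2rad(rng.uniform(lo, hi))
            child_r = radius * spec.radius_decay * rng.uniform(0.9, 1.1)
            if child_r >= spec.min_radius:
                children.append(((end), np.array([np.cos(angle), np.sin(angle)]), float(child_r)))
        if len(children) == 2:
            queue.extend(children)
    if len(segments) < 0.8 * spec.n_branch_target:
        warnings.warn(
            f"tree terminated with {len(segments)} branches "
            f"(target {spec.n_branch_target}); best effort returned"
        )
    return segments


def count_split_points(segments: list[Segment]) -> int:
    """Number of points where two child branches emanate (bifurcations)."""
    starts: dict[tuple[float, float], int] = {}
    for seg in segments:
        key = (round(seg.p0[0], 6), round(seg.p0[1], 6))
        starts[key] = starts.get(key, 0) + 1
    return sum(1 for n in starts.values() if n >= 2)


def _segment_distance_field(seg: Segment, size: int):
    """Distance to the segment axis inside its padded bounding box.

    Returns (row slice, col slice, distance array) for the box.
    """
    pad = seg.radius + 2.0
    r0 = int(max(np.floor(min(seg.p0[0], seg.p1[0]) - pad), 0))
    r1 = int(min(np.ceil(max(seg.p0[0], seg.p1[0]) + pad), size - 1))
    c0 = int(max(np.floor(min(seg.p0[1], seg.p1[1]) - pad), 0))
    c1 = int(min(np.ceil(max(seg.p0[1], seg.p1[1]) + pad), size - 1))
    rr, cc = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    a = np.array(seg.p0)
    b = np.array(seg.p1)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        d = np.hypot(rr - a[0], cc - a[1])
    else:
        t = ((rr - a[0]) * ab[0] + (cc - a[1]) * ab[1]) / denom
        t = np.clip(t, 0.0, 1.0)
        d = np.hypot(rr - (a[0] + t * ab[0]), cc - (a[1] + t * ab[1]))
    return slice(r0, r1 + 1), slice(c0, c1 + 1), d


def rasterize(segments: list[Segment], image_size: int):
    """Render segments into exact ground truth.

    A pixel belongs to the mask iff its distance to some segment axis is at
    most that segment's radius; the centerline is the rasterized axes; each
    centerline pixel carries the radius of its (thickest) owning segment.
    Returns ``(mask, centerline, radii, n_bifurcations)``.
    """
    mask = np.zeros((image_size, image_size), dtype=bool)
    centerline = np.zeros_like(mask)
    radii = np.zeros((image_size, image_size), dtype=np.float64)
    for seg in segments:
        rs, cs, d = _segment_distance_field(seg, image_size)
        mask[rs, cs] |= d <= seg.radius
        rr, cc = _draw_line(
            int(round(seg.p0[0])), int(round(seg.p0[1])),
            int(round(seg.p1[0])), int(round(seg.p1[1])),
        )
        keep = (rr >= 0) & (rr < image_size) & (cc >= 0) & (cc < image_size)
        rr, cc = rr[keep], cc[keep]
        centerline[rr, cc] = True
        radii[rr, cc] = np.maximum(radii[rr, cc], seg.radius)
    return mask, centerline, radii, count_split_points(segments)


def render_intensity(truth_mask: np.ndarray, segments: list[Segment], profile: str = "uniform") -> np.ndarray:
    """Intensity image in [0, 1] for the rasterized tree.

    'uniform': 1 inside the mask, 0 outside.  'gaussian-cross-section':
    intensity exp(-d^2 / 2 (r/2)^2) across the tube (d = distance to axis),
    uniform along it, clipped at the mask boundary — the line profile of a
    vessel on a projection image.
    """
    if profile == "uniform":
        return truth_mask.astype(np.float64)
    if profile != "gaussian-cross-section":
        raise ValueError(f"unknown intensity profile {profile!r}")
    size = truth_mask.shape[0]
    img = np.zeros_like(truth_mask, dtype=np.float64)
    for seg in segments:
        rs, cs, d = _segment_distance_field(seg, size)
        sigma = seg.radius / 2.0
        vals = np.exp(-(d**2) / (2 * sigma**2))
        vals[d > seg.radius] = 0.0
        img[rs, cs] = np.maximum(img[rs, cs], vals)
    img[~truth_mask] = 0.0
    return img


def degrade_resize_erode(image: np.ndarray, factor: int = 2, erode: bool = True) -> np.ndarray:
    """Simulate acquisition resolution loss: down/upscale then grayscale-erode.

    Downscaling uses block averaging and the upscale is bilinear, so the
    blur spreads at most one pixel beyond the original support; the 3x3
    grayscale erosion then pulls the support back inside it.  ``factor=1``
    with ``erode=False`` is the identity.
    """
    image = np.asarray(image, dtype=np.float64)
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be an integer >= 1")
    out = image
    if factor > 1:
        h, w = image.shape
        pad_h = (-h) % factor
        pad_w = (-w) % factor
        padded = np.pad(image, ((0, pad_h), (0, pad_w)), mode="edge")
        down = downscale_local_mean(padded, (factor, factor))
        out = resize(down, padded.shape, order=1, anti_aliasing=False)[:h, :w]
    if erode:
        out = ndimage.grey_erosion(out, size=(3, 3))
    out = np.clip(out, 0.0, 1.0)
    if out.max() < 0.5 * image.max() and image.max() > 0:
        warnings.warn("degradation attenuated all vessels below half contrast")
    return out


#: gray levels per unit intensity: the 12-bit depth MR images are stored at.
#: Noise levels 50-200 then span sd 1.2-4.9% of the intensity range, the
#: regime in which added noise visibly degrades but does not bury the
#: vessels; on an 8-bit reading the same levels would be 20-78% of range,
#: which no segmentation method (or radiologist) could survive.
GRAY_SCALE_MAX = 4095


def add_columnwise_noise(
    image: np.ndarray,
    level: int,
    seed: int | None = None,
    gray_scale_max: int = GRAY_SCALE_MAX,
) -> np.ndarray:
    """Add column-wise Gaussian noise with mean = sd = ``level`` gray values.

    ``level`` is one of 0/50/100/150/200 gray values (0 is the identity) on
    a ``gray_scale_max``-deep scale, rescaled to the [0, 1] intensity range
    (level / gray_scale_max).  Each column receives its own draw of per-pixel
    noise; the result is clipped to [0, 1] and deterministic given ``seed``.
    """
    if level not in NOISE_LEVELS:
        raise ValueError(f"noise level must be one of {NOISE_LEVELS}, got {level}")
    image = np.asarray(image, dtype=np.float64)
    if level == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    scale = level / gray_scale_max
    nrows, ncols = image.shape
    # one independent noise field drawn column by column
    noise = rng.normal(loc=scale, scale=scale, size=(ncols, nrows)).T
    return np.clip(image + noise, 0.0, 1.0)


def add_background_gradient(image: np.ndarray, max_fraction: float = 0.75) -> np.ndarray:
    """Add a left-to-right linear background ramp (poor background suppression).

    The ramp rises from 0 at the left edge to ``max_fraction`` x max(image)
    at the right edge; output clipped to [0, 1].
    """
    if not (0 <= max_fraction < 1):
        raise ValueError("max_fraction must lie in [0, 1)")
    image = np.asarray(image, dtype=np.float64)
    if max_fraction == 0:
        return image.copy()
    ramp = np.linspace(0.0, max_fraction * float(image.max()), image.shape[1])
    return np.clip(image + ramp[np.newaxis, :], 0.0, 1.0)


def generate_phantom(spec: PhantomSpec, resize_erode_factor: int = 2, erode: bool = True) -> Phantom:
    """Generate a complete phantom: tree, ground truth and rendered image.

    The rendered image passes through the resize-erode degradation by
    default (factor 2), matching the resolution and vessel sizes of TOF-MRA.
    The degradation genuinely thins the vessels, so the ground truth tracks
    it: the binary mask goes through the identical resize-erode (thresholded
    at 0.5), the centerline is restricted to the surviving mask, and
    truth radii are the distance-to-background of the degraded mask at the
    centerline.  Without degradation the truth equals the exact
    rasterization, with per-segment analytic radii on the centerline.
    """
    from .frangi import edt  # local import: frangi does not depend on synth

    segments = generate_tree(spec)
    mask, centerline, radii, n_bif = rasterize(segments, spec.image_size)
    img = render_intensity(mask, segments, spec.intensity_profile)
    degraded = resize_erode_factor > 1 or erode
    if degraded:
        img = degrade_resize_erode(img, factor=resize_erode_factor, erode=erode)
        # the truth undergoes the same geometric degradation, in its binary
        # form: resize at the 0.5 level set, then binary erosion (the binary
        # counterpart of the grayscale 3x3 erosion)
        truth_mask = degrade_resize_erode(
            mask.astype(np.float64), factor=resize_erode_factor, erode=False
        ) >= 0.5
        if erode:
            truth_mask = ndimage.binary_erosion(truth_mask, structure=np.ones((3, 3)))
        centerline = centerline & truth_mask
        radii = edt(truth_mask) * centerline
    else:
        truth_mask = mask
    return Phantom(
        image=img,
        truth_mask=truth_mask,
        truth_centerline=centerline,
        truth_radii=radii,
        truth_bifurcations=n_bif,
        n_branches=len(segments),
        segments=segments,
        spec=spec,
    )
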