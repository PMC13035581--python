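"""Deterministic geometry and rasterization primitives.

Every stimulus in the benchmark is built from two primitives: a *corner
fragment* (two straight strokes of equal length meeting at a vertex) and a
*pac-man* (a filled disk with a wedge removed).  Rasterization is binary
(no anti-aliasing) and purely analytic: a pixel is foreground iff its
center lies inside the primitive's footprint.  Identical inputs therefore
yield bit-identical rasters, which downstream similarity measures rely on.

Conventions
-----------
* Image coordinates: x increases rightward, y increases downward, origin
  at the top-left corner; pixel (i, j) has its center at (j + 0.5, i + 0.5).
* Angles are in degrees, counterclockwise-positive *as displayed*, with 0°
  pointing up (toward decreasing y).
* Shades are 8-bit grayscale: black = 0, white = 255.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from PIL import Image

SHADES = {"white": 255, "black": 0}

Point = Tuple[float, float]


class ClippingError(ValueError):
    """A primitive would extend past the canvas border.

    Clipping is an error rather than silent truncation: the stimulus grids
    were designed (center positions included) so that every figure fits
    entirely on the canvas, and a truncated fragment would silently change
    the quantity the benchmark measures.
    """


@dataclass(frozen=True)
class CanvasSpec:
    """A square binary canvas with opposite background/foreground shades."""

    width: int = 300
    height: int = 300
    background: str = "white"

    def __post_init__(self) -> None:
        if self.background not in SHADES:
            raise ValueError(f"background must be one of {sorted(SHADES)}")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("canvas dimensions must be positive")

    @property
    def foreground(self) -> str:
        return "black" if self.background == "white" else "white"

    @property
    def background_value(self) -> int:
        return SHADES[self.background]

    @property
    def foreground_value(self) -> int:
        return SHADES[self.foreground]


@dataclass(frozen=True)
class CornerFragmentSpec:
    """Two strokes of length ``arm_length`` from ``vertex`` along two directions."""

    vertex: Point
    arm_angles: Tuple[float, float]
    arm_length: float
    stroke_width: float = 2.0

    def __post_init__(self) -> None:
        if not self.arm_length > 0:
            raise ValueError("arm_length must be positive")
        if (self.arm_angles[0] - self.arm_angles[1]) % 360.0 == 0.0:
            raise ValueError("the two arm directions must differ")
        if not self.stroke_width > 0:
            raise ValueError("stroke_width must be positive")


@dataclass(frozen=True)
class PacmanSpec:
    """A filled disk with a wedge of ``mouth_angle`` degrees removed.

    ``mouth_direction`` is the bisector of the removed wedge.  Triangle
    inducers use a 60° mouth (the interior angle of an equilateral
    triangle), square inducers a 90° mouth.
    """

    center: Point
    radius: float
    mouth_direction: float
    mouth_angle: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("radius must be positive")
        if not 0 < self.mouth_angle < 360:
            raise ValueError("mouth_angle must lie in (0, 360)")


def new_canvas(spec: CanvasSpec) -> np.ndarray:
    """Return a fresh uint8 canvas filled with the background shade."""
    return np.full((spec.height, spec.width), spec.background_value, dtype=np.uint8)


def rotate_point(p: Point, center: Point, angle: float) -> Point:
    """Rotate ``p`` about ``center`` by ``angle`` degrees, CCW as displayed.

    Because image y runs downward, the screen-CCW rotation matrix carries
    (1, 0) to (0, -1) at 90°.  The angle is reduced modulo 360 first so
    that full turns are exact identities in floating point.
    """
    if not math.isfinite(angle):
        raise ValueError("angle must be finite")
    if angle % 360.0 == 0.0:
        return (p[0], p[1])
    a = math.radians(angle % 360.0)
    dx, dy = p[0] - center[0], p[1] - center[1]
    c, s = math.cos(a), math.sin(a)
    return (center[0] + dx * c + dy * s, center[1] - dx * s + dy * c)


def direction(angle: float) -> Point:
    """Unit vector for a direction angle (0° = up, CCW positive)."""
    a = math.radians(angle % 360.0)
    return (-math.sin(a), -math.cos(a))


def angle_between(p_from: Point, p_to: Point) -> float:
    """Direction angle of the ray from ``p_from`` to ``p_to``, in [0, 360)."""
    dx, dy = p_to[0] - p_from[0], p_to[1] - p_from[1]
    if dx == 0.0 and dy == 0.0:
        raise ValueError("points coincide; direction undefined")
    return math.degrees(math.atan2(-dx, -dy)) % 360.0


def _check_inside(xs, ys, pad: float, canvas: np.ndarray, what: str) -> None:
    h, w = canvas.shape
    lo_x, hi_x = min(xs) - pad, max(xs) + pad
    lo_y, hi_y = min(ys) - pad, max(ys) + pad
    if lo_x < 0 or lo_y < 0 or hi_x > w or hi_y > h:
        raise ClippingError(
            f"{what} extends past the {w}x{h} canvas "
            f"(x range [{lo_x:.1f}, {hi_x:.1f}], y range [{lo_y:.1f}, {hi_y:.1f}])"
        )


def _pixel_centers(canvas: np.ndarray, lo_x, hi_x, lo_y, hi_y):
    """Meshgrid of pixel-center coordinates restricted to a bounding box."""
    h, w = canvas.shape
    j0 = max(int(math.floor(lo_x)) - 1, 0)
    j1 = min(int(math.ceil(hi_x)) + 1, w)
    i0 = max(int(math.floor(lo_y)) - 1, 0)
    i1 = min(int(math.ceil(hi_y)) + 1, h)
    jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
    return ii, jj, ii + 0.5, jj + 0.5


def draw_segment(canvas: np.ndarray, p0: Point, p1: Point,
                 stroke_width: float, fg_value: int) -> np.ndarray:
    """Stamp a stroke from p0 to p1 onto the canvas, in place.

    A pixel is foreground iff its center is within stroke_width/2 of the
    (continuous) segment.
    """
    half = stroke_width / 2.0
    _check_inside([p0[0], p1[0]], [p0[1], p1[1]], half, canvas, "stroke")
    lo_x, hi_x = min(p0[0], p1[0]) - half, max(p0[0], p1[0]) + half
    lo_y, hi_y = min(p0[1], p1[1]) - half, max(p0[1], p1[1]) + half
    ii, jj, cy, cx = _pixel_centers(canvas, lo_x, hi_x, lo_y, hi_y)
    vx, vy = p1[0] - p0[0], p1[1] - p0[1]
    seg_len2 = vx * vx + vy * vy
    if seg_len2 == 0.0:
        d2 = (cx - p0[0]) ** 2 + (cy - p0[1]) ** 2
    else:
        t = np.clip(((cx - p0[0]) * vx + (cy - p0[1]) * vy) / seg_len2, 0.0, 1.0)
        d2 = (cx - (p0[0] + t * vx)) ** 2 + (cy - (p0[1] + t * vy)) ** 2
    mask = d2 <= half * half
    canvas[ii[mask], jj[mask]] = fg_value
    return canvas


def draw_corner_fragment(canvas: np.ndarray, spec: CornerFragmentSpec,
                         fg_value: int) -> np.ndarray:
    """Draw both arms of a corner fragment. Raises ClippingError if clipped."""
    ends = []
    for ang in spec.arm_angles:
        ux, uy = direction(ang)
        ends.append((spec.vertex[0] + spec.arm_length * ux,
                     spec.vertex[1] + spec.arm_length * uy))
    half = spec.stroke_width / 2.0
    xs = [spec.vertex[0]] + [e[0] for e in ends]
    ys = [spec.vertex[1]] + [e[1] for e in ends]
    _check_inside(xs, ys, half, canvas, "corner fragment")
    for end in ends:
        draw_segment(canvas, spec.vertex, end, spec.stroke_width, fg_value)
    return canvas


def draw_pacman(canvas: np.ndarray, spec: PacmanSpec, fg_value: int) -> np.ndarray:
    """Draw a pac-man inducer. Raises ClippingError if the disk is clipped.

    A pixel belongs to the pac-man iff its center is inside the disk and
    its angular offset from the mouth bisector is at least mouth_angle/2.
    """
    cx0, cy0, r = spec.center[0], spec.center[1], spec.radius
    _check_inside([cx0], [cy0], r, canvas, "pac-man disk")
    ii, jj, cy, cx = _pixel_centers(canvas, cx0 - r, cx0 + r, cy0 - r, cy0 + r)
    dx, dy = cx - cx0, cy - cy0
    inside = dx * dx + dy * dy <= r * r
    # angle convention matches direction(): theta s.t. dir(theta) ∝ (dx, dy)
    ang = np.degrees(np.arctan2(-dx, -dy)) % 360.0
    offset = np.abs((ang - spec.mouth_direction % 360.0 + 180.0) % 360.0 - 180.0)
    mask = inside & (offset >= spec.mouth_angle / 2.0)
    canvas[ii[mask], jj[mask]] = fg_value
    return canvas


def draw_polygon_outline(canvas: np.ndarray, vertices, stroke_width: float,
                         fg_value: int) -> np.ndarray:
    """Draw the closed outline through ``vertices`` as strokes."""
    n = len(vertices)
    for k in range(n):
        draw_segment(canvas, vertices[k], vertices[(k + 1) % n],
                     stroke_width, fg_value)
    return canvas


def save_png(path, pixels: np.ndarray) -> None:
    """Write an 8-bit grayscale PNG (0 = black, 255 = white)."""
    Image.fromarray(pixels, mode="L").save(path, format="PNG")


def load_png(path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.uint8)
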