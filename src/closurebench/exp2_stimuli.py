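"""Configural-effect stimulus sets: base and composite pairs.

Each set contains four images built on a square of side 95 px:

* ``composite_c`` — four components, one per square corner, arranged so
  the figure closes: square-corner fragments whose arms run along the
  square's sides (``line_segments``), or pac-men whose 90° mouths face
  the square's center (``kanizsa_squares``).
* ``composite_d`` — the two *base* components (one diagonal) are each
  rotated 180° in place, breaking closure; the two *appended* components
  (the other diagonal) are pixel-identical to composite_c.
* ``base_c`` / ``base_d`` — only the two differing diagonal components,
  at the same positions as in the composites.

Because the appended context is identical across a pair and disjoint from
the base components, the raw-pixel distance between the composite pair
equals that between the base pair exactly; any nonzero configural effect
downstream must come from the feature extractor's nonlinearity.

The grid crosses 8 global orientations x 9 edge lengths x 2 backgrounds
x 2 center positions = 288 sets (1152 images) per condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .exp1_stimuli import StimulusImage, _fmt
from .stimulus_core import (
    CanvasSpec,
    PacmanSpec,
    angle_between,
    direction,
    draw_pacman,
    draw_segment,
    new_canvas,
    rotate_point,
    save_png,
)

CONDITIONS2 = ("line_segments", "kanizsa_squares")
THETA_GLOBAL2 = tuple(i * 11.25 for i in range(8))   # 0 .. 78.75
EDGE_LENGTHS2 = (5, 10, 14, 19, 24, 29, 33, 38, 43)
BACKGROUNDS2 = ("white", "black")
CENTERS2 = ((150.0, 150.0), (134.0, 134.0))

SIDE = 95.0            # vertex-to-vertex (line segments) / center-to-center (kanizsa)
STROKE_WIDTH = 2.0
SQUARE_MOUTH_ANGLE = 90.0

ROLES = ("base_c", "base_d", "composite_c", "composite_d")


@dataclass(frozen=True)
class Exp2SetParams:
    condition: str
    theta_global: float
    edge_length: float
    background: str
    center: Tuple[float, float]

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS2:
            raise ValueError(f"unknown condition {self.condition!r}")
        if not 0 <= self.theta_global < 90:
            raise ValueError("theta_global must lie in [0, 90); a quarter turn "
                             "maps the square onto itself")
        if not 0 < self.edge_length < SIDE:
            raise ValueError("edge_length must lie in (0, side)")


@dataclass(eq=False)
class PairSet:
    params: Exp2SetParams
    images: Dict[str, StimulusImage]


def enumerate_exp2_sets(condition: str) -> List[Exp2SetParams]:
    """Deterministic 8 x 9 x 2 x 2 = 288-set grid."""
    if condition not in CONDITIONS2:
        raise ValueError(f"unknown condition {condition!r}")
    out = []
    for tg in THETA_GLOBAL2:
        for el in EDGE_LENGTHS2:
            for bg in BACKGROUNDS2:
                for ctr in CENTERS2:
                    out.append(Exp2SetParams(condition, tg, el, bg, ctr))
    return out


def square_corners(center: Tuple[float, float],
                   theta_global: float) -> List[Tuple[float, float]]:
    """The four corners of the side-95 square, rotated about ``center``."""
    half_diag = SIDE / math.sqrt(2.0)
    corners = []
    for k in range(4):
        ux, uy = direction(45.0 + 90.0 * k)
        p = (center[0] + half_diag * ux, center[1] + half_diag * uy)
        corners.append(rotate_point(p, center, theta_global))
    return corners


def _segment_component(corner, neighbors, edge_length) -> List[Tuple]:
    """A square-corner fragment as a list of (p0, p1) strokes."""
    segs = []
    for nb in neighbors:
        ux, uy = direction(angle_between(corner, nb))
        segs.append((corner, (corner[0] + edge_length * ux,
                              corner[1] + edge_length * uy)))
    return segs


def _rot180(p, g):
    return (2.0 * g[0] - p[0], 2.0 * g[1] - p[1])


def _segments_centroid(segs):
    mids = [((p0[0] + p1[0]) / 2.0, (p0[1] + p1[1]) / 2.0) for p0, p1 in segs]
    return (sum(m[0] for m in mids) / len(mids), sum(m[1] for m in mids) / len(mids))


def _component_primitives(p: Exp2SetParams, corner_idx: int, corners,
                          disordered: bool):
    """Primitives for the component at one corner.

    ``disordered`` components are rotated 180° about their own centroid
    (fragment) or disk center (pac-man), which keeps their centroid fixed
    but breaks the closing configuration.
    """
    corner = corners[corner_idx]
    if p.condition == "line_segments":
        neighbors = [corners[(corner_idx + 1) % 4], corners[(corner_idx - 1) % 4]]
        segs = _segment_component(corner, neighbors, p.edge_length)
        if disordered:
            g = _segments_centroid(segs)
            segs = [(_rot180(a, g), _rot180(b, g)) for a, b in segs]
        return [("segment", s) for s in segs]
    mouth = angle_between(corner, p.center)
    if disordered:
        mouth += 180.0
    return [("pacman", PacmanSpec(corner, p.edge_length, mouth, SQUARE_MOUTH_ANGLE))]


def _render(p: Exp2SetParams, spec: CanvasSpec, primitives,
            role: str) -> StimulusImage:
    canvas = new_canvas(spec)
    fg = spec.foreground_value
    for kind, prim in primitives:
        if kind == "segment":
            p0, p1 = prim
            draw_segment(canvas, p0, p1, STROKE_WIDTH, fg)
        else:
            draw_pacman(canvas, prim, fg)
    return StimulusImage(p, role, canvas)


BASE_CORNERS = (0, 2)       # the differing diagonal
APPENDED_CORNERS = (1, 3)   # the identical context diagonal


def render_pair_set(p: Exp2SetParams,
                    canvas_spec: Optional[CanvasSpec] = None) -> PairSet:
    """Render the four images of one set, keyed by role."""
    spec = canvas_spec or CanvasSpec(background=p.background)
    if spec.background != p.background:
        spec = CanvasSpec(spec.width, spec.height, p.background)
    corners = square_corners(p.center, p.theta_global)

    base_c = [prim for k in BASE_CORNERS
              for prim in _component_primitives(p, k, corners, disordered=False)]
    base_d = [prim for k in BASE_CORNERS
              for prim in _component_primitives(p, k, corners, disordered=True)]
    appended = [prim for k in APPENDED_CORNERS
                for prim in _component_primitives(p, k, corners, disordered=False)]

    images = {
        "base_c": _render(p, spec, base_c, "base_c"),
        "base_d": _render(p, spec, base_d, "base_d"),
        "composite_c": _render(p, spec, base_c + appended, "composite_c"),
        "composite_d": _render(p, spec, base_d + appended, "composite_d"),
    }
    return PairSet(p, images)


def set_id(p: Exp2SetParams) -> str:
    return (f"{p.condition}_tg{_fmt(p.theta_global)}_el{_fmt(p.edge_length)}"
            f"_{p.background}_c{_fmt(p.center[0])}-{_fmt(p.center[1])}")


MANIFEST2_COLUMNS = ["filename", "set_id", "role", "condition", "theta_global",
                     "edge_length", "background", "center_x", "center_y"]


def manifest_rows(p: Exp2SetParams) -> List[dict]:
    sid = set_id(p)
    return [{
        "filename": f"{sid}_{role}.png",
        "set_id": sid,
        "role": role,
        "condition": p.condition,
        "theta_global": float(p.theta_global),
        "edge_length": float(p.edge_length),
        "background": p.background,
        "center_x": float(p.center[0]),
        "center_y": float(p.center[1]),
    } for role in ROLES]


def params_from_row(row) -> Exp2SetParams:
    return Exp2SetParams(
        condition=str(row["condition"]),
        theta_global=float(row["theta_global"]),
        edge_length=float(row["edge_length"]),
        background=str(row["background"]),
        center=(float(row["center_x"]), float(row["center_y"])),
    )


def generate_exp2(condition: str, out_dir,
                  canvas_spec: Optional[CanvasSpec] = None) -> pd.DataFrame:
    """Render all 288 sets (1152 PNGs) plus manifest.csv; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in enumerate_exp2_sets(condition):
        pair = render_pair_set(p, canvas_spec)
        for row in manifest_rows(p):
            save_png(out / row["filename"], pair.images[row["role"]].pixels)
            rows.append(row)
    manifest = pd.DataFrame(rows, columns=MANIFEST2_COLUMNS)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
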