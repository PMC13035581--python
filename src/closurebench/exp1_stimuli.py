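"""Triangle-completion stimulus grids.

Two variants of the same equilateral-triangle design:

* ``segments`` — triangle segment completion: a complete triangle outline,
  *aligned* corner fragments that continue the triangle's contour, or
  *disordered* fragments each rotated about its own vertex.
* ``kanizsa`` — Kanizsa triangles: the aligned/disordered fragments are
  replaced by pac-man inducers whose mouths face the centroid (valid) or
  are rotated away from it (invalid); the complete condition is the full
  triangle outline.

Both grids share one parameter space: 8 global orientations x 2
backgrounds x 2 center positions, crossed with 6 edge lengths for aligned
figures and additionally 4 local orientations for disordered ones, giving
32 complete + 192 aligned + 768 disordered = 992 images per variant.  The
triangle's vertices are always 116 px apart on a 300 x 300 canvas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .stimulus_core import (
    CanvasSpec,
    CornerFragmentSpec,
    PacmanSpec,
    angle_between,
    direction,
    draw_corner_fragment,
    draw_pacman,
    draw_polygon_outline,
    new_canvas,
    rotate_point,
    save_png,
)

VARIANTS = ("segments", "kanizsa")
CONDITIONS = ("complete", "aligned", "disordered")

THETA_GLOBAL = tuple(range(0, 120, 15))          # 0..105 in steps of 15
THETA_LOCAL = (72, 144, 216, 288)
EDGE_LENGTHS = (3, 8, 13, 18, 24, 29)
BACKGROUNDS = ("white", "black")
CENTERS = ((150.0, 150.0), (134.0, 134.0))

VERTEX_DISTANCE = 116.0
# circumradius of an equilateral triangle with side VERTEX_DISTANCE
CIRCUMRADIUS = VERTEX_DISTANCE / math.sqrt(3.0)

STROKE_WIDTH = 2.0
PACMAN_MOUTH_ANGLE = 60.0   # interior angle of the equilateral triangle


@dataclass(frozen=True)
class Exp1Params:
    variant: str
    condition: str
    theta_global: float
    background: str
    center: Tuple[float, float]
    edge_length: Optional[float] = None    # absent for complete figures
    theta_local: Optional[float] = None    # present only for disordered

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if (self.condition == "complete") != (self.edge_length is None):
            raise ValueError("edge_length must be absent iff condition is complete")
        if (self.condition == "disordered") != (self.theta_local is not None):
            raise ValueError("theta_local must be present iff condition is disordered")


@dataclass(eq=False)
class StimulusImage:
    """A rendered raster together with the parameters that produced it."""

    params: object
    role: str
    pixels: np.ndarray


def enumerate_exp1_params(variant: str) -> List[Exp1Params]:
    """The full deterministic grid: 32 complete, 192 aligned, 768 disordered."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    out: List[Exp1Params] = []
    for tg in THETA_GLOBAL:
        for bg in BACKGROUNDS:
            for ctr in CENTERS:
                out.append(Exp1Params(variant, "complete", tg, bg, ctr))
    for tg in THETA_GLOBAL:
        for bg in BACKGROUNDS:
            for ctr in CENTERS:
                for el in EDGE_LENGTHS:
                    out.append(Exp1Params(variant, "aligned", tg, bg, ctr,
                                          edge_length=el))
    for tg in THETA_GLOBAL:
        for bg in BACKGROUNDS:
            for ctr in CENTERS:
                for el in EDGE_LENGTHS:
                    for tl in THETA_LOCAL:
                        out.append(Exp1Params(variant, "disordered", tg, bg, ctr,
                                              edge_length=el, theta_local=tl))
    return out


def triangle_vertices(center: Tuple[float, float],
                      theta_global: float) -> List[Tuple[float, float]]:
    """Vertices of the equilateral triangle, top vertex up at theta_global=0."""
    verts = []
    for k in range(3):
        ux, uy = direction(120.0 * k)
        p = (center[0] + CIRCUMRADIUS * ux, center[1] + CIRCUMRADIUS * uy)
        verts.append(rotate_point(p, center, theta_global))
    return verts


def render_exp1_stimulus(p: Exp1Params,
                         canvas_spec: Optional[CanvasSpec] = None,
                         stroke_width: float = STROKE_WIDTH) -> StimulusImage:
    """Rasterize one grid point; raises ClippingError if the figure is clipped."""
    spec = canvas_spec or CanvasSpec(background=p.background)
    if spec.background != p.background:
        spec = CanvasSpec(spec.width, spec.height, p.background)
    canvas = new_canvas(spec)
    fg = spec.foreground_value
    verts = triangle_vertices(p.center, p.theta_global)

    if p.condition == "complete":
        draw_polygon_outline(canvas, verts, stroke_width, fg)
        return StimulusImage(p, "complete", canvas)

    tl = p.theta_local or 0.0
    for k, v in enumerate(verts):
        others = [verts[(k + 1) % 3], verts[(k + 2) % 3]]
        if p.variant == "segments":
            angles = tuple(angle_between(v, o) + tl for o in others)
            frag = CornerFragmentSpec(v, angles, p.edge_length, stroke_width)
            draw_corner_fragment(canvas, frag, fg)
        else:
            mouth = angle_between(v, p.center) + tl
            pac = PacmanSpec(v, p.edge_length, mouth, PACMAN_MOUTH_ANGLE)
            draw_pacman(canvas, pac, fg)
    return StimulusImage(p, p.condition, canvas)


def _fmt(x) -> str:
    if x is None:
        return "NA"
    f = float(x)
    return str(int(f)) if f == int(f) else str(f)


def stimulus_filename(p: Exp1Params) -> str:
    """Encode every parameter in the name so the manifest is recoverable."""
    return (
        f"{p.variant}_{p.condition}"
        f"_tg{_fmt(p.theta_global)}_el{_fmt(p.edge_length)}"
        f"_tl{_fmt(p.theta_local)}_{p.background}"
        f"_c{_fmt(p.center[0])}-{_fmt(p.center[1])}.png"
    )


MANIFEST_COLUMNS = ["filename", "variant", "condition", "theta_global",
                    "edge_length", "theta_local", "background",
                    "center_x", "center_y"]


def manifest_row(p: Exp1Params) -> dict:
    return {
        "filename": stimulus_filename(p),
        "variant": p.variant,
        "condition": p.condition,
        "theta_global": float(p.theta_global),
        "edge_length": None if p.edge_length is None else float(p.edge_length),
        "theta_local": None if p.theta_local is None else float(p.theta_local),
        "background": p.background,
        "center_x": float(p.center[0]),
        "center_y": float(p.center[1]),
    }


def params_from_row(row) -> Exp1Params:
    def opt(v):
        return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

    return Exp1Params(
        variant=str(row["variant"]),
        condition=str(row["condition"]),
        theta_global=float(row["theta_global"]),
        background=str(row["background"]),
        center=(float(row["center_x"]), float(row["center_y"])),
        edge_length=opt(row["edge_length"]),
        theta_local=opt(row["theta_local"]),
    )


def generate_exp1(variant: str, out_dir,
                  canvas_spec: Optional[CanvasSpec] = None) -> pd.DataFrame:
    """Render the full grid to PNG files plus a manifest.csv; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in enumerate_exp1_params(variant):
        img = render_exp1_stimulus(p, canvas_spec)
        row = manifest_row(p)
        save_png(out / row["filename"], img.pixels)
        rows.append(row)
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
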