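"""Rasterization of contour scenes to fixed-size RGB frames.

The default frame is 227 x 227 pixels.  Two style presets cover the stimulus
families: outline tasks draw black 2-px strokes on white with a filled red
square probe; the polygon-counting task draws filled white polygons on black
with a filled red dot.  Anti-aliasing is off so that pixel-level oracles
(flood fill, connected components) are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from PIL import Image, ImageDraw

from .geometry import Contour

FRAME_PX = 227


class OutOfFrameError(ValueError):
    """Scene geometry (or the probe marker) extends beyond the frame."""


@dataclass(frozen=True)
class RenderStyle:
    background: tuple[int, int, int] = (255, 255, 255)
    stroke: tuple[int, int, int] = (0, 0, 0)
    stroke_width: int = 2
    fill_shapes: bool = False
    fill_color: tuple[int, int, int] = (255, 255, 255)
    probe_color: tuple[int, int, int] = (255, 0, 0)
    probe_size: int = 5  # side (square) or diameter (dot), px
    probe_shape: str = "square"  # {"square", "dot"}


#: black strokes on white, red square probe (same-different + enclosure displays)
OUTLINE_STYLE = RenderStyle()
#: filled white polygons on black, red dot probe (more-fewer displays)
FILLED_STYLE = RenderStyle(
    background=(0, 0, 0),
    stroke=(255, 255, 255),
    fill_shapes=True,
    probe_shape="dot",
)

TASK_STYLES = {
    "same_different": OUTLINE_STYLE,
    "enclosure": OUTLINE_STYLE,
    "more_fewer": FILLED_STYLE,
}


def probe_clearance(style: RenderStyle) -> float:
    """Minimum center distance from a contour at which the probe cannot touch it."""
    half_diag = style.probe_size * np.sqrt(2.0) / 2.0
    return float(half_diag + style.stroke_width / 2.0 + 1.0)


def rasterize_scene(
    contours: Sequence[Contour],
    probe: Optional[Sequence[float]] = None,
    frame_px: int = FRAME_PX,
    style: RenderStyle = OUTLINE_STYLE,
) -> np.ndarray:
    """Render contours (and an optional probe marker) into an (H, W, 3) uint8 array."""
    for c in contours:
        x0, y0, x1, y1 = c.bbox()
        if x0 < 0 or y0 < 0 or x1 > frame_px or y1 > frame_px:
            raise OutOfFrameError(f"contour bbox {(x0, y0, x1, y1)} exceeds frame")
    if probe is not None:
        px, py = float(probe[0]), float(probe[1])
        h = style.probe_size / 2.0
        if px - h < 0 or py - h < 0 or px + h > frame_px or py + h > frame_px:
            raise OutOfFrameError("probe marker exceeds frame")

    img = Image.new("RGB", (frame_px, frame_px), style.background)
    draw = ImageDraw.Draw(img)
    for c in contours:
        pts = [tuple(v) for v in c.vertices]
        if c.closed:
            if style.fill_shapes:
                draw.polygon(pts, fill=style.fill_color, outline=None)
            else:
                draw.line(
                    pts + [pts[0]], fill=style.stroke, width=style.stroke_width,
                    joint="curve",
                )
        else:
            draw.line(pts, fill=style.stroke, width=style.stroke_width, joint="curve")
    if probe is not None:
        h = style.probe_size / 2.0
        box = [px - h, py - h, px + h, py + h]
        if style.probe_shape == "square":
            draw.rectangle(box, fill=style.probe_color)
        else:
            draw.ellipse(box, fill=style.probe_color)
    return np.asarray(img, dtype=np.uint8)


def to_image(arr: np.ndarray) -> Image.Image:
    return Image.fromarray(arr, mode="RGB")


def save_png(arr: np.ndarray, path) -> None:
    to_image(arr).save(path, format="PNG")
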