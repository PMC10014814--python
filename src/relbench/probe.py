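"""Decision-map probing: classify a fixed scene at every probe position.

For a background scene (typically one closed contour, with or without noise
fragments) the sweep renders the scene with the probe marker centered at
each node of a regular pixel grid, classifies every rendered image, and
records both the binary decision and the graded positive-class score
("p(inside)").  Grid nodes where the marker would overhang the frame are
marked invalid rather than clipped, since training never shows clipped
probes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from PIL import Image

from .geometry import Contour, points_in_region
from .render import FRAME_PX, RenderStyle, OUTLINE_STYLE, rasterize_scene

DECISION_THRESHOLD = 0.5


@dataclass
class ProbeMap:
    grid_step: int
    xs: np.ndarray  # grid x coordinates (probe centers, px)
    ys: np.ndarray
    decisions: np.ndarray  # int8, 1=inside, 0=outside, -1=invalid
    scores: np.ndarray  # float, NaN where invalid
    scene_id: str = ""

    def __post_init__(self) -> None:
        if self.decisions.shape != self.scores.shape:
            raise ValueError("decision and score grids must share dimensions")
        valid = self.decisions >= 0
        if valid.any():
            s = self.scores[valid]
            if np.isnan(s).any() or s.min() < 0 or s.max() > 1:
                raise ValueError("scores must lie in [0, 1] where valid")

    @property
    def valid(self) -> np.ndarray:
        return self.decisions >= 0


class OracleEnclosureModel:
    """Ideal inside/outside classifier recovered from the rendered image.

    Locates the red probe marker in each image (the probe is the only red
    ink) and ray-casts its centroid against the known closed contour.  Used
    as the exact reference against which trained models' decision maps are
    compared; it exercises the identical render-classify path.
    """

    input_size = FRAME_PX

    def __init__(self, closed: Contour, frame_px: int = FRAME_PX):
        if not closed.closed:
            raise ValueError("oracle needs the closed contour")
        self.closed = closed
        self.frame_px = frame_px

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.dtype != np.uint8:
            X = (X * 255).astype(np.uint8)
        scores = np.empty(len(X))
        for i, img in enumerate(X):
            red = (
                (img[:, :, 0].astype(int) - img[:, :, 1].astype(int) > 100)
                & (img[:, :, 0].astype(int) - img[:, :, 2].astype(int) > 100)
            )
            ys, xs = np.nonzero(red)
            if len(xs) == 0:
                scores[i] = 0.0
                continue
            center = np.array([xs.mean() + 0.5, ys.mean() + 0.5])
            scores[i] = float(points_in_region(center[None, :], self.closed)[0])
        return scores

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_scores(X) >= DECISION_THRESHOLD).astype(int)


def sweep_probe(
    model,
    scene: Sequence[Contour],
    grid_step: int = 2,
    frame_px: int = FRAME_PX,
    style: RenderStyle = OUTLINE_STYLE,
    scene_id: str = "",
    batch: int = 256,
) -> ProbeMap:
    """Classify the scene for every probe-center position on a regular grid."""
    if grid_step < 1:
        raise ValueError("grid_step must be >= 1")
    coords = np.arange(0, frame_px, grid_step, dtype=float) + 0.5
    n = len(coords)
    half = style.probe_size / 2.0
    decisions = np.full((n, n), -1, dtype=np.int8)
    scores = np.full((n, n), np.nan)

    size = getattr(model, "input_size", frame_px)
    positions = []
    index = []
    for iy, py in enumerate(coords):
        for ix, px in enumerate(coords):
            if px - half < 0 or py - half < 0 or px + half > frame_px or py + half > frame_px:
                continue  # probe would overhang the frame: invalid
            positions.append((px, py))
            index.append((iy, ix))

    for start in range(0, len(positions), batch):
        chunk = positions[start : start + batch]
        imgs = np.empty((len(chunk), size, size, 3), dtype=np.float32)
        for j, (px, py) in enumerate(chunk):
            arr = rasterize_scene(scene, probe=(px, py), frame_px=frame_px, style=style)
            if size != frame_px:
                arr = np.asarray(
                    Image.fromarray(arr).resize((size, size), Image.BILINEAR)
                )
            imgs[j] = arr.astype(np.float32) / 255.0
        s = np.clip(np.asarray(model.predict_scores(imgs), dtype=float), 0.0, 1.0)
        for j, (iy, ix) in enumerate(index[start : start + batch]):
            scores[iy, ix] = s[j]
            decisions[iy, ix] = 1 if s[j] >= DECISION_THRESHOLD else 0
    return ProbeMap(
        grid_step=grid_step, xs=coords, ys=coords,
        decisions=decisions, scores=scores, scene_id=scene_id,
    )


def interior_mask(pmap: ProbeMap, closed: Contour) -> np.ndarray:
    """Boolean grid: which valid probe centers lie in the closed interior."""
    gx, gy = np.meshgrid(pmap.xs, pmap.ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    return points_in_region(pts, closed).reshape(len(pmap.ys), len(pmap.xs))


def interior_fraction_inside(pmap: ProbeMap, closed: Contour) -> float:
    """Fraction of valid interior probe positions classified "Inside"."""
    sel = interior_mask(pmap, closed) & pmap.valid
    if not sel.any():
        return float("nan")
    return float((pmap.decisions[sel] == 1).mean())


def render_probe_map(
    pmap: ProbeMap,
    scene: Sequence[Contour],
    frame_px: int = FRAME_PX,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary (white=Inside) and grayscale (score) panels with the scene in red."""
    def upsample(grid: np.ndarray) -> np.ndarray:
        img = np.zeros((frame_px, frame_px), dtype=np.uint8)
        step = pmap.grid_step
        vals = np.repeat(np.repeat(grid, step, axis=0), step, axis=1)
        img[: vals.shape[0], : vals.shape[1]] = vals[:frame_px, :frame_px]
        return img

    binary = upsample(np.where(pmap.decisions == 1, 255, 0).astype(np.uint8))
    gray = upsample(
        (np.nan_to_num(pmap.scores, nan=0.0) * 255).round().astype(np.uint8)
    )

    def overlay(base: np.ndarray) -> np.ndarray:
        rgb = np.stack([base] * 3, axis=-1)
        outline = rasterize_scene(
            scene, frame_px=frame_px,
            style=RenderStyle(background=(255, 255, 255), stroke=(0, 0, 0)),
        )
        mask = (outline == 0).all(axis=2)
        rgb[mask] = (255, 0, 0)
        return rgb

    return overlay(binary), overlay(gray)
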