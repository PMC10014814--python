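"""Task dataset assembly: training corpora and generalization sets.

Three binary relation tasks are composed from the geometry primitives:

* ``same_different`` — two amoeboid contours per frame; "Same" frames show
  one library shape twice at independently drawn sizes and positions (no
  rotation), "Different" frames show two distinct library shapes.
* ``enclosure`` — one closed contour among 22 open noise fragments plus a
  red probe marker; the label is whether the probe lies in the closed
  contour's interior.
* ``more_fewer`` — two filled regular polygons with different side counts
  on black; a red dot marks one polygon's centroid and the label is whether
  the dotted polygon has more sides.

Every record stores enough geometry to re-render the image and to recompute
its label from first principles (``recompute_label``), which is the dataset's
self-consistency guarantee: labels are never stored facts that the geometry
cannot verify.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import geometry as geo
from .geometry import (
    Contour,
    RadialContourSpec,
    PolygonSpec,
    RectangleSpec,
    generate_amoeboid,
    generate_regular_polygon,
    generate_rectangle,
    extract_fragment,
    point_in_region,
    distance_to_contour,
    similarity_fit_residual,
    contours_disjoint,
)
from .render import FRAME_PX, RenderStyle, TASK_STYLES, probe_clearance, rasterize_scene, save_png

# class tuples are ordered (negative, positive); the positive class drives
# the score semantics used by the probe sweep (p(inside)).
TASK_CLASSES = {
    "same_different": ("different", "same"),
    "enclosure": ("outside", "inside"),
    "more_fewer": ("fewer", "more"),
}


class PlacementError(RuntimeError):
    """Non-overlapping placement could not be found within the attempt budget."""


class SamplingError(RuntimeError):
    """No valid probe position found within the attempt budget."""


_SEED_CAP = 2**31 - 1


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(_SEED_CAP))


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlacementConstraints:
    """Size/position constraints for placing shapes in a frame.

    Sizes are drawn from ``n_discrete_sizes`` evenly spaced values spanning
    ``size_range`` (fractions of the frame side, applied to the shape's
    longest bounding-box extent).  "Did not touch the image boundary" is
    realized as a ``frame_margin_px`` clearance; non-overlap additionally
    keeps a ``min_gap_px`` gap between outlines.
    """

    size_range: tuple[float, float] = (0.20, 0.30)
    n_discrete_sizes: int = 10
    frame_margin_px: float = 2.0
    require_nonoverlap: bool = True
    min_gap_px: float = 2.0
    max_attempts: int = 200

    def __post_init__(self) -> None:
        lo, hi = self.size_range
        if not 0 < lo <= hi < 1:
            raise ValueError("size_range must satisfy 0 < min <= max < 1")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")

    def size_grid(self) -> np.ndarray:
        lo, hi = self.size_range
        return np.linspace(lo, hi, self.n_discrete_sizes)


@dataclass(frozen=True)
class EnclosureConfig:
    n_fragments: int = 22
    fragment_fraction_range: tuple[float, float] = (0.25, 0.50)
    shape_extent_range: tuple[float, float] = (1 / 6, 1 / 3)  # 16.7%-33.3% of frame
    outside_edge_margin_px: float = 23.0
    n_per_class: int = 1000
    n_control: int = 10
    frame_margin_px: float = 2.0
    max_attempts: int = 2000

    def __post_init__(self) -> None:
        lo, hi = self.fragment_fraction_range
        if not 0 < lo <= hi <= 1:
            raise ValueError("invalid fragment_fraction_range")
        lo, hi = self.shape_extent_range
        if not 0 < lo <= hi < 1:
            raise ValueError("invalid shape_extent_range")


@dataclass
class Placement:
    """Similarity transform placing a canonical library shape into the frame."""

    shape_id: str
    scale: float
    dx: float
    dy: float
    size_frac: float  # longest extent as fraction of frame
    size_px: float  # the same size in pixels (unit-unambiguous audits)


@dataclass
class StimulusRecord:
    image_id: str
    task: str
    phase: str
    label: str
    shape_meta: dict
    probe_xy: Optional[tuple[float, float]] = None
    seed: int = 0
    scene: Optional[list[Contour]] = None  # inline geometry, or ...
    placements: Optional[list[Placement]] = None  # ... library references


@dataclass
class DatasetManifest:
    """Records plus the shared shape library and a generation-config echo."""

    task: str
    phase: str
    records: list[StimulusRecord]
    frame_px: int = FRAME_PX
    config: dict = field(default_factory=dict)
    shape_library: dict[str, Contour] = field(default_factory=dict)

    # -- access -------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.label] = counts.get(r.label, 0) + 1
        return counts

    def scene(self, record: StimulusRecord) -> list[Contour]:
        if record.scene is not None:
            return record.scene
        assert record.placements is not None
        return [
            self.shape_library[p.shape_id].transformed(p.scale, (p.dx, p.dy))
            for p in record.placements
        ]

    def render(self, record: StimulusRecord, style: Optional[RenderStyle] = None) -> np.ndarray:
        style = style or TASK_STYLES[self.task]
        return rasterize_scene(
            self.scene(record), probe=record.probe_xy,
            frame_px=self.frame_px, style=style,
        )

    def labels(self) -> np.ndarray:
        neg, pos = TASK_CLASSES[self.task]
        return np.array([1 if r.label == pos else 0 for r in self.records])

    # -- persistence ---------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "image_id": r.image_id,
                "task": r.task,
                "phase": r.phase,
                "label": r.label,
                "probe_x": r.probe_xy[0] if r.probe_xy else np.nan,
                "probe_y": r.probe_xy[1] if r.probe_xy else np.nan,
                "seed": r.seed,
            }
            for k, v in r.shape_meta.items():
                if np.isscalar(v) or v is None:
                    row[k] = v
            rows.append(row)
        return pd.DataFrame(rows)

    def save(self, outdir, write_images: bool = False,
             style: Optional[RenderStyle] = None) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(outdir / "manifest.csv", index=False)
        payload = {
            "task": self.task,
            "phase": self.phase,
            "frame_px": self.frame_px,
            "config": self.config,
            "shape_library": {k: c.to_dict() for k, c in self.shape_library.items()},
            "records": [
                {
                    "image_id": r.image_id,
                    "task": r.task,
                    "phase": r.phase,
                    "label": r.label,
                    "shape_meta": r.shape_meta,
                    "probe_xy": list(r.probe_xy) if r.probe_xy else None,
                    "seed": r.seed,
                    "scene": [c.to_dict() for c in r.scene] if r.scene else None,
                    "placements": [asdict(p) for p in r.placements]
                    if r.placements
                    else None,
                }
                for r in self.records
            ],
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(payload, fh)
        if write_images:
            for r in self.records:
                img_dir = outdir / self.task / self.phase / r.label
                img_dir.mkdir(parents=True, exist_ok=True)
                save_png(self.render(r, style), img_dir / f"{r.image_id}.png")
        return outdir

    @classmethod
    def load(cls, outdir) -> "DatasetManifest":
        with open(Path(outdir) / "manifest.json") as fh:
            payload = json.load(fh)
        records = [
            StimulusRecord(
                image_id=d["image_id"],
                task=d["task"],
                phase=d["phase"],
                label=d["label"],
                shape_meta=d["shape_meta"],
                probe_xy=tuple(d["probe_xy"]) if d["probe_xy"] else None,
                seed=d["seed"],
                scene=[Contour.from_dict(c) for c in d["scene"]]
                if d["scene"]
                else None,
                placements=[Placement(**p) for p in d["placements"]]
                if d["placements"]
                else None,
            )
            for d in payload["records"]
        ]
        return cls(
            task=payload["task"],
            phase=payload["phase"],
            records=records,
            frame_px=payload["frame_px"],
            config=payload["config"],
            shape_library={
                k: Contour.from_dict(c) for k, c in payload["shape_library"].items()
            },
        )


# ---------------------------------------------------------------------------
# canonical shapes and placement
# ---------------------------------------------------------------------------


def canonical_amoeboid(seed: int, n_control: int = 10,
                       perturbation_range: float = 0.3,
                       shape_id: Optional[str] = None) -> Contour:
    """Amoeboid centered on its vertex mean with unit longest bbox extent."""
    c = generate_amoeboid(
        RadialContourSpec(
            n_control=n_control, perturbation_range=perturbation_range, seed=seed
        ),
        shape_id=shape_id,
    )
    v = c.vertices - c.vertices.mean(axis=0)
    v /= max(np.ptp(v[:, 0]), np.ptp(v[:, 1]))
    c.vertices = v
    return c


def canonical_square(shape_id: Optional[str] = None) -> Contour:
    verts = 0.5 * np.array([[-1.0, -1.0], [1.0, -1.0], [1.0, 1.0], [-1.0, 1.0]])
    return Contour(verts, closed=True, shape_id=shape_id)


def _random_offset(contour: Contour, frame_px: int, margin: float,
                   rng: np.random.Generator) -> Optional[np.ndarray]:
    x0, y0, x1, y1 = contour.bbox()
    lo_x, hi_x = margin - x0, frame_px - margin - x1
    lo_y, hi_y = margin - y0, frame_px - margin - y1
    if hi_x < lo_x or hi_y < lo_y:
        return None
    return np.array([rng.uniform(lo_x, hi_x), rng.uniform(lo_y, hi_y)])


def place_nonoverlapping(
    contours: Sequence[Contour],
    constraints: PlacementConstraints,
    rng: np.random.Generator,
    frame_px: int = FRAME_PX,
    sizes_px: Optional[Sequence[float]] = None,
) -> tuple[list[Placement], list[Contour]]:
    """Scale canonical shapes (unit longest extent) and place them disjointly.

    Sizes come from the constraint's discrete grid unless ``sizes_px`` gives
    explicit pixel extents.  The whole scene is re-drawn on conflict, up to
    ``max_attempts`` times.
    """
    grid = constraints.size_grid()
    for _ in range(constraints.max_attempts):
        placed: list[Contour] = []
        placements: list[Placement] = []
        ok = True
        for i, c in enumerate(contours):
            if sizes_px is not None:
                size_px = float(sizes_px[i])
            else:
                size_px = float(rng.choice(grid)) * frame_px
            scale = size_px / c.bbox_extent()
            scaled = c.transformed(scale)
            off = _random_offset(scaled, frame_px, constraints.frame_margin_px, rng)
            if off is None:
                ok = False
                break
            cand = scaled.transformed(1.0, off)
            if constraints.require_nonoverlap and any(
                not contours_disjoint(cand, p, constraints.min_gap_px) for p in placed
            ):
                ok = False
                break
            placed.append(cand)
            placements.append(
                Placement(
                    shape_id=c.shape_id or f"shape{i}",
                    scale=scale,
                    dx=float(off[0]),
                    dy=float(off[1]),
                    size_frac=size_px / frame_px,
                    size_px=size_px,
                )
            )
        if ok:
            return placements, placed
    raise PlacementError(
        f"no non-overlapping placement after {constraints.max_attempts} attempts"
    )


def sample_probe(
    region: str,
    closed: Contour,
    frame_px: int,
    config: EnclosureConfig,
    rng: np.random.Generator,
    clearance: float,
    max_attempts: Optional[int] = None,
) -> tuple[float, float]:
    """Draw a probe-marker center inside or outside a placed closed contour.

    ``inside`` positions keep ``clearance`` away from the contour so the
    marker cannot touch the border; ``outside`` positions additionally keep
    ``outside_edge_margin_px`` from every frame edge.
    """
    if region not in ("inside", "outside"):
        raise ValueError(f"unknown region {region!r}")
    attempts = max_attempts or config.max_attempts
    x0, y0, x1, y1 = closed.bbox()
    for _ in range(attempts):
        if region == "inside":
            p = np.array([rng.uniform(x0, x1), rng.uniform(y0, y1)])
            if not point_in_region(p, closed):
                continue
        else:
            m = max(config.outside_edge_margin_px, clearance)
            p = np.array(
                [rng.uniform(m, frame_px - m), rng.uniform(m, frame_px - m)]
            )
            if point_in_region(p, closed):
                continue
        if distance_to_contour(p, closed) > clearance:
            return float(p[0]), float(p[1])
    raise SamplingError(f"no valid {region} probe position after {attempts} attempts")


# ---------------------------------------------------------------------------
# same-different
# ---------------------------------------------------------------------------


def _interleaved_labels(task: str, n_per_class: int) -> list[str]:
    neg, pos = TASK_CLASSES[task]
    return [pos, neg] * n_per_class


def make_shape_library(n_shapes: int, rng: np.random.Generator,
                       prefix: str = "train", n_control: int = 10) -> dict[str, Contour]:
    return {
        f"{prefix}{i:02d}": canonical_amoeboid(
            _child_seed(rng), n_control=n_control, shape_id=f"{prefix}{i:02d}"
        )
        for i in range(n_shapes)
    }


def build_same_different_train(
    n_shapes: int = 20,
    n_per_class: int = 10_000,
    constraints: PlacementConstraints = PlacementConstraints(),
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
    frame_px: int = FRAME_PX,
    phase: str = "train",
    library: Optional[dict[str, Contour]] = None,
) -> DatasetManifest:
    """Same-different training corpus: pairs of library amoeboids."""
    if n_shapes < 2:
        raise ValueError("need at least 2 library shapes")
    rng = rng or np.random.default_rng(seed)
    library = library or make_shape_library(n_shapes, rng)
    ids = list(library)
    records = []
    for i, label in enumerate(_interleaved_labels("same_different", n_per_class)):
        rec_seed = _child_seed(rng)
        rec_rng = np.random.default_rng(rec_seed)
        if label == "same":
            a = b = ids[rec_rng.integers(len(ids))]
        else:
            a, b = rec_rng.choice(len(ids), size=2, replace=False)
            a, b = ids[a], ids[b]
        placements, _ = place_nonoverlapping(
            [library[a], library[b]], constraints, rec_rng, frame_px
        )
        records.append(
            StimulusRecord(
                image_id=f"sd_{phase}_{i:05d}",
                task="same_different",
                phase=phase,
                label=label,
                shape_meta={
                    "shape_id_a": a,
                    "shape_id_b": b,
                    "size_frac_a": placements[0].size_frac,
                    "size_frac_b": placements[1].size_frac,
                    "size_px_a": placements[0].size_px,
                    "size_px_b": placements[1].size_px,
                },
                seed=rec_seed,
                placements=placements,
            )
        )
    return DatasetManifest(
        task="same_different",
        phase=phase,
        records=records,
        frame_px=frame_px,
        config={
            "n_shapes": n_shapes,
            "n_per_class": n_per_class,
            "constraints": asdict(constraints),
            "seed": seed,
        },
        shape_library=library,
    )


def build_same_different_generalization(
    kind: str,
    n_per_class: int = 30,
    constraints: PlacementConstraints = PlacementConstraints(),
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
    frame_px: int = FRAME_PX,
    n_new_shapes: int = 30,
    min_aspect_gap: float = 0.1,
) -> DatasetManifest:
    """Generalization sets: fresh amoeboids, or axis-aligned rectangle pairs."""
    rng = rng or np.random.default_rng(seed)
    if kind == "new_amoeboids":
        library = make_shape_library(n_new_shapes, rng, prefix="gen")
        return build_same_different_train(
            n_shapes=n_new_shapes,
            n_per_class=n_per_class,
            constraints=constraints,
            rng=rng,
            frame_px=frame_px,
            phase="gen_new_amoeboids",
            library=library,
        )
    if kind != "rectangles":
        raise ValueError(f"unknown generalization kind {kind!r}")

    lo_a, hi_a = geo.RECT_ASPECT_BOUNDS
    records = []
    for i, label in enumerate(_interleaved_labels("same_different", n_per_class)):
        rec_seed = _child_seed(rng)
        rec_rng = np.random.default_rng(rec_seed)
        a1 = rec_rng.uniform(lo_a, hi_a)
        if label == "same":
            a2 = a1
        else:
            while True:
                a2 = rec_rng.uniform(lo_a, hi_a)
                if abs(a2 - a1) >= min_aspect_gap:
                    break
        rects = [
            generate_rectangle(RectangleSpec(a, 1.0), shape_id=f"rect_{a:.6f}")
            for a in (a1, a2)
        ]
        # canonical rectangles have unit principal axis == unit bbox extent
        placements, _ = place_nonoverlapping(rects, constraints, rec_rng, frame_px)
        records.append(
            StimulusRecord(
                image_id=f"sd_gen_rect_{i:05d}",
                task="same_different",
                phase="gen_rectangles",
                label=label,
                shape_meta={
                    "aspect_a": a1,
                    "aspect_b": a2,
                    "size_frac_a": placements[0].size_frac,
                    "size_frac_b": placements[1].size_frac,
                },
                seed=rec_seed,
                scene=[
                    r.transformed(p.scale, (p.dx, p.dy))
                    for r, p in zip(rects, placements)
                ],
            )
        )
    return DatasetManifest(
        task="same_different",
        phase="gen_rectangles",
        records=records,
        frame_px=frame_px,
        config={"kind": kind, "n_per_class": n_per_class, "seed": seed},
    )


# ---------------------------------------------------------------------------
# enclosure
# ---------------------------------------------------------------------------


def _place_fragment(
    frag: Contour,
    frame_px: int,
    margin: float,
    probe: np.ndarray,
    clearance: float,
    rng: np.random.Generator,
    max_attempts: int,
) -> Contour:
    for _ in range(max_attempts):
        off = _random_offset(frag, frame_px, margin, rng)
        if off is None:
            raise PlacementError("fragment larger than frame")
        cand = frag.transformed(1.0, off)
        if distance_to_contour(probe, cand) > clearance:
            return cand
    raise PlacementError("fragment placement kept hitting the probe marker")


def _build_enclosure_record(
    i: int,
    label: str,
    phase: str,
    config: EnclosureConfig,
    rng: np.random.Generator,
    frame_px: int,
    style: RenderStyle,
    kind: str = "train",
) -> StimulusRecord:
    rec_seed = _child_seed(rng)
    rec_rng = np.random.default_rng(rec_seed)
    lo, hi = config.shape_extent_range
    clearance = probe_clearance(style)

    def closed_shape() -> Contour:
        if kind == "squares":
            base = canonical_square(shape_id=f"sq_{i}")
        else:
            base = canonical_amoeboid(
                _child_seed(rec_rng), n_control=config.n_control,
                shape_id=f"amoeboid_{phase}_{i}",
            )
        if kind == "big_contour":
            extent = 0.80 * frame_px
        else:
            extent = rec_rng.uniform(lo, hi) * frame_px
        return base.transformed(extent / base.bbox_extent())

    def fragment_parent() -> Contour:
        if kind == "squares":
            base = canonical_square()
        else:
            base = canonical_amoeboid(
                _child_seed(rec_rng), n_control=config.n_control
            )
        # fragment parents sized like the training closed contours
        extent = rec_rng.uniform(lo, hi) * frame_px
        return base.transformed(extent / base.bbox_extent())

    for _ in range(20):  # outer retries for probe-sampling dead ends
        shape = closed_shape()
        off = _random_offset(shape, frame_px, config.frame_margin_px, rec_rng)
        if off is None:
            continue
        shape = shape.transformed(1.0, off)
        try:
            probe = sample_probe(label, shape, frame_px, config, rec_rng, clearance)
        except SamplingError:
            continue
        probe_arr = np.asarray(probe)
        fragments = []
        for j in range(config.n_fragments):
            parent = fragment_parent()
            frac = rec_rng.uniform(*config.fragment_fraction_range)
            frag = extract_fragment(
                parent, frac, rec_rng.uniform(), fragment_id=f"frag_{i}_{j}"
            )
            fragments.append(
                _place_fragment(
                    frag, frame_px, config.frame_margin_px, probe_arr,
                    clearance, rec_rng, config.max_attempts,
                )
            )
        return StimulusRecord(
            image_id=f"enc_{phase}_{i:05d}",
            task="enclosure",
            phase=phase,
            label=label,
            shape_meta={
                "closed_extent_px": shape.bbox_extent(),
                "closed_extent_frac": shape.bbox_extent() / frame_px,
                "n_fragments": config.n_fragments,
                "probe_contour_dist_px": distance_to_contour(probe_arr, shape),
            },
            probe_xy=probe,
            seed=rec_seed,
            scene=[shape] + fragments,
        )
    raise SamplingError(f"could not build enclosure record {i} ({label})")


def build_enclosure_train(
    config: EnclosureConfig = EnclosureConfig(),
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
    frame_px: int = FRAME_PX,
    phase: str = "train",
    kind: str = "train",
) -> DatasetManifest:
    """Inside/outside corpus: one closed contour + open fragments + red probe."""
    rng = rng or np.random.default_rng(seed)
    style = TASK_STYLES["enclosure"]
    records = [
        _build_enclosure_record(i, label, phase, config, rng, frame_px, style, kind)
        for i, label in enumerate(_interleaved_labels("enclosure", config.n_per_class))
    ]
    return DatasetManifest(
        task="enclosure",
        phase=phase,
        records=records,
        frame_px=frame_px,
        config={"enclosure": asdict(config), "seed": seed, "kind": kind},
    )


def build_enclosure_generalization(
    kind: str,
    n_per_class: int = 30,
    config: EnclosureConfig = EnclosureConfig(),
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
    frame_px: int = FRAME_PX,
) -> DatasetManifest:
    """Generalization sets: 16-control-point shapes, squares, or an 80%-frame contour."""
    if kind not in ("cp16", "squares", "big_contour"):
        raise ValueError(f"unknown generalization kind {kind!r}")
    cfg = EnclosureConfig(
        **{
            **asdict(config),
            "n_per_class": n_per_class,
            "n_control": 16 if kind == "cp16" else config.n_control,
        }
    )
    return build_enclosure_train(
        cfg, rng=rng, seed=seed, frame_px=frame_px, phase=f"gen_{kind}", kind=kind
    )


# ---------------------------------------------------------------------------
# more-fewer
# ---------------------------------------------------------------------------

POLYGON_EXTENT_RANGE = (22.0, 42.0)  # admissible longest vertex-to-vertex, px


def build_more_fewer(
    sides_set: Sequence[int] = (3, 4, 5),
    n_per_class: int = 10_000,
    constraints: PlacementConstraints = PlacementConstraints(min_gap_px=2.0),
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
    frame_px: int = FRAME_PX,
    phase: Optional[str] = None,
    extent_range: tuple[float, float] = POLYGON_EXTENT_RANGE,
) -> DatasetManifest:
    """More-fewer corpus: two filled regular polygons, red dot on one centroid."""
    sides_set = sorted(set(int(s) for s in sides_set))
    if len(sides_set) < 2:
        raise ValueError("sides_set needs at least 2 distinct values")
    rng = rng or np.random.default_rng(seed)
    phase = phase or ("train" if max(sides_set) <= 5 else "gen_doubled")
    records = []
    for i, label in enumerate(_interleaved_labels("more_fewer", n_per_class)):
        rec_seed = _child_seed(rng)
        rec_rng = np.random.default_rng(rec_seed)
        n1, n2 = rec_rng.choice(len(sides_set), size=2, replace=False)
        n1, n2 = sides_set[n1], sides_set[n2]
        extents = [float(rec_rng.uniform(*extent_range)) for _ in range(2)]
        polys = [
            generate_regular_polygon(
                PolygonSpec(n, ext, float(rec_rng.uniform(0.0, 360.0))),
                admissible_extent=extent_range,
                shape_id=f"poly{n}",
            )
            for n, ext in zip((n1, n2), extents)
        ]
        # preserve the generated scale: placement only translates
        placements, placed = place_nonoverlapping(
            [p.transformed(1.0 / p.bbox_extent()) for p in polys],
            constraints, rec_rng, frame_px,
            sizes_px=[p.bbox_extent() for p in polys],
        )
        dotted = 0 if (label == "more") == (n1 > n2) else 1
        probe = placed[dotted].centroid()
        records.append(
            StimulusRecord(
                image_id=f"mf_{phase}_{i:05d}",
                task="more_fewer",
                phase=phase,
                label=label,
                shape_meta={
                    "n_sides_dotted": (n1, n2)[dotted],
                    "n_sides_other": (n1, n2)[1 - dotted],
                    "extent_px_dotted": extents[dotted],
                    "extent_px_other": extents[1 - dotted],
                },
                probe_xy=(float(probe[0]), float(probe[1])),
                seed=rec_seed,
                scene=placed,
            )
        )
    return DatasetManifest(
        task="more_fewer",
        phase=phase,
        records=records,
        frame_px=frame_px,
        config={
            "sides_set": sides_set,
            "n_per_class": n_per_class,
            "extent_range": list(extent_range),
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# ground-truth recomputation
# ---------------------------------------------------------------------------

SAME_RESIDUAL_THRESHOLD = 1e-3  # of the frame side


def recompute_label(record: StimulusRecord, manifest: DatasetManifest) -> str:
    """Recompute a record's label from its geometry alone.

    This is the machine-checkable self-consistency of the ground truth: the
    defining relation (similarity, enclosure, side-count comparison) is
    evaluated with the geometry predicates, never read off stored metadata.
    """
    scene = manifest.scene(record)
    task = record.task
    if task == "same_different":
        resid = similarity_fit_residual(scene[0], scene[1])
        return (
            "same"
            if resid < SAME_RESIDUAL_THRESHOLD * manifest.frame_px
            else "different"
        )
    if task == "enclosure":
        closed = next(c for c in scene if c.closed)
        return "inside" if point_in_region(record.probe_xy, closed) else "outside"
    if task == "more_fewer":
        probe = np.asarray(record.probe_xy)
        dists = [np.linalg.norm(c.centroid() - probe) for c in scene]
        dotted = int(np.argmin(dists))
        return (
            "more"
            if scene[dotted].n_vertices > scene[1 - dotted].n_vertices
            else "fewer"
        )
    raise ValueError(f"unknown task {task!r}")
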