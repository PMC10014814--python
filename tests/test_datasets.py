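"""Dataset composition: placement, probes, labels, balance, determinism."""

import numpy as np
import pytest
from scipy import stats as sps

from relbench.datasets import (
    EnclosureConfig,
    PlacementConstraints,
    PlacementError,
    SamplingError,
    build_enclosure_generalization,
    build_enclosure_train,
    build_more_fewer,
    build_same_different_generalization,
    build_same_different_train,
    canonical_amoeboid,
    place_nonoverlapping,
    recompute_label,
    sample_probe,
)
from relbench.geometry import (
    Contour,
    distance_to_contour,
    point_in_region,
    segments_intersect,
    similarity_fit_residual,
)
from relbench.render import OUTLINE_STYLE, probe_clearance


def brute_force_disjoint(a: Contour, b: Contour) -> bool:
    """Oracle: exhaustive edge-pair intersection + containment check."""
    for s1 in a.edges():
        for s2 in b.edges():
            if segments_intersect(s1[0], s1[1], s2[0], s2[1]):
                return False
    if a.closed and point_in_region(b.vertices[0], a):
        return False
    if b.closed and point_in_region(a.vertices[0], b):
        return False
    return True


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------


def test_single_shape_inside_margin(rng):
    shape = canonical_amoeboid(1)
    constraints = PlacementConstraints(frame_margin_px=2.0)
    _, placed = place_nonoverlapping([shape], constraints, rng)
    x0, y0, x1, y1 = placed[0].bbox()
    assert x0 >= 2.0 and y0 >= 2.0 and x1 <= 225.0 and y1 <= 225.0


def test_placed_pairs_disjoint_by_brute_force(rng):
    shapes = [canonical_amoeboid(i) for i in (2, 3)]
    constraints = PlacementConstraints()
    for _ in range(25):
        _, placed = place_nonoverlapping(shapes, constraints, rng)
        assert brute_force_disjoint(placed[0], placed[1])


def test_impossible_placement_fails(rng):
    shapes = [canonical_amoeboid(i) for i in (2, 3)]
    constraints = PlacementConstraints(
        size_range=(0.9, 0.95), n_discrete_sizes=2, max_attempts=20
    )
    with pytest.raises(PlacementError):
        place_nonoverlapping(shapes, constraints, rng)


# ---------------------------------------------------------------------------
# same-different
# ---------------------------------------------------------------------------


def test_sd_counts_and_balance(sd_small):
    assert sd_small.class_counts() == {"same": 30, "different": 30}


def test_sd_same_pairs_similarity_aligned(sd_small):
    for rec in sd_small.records:
        scene = sd_small.scene(rec)
        resid = similarity_fit_residual(scene[0], scene[1])
        if rec.label == "same":
            assert resid < 1e-3 * sd_small.frame_px
        else:
            assert resid > 1e-3 * sd_small.frame_px


def test_sd_sizes_come_from_ten_value_grid(sd_small):
    sizes = {
        round(s, 9)
        for rec in sd_small.records
        for s in (rec.shape_meta["size_frac_a"], rec.shape_meta["size_frac_b"])
    }
    grid = {round(v, 9) for v in np.linspace(0.20, 0.30, 10)}
    assert sizes <= grid
    assert len(sizes) > 5  # the grid is actually exercised


def test_sd_generalization_library_disjoint():
    gen = build_same_different_generalization("new_amoeboids", n_per_class=5, seed=9)
    train = build_same_different_train(n_per_class=5, seed=9)
    assert not (set(gen.shape_library) & set(train.shape_library))


def test_sd_rectangle_pairs_aspects():
    gen = build_same_different_generalization("rectangles", n_per_class=10, seed=4)
    assert gen.class_counts() == {"same": 10, "different": 10}
    for rec in gen.records:
        a, b = rec.shape_meta["aspect_a"], rec.shape_meta["aspect_b"]
        if rec.label == "same":
            assert abs(a - b) < 1e-6
        else:
            assert abs(a - b) > 1e-6


def test_sd_no_trivial_size_position_cue():
    """Size/position marginals should not separate the classes."""
    m = build_same_different_train(n_per_class=300, seed=77)
    df = m.to_dataframe()
    same = df[df.label == "same"]
    diff = df[df.label == "different"]
    for col in ("size_frac_a", "size_frac_b"):
        p = sps.ks_2samp(same[col], diff[col]).pvalue
        assert p > 0.01


def test_sd_regeneration_is_identical():
    a = build_same_different_train(n_per_class=5, seed=123)
    b = build_same_different_train(n_per_class=5, seed=123)
    for ra, rb in zip(a.records, b.records):
        assert ra.image_id == rb.image_id and ra.label == rb.label
        for ca, cb in zip(a.scene(ra), b.scene(rb)):
            assert np.array_equal(ca.vertices, cb.vertices)
    assert np.array_equal(a.render(a.records[0]), b.render(b.records[0]))


# ---------------------------------------------------------------------------
# probes
# ---------------------------------------------------------------------------


def test_probe_inside_region(rng):
    shape = canonical_amoeboid(10).transformed(70.0, (113, 113))
    cfg = EnclosureConfig()
    clearance = probe_clearance(OUTLINE_STYLE)
    p = sample_probe("inside", shape, 227, cfg, rng, clearance)
    assert point_in_region(p, shape)
    assert distance_to_contour(p, shape) > clearance


def test_probe_outside_margin(rng):
    shape = canonical_amoeboid(11).transformed(70.0, (113, 113))
    cfg = EnclosureConfig()
    clearance = probe_clearance(OUTLINE_STYLE)
    for _ in range(25):
        p = sample_probe("outside", shape, 227, cfg, rng, clearance)
        assert not point_in_region(p, shape)
        assert min(p[0], p[1], 227 - p[0], 227 - p[1]) >= 23.0


def test_probe_infeasible_sliver(rng):
    # a long thin closed sliver: interior thinner than the probe everywhere
    t = np.linspace(0, 1, 50)
    top = np.column_stack([20 + 180 * t, 100 + 0.5 * np.sin(6 * t)])
    bottom = np.column_stack([200 - 180 * t, 101.5 + 0.5 * np.sin(6 * t)])
    sliver = Contour(np.vstack([top, bottom]), closed=True)
    cfg = EnclosureConfig(max_attempts=200)
    with pytest.raises(SamplingError):
        sample_probe("inside", sliver, 227, cfg, rng, probe_clearance(OUTLINE_STYLE))


# ---------------------------------------------------------------------------
# enclosure corpora
# ---------------------------------------------------------------------------


def test_enclosure_structure_and_labels(enclosure_small):
    assert enclosure_small.class_counts() == {"inside": 8, "outside": 8}
    for rec in enclosure_small.records:
        scene = enclosure_small.scene(rec)
        assert sum(c.closed for c in scene) == 1
        assert sum(not c.closed for c in scene) == 22
        closed = next(c for c in scene if c.closed)
        assert (rec.label == "inside") == point_in_region(rec.probe_xy, closed)
        assert 1 / 6 <= rec.shape_meta["closed_extent_frac"] <= 1 / 3 + 1e-9


def test_enclosure_fragments_clear_probe(enclosure_small):
    clearance = probe_clearance(OUTLINE_STYLE)
    for rec in enclosure_small.records:
        for frag in enclosure_small.scene(rec):
            if not frag.closed:
                assert distance_to_contour(rec.probe_xy, frag) > clearance


def test_enclosure_generalization_squares():
    gen = build_enclosure_generalization("squares", n_per_class=3, seed=31)
    for rec in gen.records:
        closed = next(c for c in gen.scene(rec) if c.closed)
        assert closed.n_vertices == 4
        # four right angles
        v = closed.vertices
        for i in range(4):
            e1 = v[(i + 1) % 4] - v[i]
            e2 = v[(i + 2) % 4] - v[(i + 1) % 4]
            assert abs(e1 @ e2) < 1e-6


def test_enclosure_generalization_big_contour():
    gen = build_enclosure_generalization("big_contour", n_per_class=3, seed=32)
    for rec in gen.records:
        closed = next(c for c in gen.scene(rec) if c.closed)
        assert abs(closed.bbox_extent() / gen.frame_px - 0.80) < 0.01


def test_enclosure_generalization_cp16_zero_perturbation_limit():
    from relbench.geometry import RadialContourSpec, generate_amoeboid

    c = generate_amoeboid(RadialContourSpec(n_control=16, perturbation_range=0.0, seed=5))
    radii = np.linalg.norm(c.vertices, axis=1)
    assert np.allclose(radii, radii[0], atol=1e-6)


# ---------------------------------------------------------------------------
# more-fewer corpora
# ---------------------------------------------------------------------------


def test_more_fewer_structure(more_fewer_small):
    assert more_fewer_small.class_counts() == {"more": 30, "fewer": 30}
    for rec in more_fewer_small.records:
        meta = rec.shape_meta
        assert meta["n_sides_dotted"] != meta["n_sides_other"]
        assert 22.0 <= meta["extent_px_dotted"] <= 42.0
        assert 22.0 <= meta["extent_px_other"] <= 42.0


def test_more_fewer_doubled_sides_set():
    gen = build_more_fewer(sides_set=(6, 8, 10), n_per_class=10, seed=41)
    counts = {rec.shape_meta["n_sides_dotted"] for rec in gen.records}
    assert counts <= {6, 8, 10}
    assert gen.phase == "gen_doubled"


def test_more_fewer_polygons_disjoint(more_fewer_small):
    for rec in more_fewer_small.records[:20]:
        a, b = more_fewer_small.scene(rec)
        assert brute_force_disjoint(a, b)


# ---------------------------------------------------------------------------
# ground-truth self-consistency and persistence
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "fixture", ["sd_small", "enclosure_small", "more_fewer_small"]
)
def test_labels_recomputable_from_geometry(fixture, request):
    manifest = request.getfixturevalue(fixture)
    for rec in manifest.records:
        assert recompute_label(rec, manifest) == rec.label


def test_manifest_roundtrip(tmp_path, more_fewer_small):
    from relbench.datasets import DatasetManifest

    more_fewer_small.save(tmp_path / "mf", write_images=True)
    loaded = DatasetManifest.load(tmp_path / "mf")
    assert len(loaded) == len(more_fewer_small)
    assert loaded.class_counts() == more_fewer_small.class_counts()
    rec0 = loaded.records[0]
    assert recompute_label(rec0, loaded) == rec0.label
    # one image file per record, in task/phase/label layout
    pngs = list((tmp_path / "mf").rglob("*.png"))
    assert len(pngs) == len(more_fewer_small)
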