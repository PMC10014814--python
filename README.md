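# relbench

Synthetic benchmarks for **abstract visual relations** — and the machinery to
test whether a learner actually acquired the relation or merely memorized its
concrete instances.

Human observers learn rules like *"these two shapes are the same"*, *"the dot
is inside the closed figure"*, or *"the dot is on the polygon with more
sides"* within a few dozen feedback trials, and then apply them to stimuli
they have never seen. Standard convolutional classifiers can often be trained
to high accuracy on such tasks, yet collapse toward chance the moment the
surface features change — the signature of *conjunctive* learning, where the
relation is bound to its concrete argument fillers. This package builds the
three tasks, the generalization probes that expose the dissociation, and the
behavioral statistics to quantify it, for researchers in visual cognition and
machine-learning evaluation.

## The three tasks

All stimuli are generated programmatically into 227 × 227 RGB frames with a
per-image manifest that stores the full geometry, so every label can be
recomputed (and audited) from first principles.

| Task | Display | Relation |
|---|---|---|
| `same_different` | two smooth closed contours ("amoeboids": radially jittered control points interpolated by a periodic cubic spline) | same shape twice vs. two different shapes, invariant to position and size |
| `enclosure` | one closed contour among 22 open contour fragments + a red probe | probe inside vs. outside the closed region |
| `more_fewer` | two filled regular polygons, red dot on one centroid | dotted polygon has more vs. fewer sides |

Each task ships its generalization sets: novel amoeboids and rectangle pairs
(same–different); 16-control-point shapes, squares, and an 80 %-of-frame
contour (enclosure); polygons with doubled side counts, {6, 8, 10} replacing
{3, 4, 5} (more–fewer).

## What the library provides

- `relbench.geometry` / `relbench.render` — contour primitives (splines,
  polygons, fragments, turning angle, ray-cast point-in-region) and crisp,
  deterministic rasterization.
- `relbench.datasets` — corpus builders with all placement constraints
  (non-overlap, frame margins, 10 discrete sizes at 20–30 % of frame,
  outside-probes ≥ 23 px from edges, …) and self-consistent manifests.
- `relbench.training` — transfer-learning harness: stratified splits,
  per-epoch validation with the six-consecutive-increases stopping rule,
  *restricted* (readout-only, features bit-frozen) and *unrestricted* modes.
  The reference backend is a compact numpy CNN trainable from scratch on one
  CPU; external models plug in through the same contract.
- `relbench.probe` — decision maps: classify a scene at every probe position
  and render binary/graded panels.
- `relbench.observers` / `relbench.analysis` — simulated relational and
  conjunctive observers, and the blocked behavioral statistics (50-trial
  blocks, one-sample and paired t-tests) applied identically to simulated,
  human, or network response logs.
- `relbench.studies` — the packaged desk-scale dissociation studies.
- `relbench` CLI — `gen`, `train`, `eval`, `sweep`, `simulate`, `report`,
  `run` (full experiment from a YAML config).

## Worked example

`python examples/04_simulated_observers.py` runs two six-subject cohorts
through the same–different design (150 feedback trials, then 40 novel-shape
trials) and prints:

```
relational cohort (n=6):
  learning blocks (prop ± SEM): 0.73±0.02 0.99±0.00 0.99±0.00
  novel-shape generalization:   0.99
  block-3 vs generalization:    t(5) = -0.09, p = 0.9304

conjunctive cohort (n=6):
  learning blocks (prop ± SEM): 0.58±0.02 0.74±0.02 0.79±0.02
  novel-shape generalization:   0.49
  block-3 vs generalization:    t(5) = 8.24, p = 0.0004
```

Both cohorts learn; only the relational observer transfers. The conjunctive
observer — which memorizes shape-pair → label bindings — is at chance on
shapes it has never seen, and the paired block-3 vs generalization test
flags the drop. The other examples generate stimuli (`01`), train the CNN
and show the validation/generalization gap (`02`), draw probe decision maps
(`03`), and run a full experiment end-to-end (`05`).

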