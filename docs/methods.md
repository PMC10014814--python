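# Methods

This note records the models, parameter choices, and numerical decisions
behind the package, and what its tests do and do not establish.

## Stimulus geometry

**Amoeboid contours.** A shape is defined by `n_control` control points at
uniform angular spacing on a circle of radius `base_radius`, each moved
radially by a factor drawn uniformly from `1 ± perturbation_range`. A
*periodic cubic spline of radius over angle* interpolates the control-point
radii; sampling it at `samples_per_segment` points per segment (default 12)
yields the vertex chain. Interpolating the radius rather than Cartesian
coordinates follows directly from the generative idea — control points move
only toward or away from the center — and has two useful consequences: the
zero-perturbation limit is an exact circle, and the contour is star-shaped
about its center, so it can never self-intersect while the interpolated
radius stays positive (a rejection loop guards the spline-overshoot corner
case at extreme perturbations). The perturbation magnitude is not dictated
by the task definition; the default 0.3 produces visibly irregular but
simple shapes and is exposed in the spec object.

**Fragments.** Open noise fragments are contiguous arcs cut from a closed
parent at a uniformly drawn start phase, covering a requested fraction
(0.25–0.50) of the parent's perimeter, with endpoints interpolated exactly
on the parent polyline.

**Polygons.** Regular polygons are placed on a circumcircle sized so that
the *longest vertex-to-vertex distance* equals the requested extent. "Length"
of a polygon is ambiguous between side length and overall extent; we read it
as overall extent, which keeps triangles and decagons visually comparable at
the same nominal size. Admissible extents are 22–42 px.

**Coordinates.** 0-based raster convention: x rightward, y downward,
sub-pixel floats, pixel centers at integer + 0.5.

## Rendering

Scenes are drawn with PIL without anti-aliasing so that pixel-level oracles
(flood fill, connected components) are exact. Outline tasks: black 2-px
strokes on white, probe = filled red square of side 5 px (marker shape and
stroke parameters are not dictated by the task; both are style options).
The polygon task: filled white polygons on black, probe = filled red dot of
diameter 5 px. A probe "touches" nothing when its center is farther from any
contour than half the marker diagonal plus half the stroke width plus 1 px
(`probe_clearance`).

## Dataset composition

Placement draws sizes from 10 evenly spaced values spanning 20–30 % of the
frame (same–different), positions uniformly such that shapes keep a 2-px
margin from the frame ("did not touch the boundary"; the exact margin is a
config value), and redraws the whole scene if closed shapes come within
2 px of each other (non-overlap, checked with shapely and audited in tests
by brute-force edge intersection). "Same" pairs differ by translation and
uniform scale only — no rotation — and the similarity-fit residual under a
closed-form scale+translation least-squares alignment is the machine check
of that definition (threshold 10⁻³ of the frame side). Enclosure images
carry exactly one closed contour (extent uniform in 16.7–33.3 % of frame,
or fixed 80 % in the big-contour set) plus 22 fragments; fragments may
overlap anything except the probe marker. Outside probes stay ≥ 23 px from
every frame edge. Rectangle "Different" pairs must differ in aspect by at
least 0.1 so the two classes are visually distinct; all rectangles are
axis-aligned (whether the original design rotated them is ambiguous;
rotation is left to a config option). Polygons in the more–fewer task are
placed without overlap, since merging white fills would corrupt the side
counts, and the red dot sits exactly on the dotted polygon's vertex
centroid.

Every record stores its full geometry (or a library reference plus
transform), so `recompute_label` can re-derive the label from the defining
relation alone; the test suite asserts 100 % agreement. Identical config +
seed reproduces manifests and rasters bit-for-bit.

## Transfer-learning harness

Training uses minibatch SGD (optional classical momentum; default none) with
a fixed learning rate, per-epoch validation checks, and stops at the first
of `max_epochs` or `patience` (default 6) *consecutive strict increases* of
validation error relative to the immediately preceding check. The final-
epoch model is returned; there is no best-checkpoint restoration. Restricted
mode updates only the readout layer and is audited by hashing all non-readout
parameters before and after training.

**Reference backend.** `SmallCNN` is a compact convolutional classifier
implemented in numpy with explicit backpropagation: 5×5/stride-2 conv (12
ch) → leaky ReLU (slope 0.1) → 2×2 max-pool → 3×3 conv (24 ch) → leaky ReLU
→ 2×2 max-pool → 3×3 conv (32 ch) → leaky ReLU → global average pooling →
2-way softmax readout, consuming 56×56 bilinear-resized inputs centered to
[−0.5, 0.5]. The translation-invariant pooled head is the load-bearing
choice: with a flattened fully connected head the same stack memorizes
position-specific patterns (training error → 0, validation at chance),
whereas pooled local detectors must generalize within the training
distribution. Leaky ReLU keeps small from-scratch nets trainable; a global
gradient-norm clip (default 1.0) prevents the occasional destructive loss
spikes of long momentum-SGD runs and acts as a pure rescale otherwise.
Gradients are verified against numerical differentiation in development.

## Packaged studies (`relbench.studies`)

*More–fewer network dissociation*: 2,000 training images (1,000 per class,
sides {3,4,5}), 80/20 split, minibatch 50, learning rate 0.05 with momentum
0.9, up to 120 epochs under the patience-6 rule, evaluated on 100
doubled-sides images ({6,8,10}). These are the package's desk-scale study
conditions, chosen once: the corpus is 10× smaller than the full corpus and
the optimizer settings are those under which the from-scratch reference
net learns the task reliably. The expectation is directional — validation
accuracy well above the doubled-sides accuracy — not a reproduction of any
particular accuracy level, which would require an ImageNet-pretrained
backbone (supported via the backend contract but not shipped).

*Observer dissociation*: 20 replications of two six-subject cohorts run
through 150 feedback trials + 40 novel-shape trials. The relational observer
answers with the true relation (recomputed from geometry) after a 25-trial
acquisition delay, with a 2 % lapse rate; the conjunctive observer memorizes
shape-identity-pair → label bindings from feedback and guesses on unseen
pairs. The acquisition delay stands in for humans' rapid rule discovery
(near-ceiling within the first 50-trial block); lapse and delay values are
testing placeholders for the analysis stage, not estimates of human
parameters. Keying conjunctive memory on generator shape identifiers is a
deliberate idealization of feature-conjunction learning; a pixel-similarity
variant is out of scope.

## Behavioral statistics

Per-subject proportions correct are aggregated as mean ± SEM across subjects
(SEM across subjects, matching the figure convention). One-sample t-tests
compare each 50-trial block against chance 0.5; paired t-tests compare the
final block with each generalization phase. Tests are two-sided and reported
uncorrected, with a Holm-adjusted column added for transparency. Zero-
variance inputs yield an explicitly flagged infinite (or zero) statistic
rather than an exception or a silent NaN. The t implementations are written
out from the textbook formulas and cross-checked against scipy to 10⁻⁹.

## Probe sweep

The sweep classifies the scene with the probe centered at every node of a
regular grid (default 2 px; 1 px available at 4× cost — whether the original
analysis used every pixel is not stated). Nodes where the marker would
overhang the frame are excluded rather than clipped, since training never
shows clipped probes. The binary map thresholds the positive-class score at
0.5. The exact-oracle model recovers the probe position from the rendered
pixels (the marker is the only red ink) and ray-casts it, exercising the
identical render-classify path as a trained model.

## What passing tests show — and what they do not

The synthetic corpora realize the documented generative rules exactly, and
the simulated observers realize the two strategy idealizations exactly; the
tests therefore validate the *pipeline* (generation → training → evaluation
→ statistics), the geometry against independent oracles, and the qualitative
human/network dissociation under these idealizations. They do not establish
anything about real human parameters (lapse rates, learning curves), nor
reproduce accuracy levels of large pretrained networks, and the reference
CNN's absolute accuracies should be read only through the within-study
validation/generalization contrast.

## Known limitations

- No pretrained backbone is shipped; restricted-mode transfer from rich
  features can only be exercised with a plug-in backend.
- Amoeboids are star-shaped by construction; the generator cannot produce
  closed curves that wrap around themselves.
- Fragment clutter is placed uniformly; no attempt is made to match the
  spatial statistics of any particular published figure.
- The reference CNN is orders of magnitude smaller than the networks whose
  behavior motivates the benchmark; its dissociation is qualitative.
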