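"""Train the reference CNN on a small more-fewer corpus and evaluate transfer.

A short demonstration of the harness mechanics: stratified split, per-epoch
validation checks with the consecutive-increase stopping rule, then
evaluation on the validation split and on the doubled-sides generalization
set.  At this deliberately tiny scale (400 images, 15 epochs) the network
stays near chance; the packaged study
(`relbench.studies.more_fewer_network_dissociation`, 2,000 images and a
120-epoch budget) is where the validation/generalization dissociation
emerges.
"""

from relbench.backends import SmallCNN
from relbench.datasets import build_more_fewer
from relbench.training import (
    TrainConfig,
    evaluate,
    split_dataset,
    train_with_early_stopping,
)

train = build_more_fewer(n_per_class=200, seed=11)
gen = build_more_fewer(sides_set=(6, 8, 10), n_per_class=25, seed=12)
tr, val = split_dataset(train, val_fraction=0.2, seed=0)

net = SmallCNN(seed=0)
cfg = TrainConfig(
    batch_size=50, learning_rate=0.05, momentum=0.9, max_epochs=15, patience=6, seed=0
)
net, trace = train_with_early_stopping(net, tr, val, cfg)

print(f"stopped after epoch {trace.stop_epoch} ({trace.stop_reason})")
print("validation error by epoch:", [round(e, 3) for e in trace.val_errors])
v = evaluate(net, val)
g = evaluate(net, gen)
print(f"validation accuracy ({v.n} images): {v.accuracy:.3f}")
print(f"doubled-sides generalization ({g.n} images): {g.accuracy:.3f}")
print(f"per-class on generalization: {g.per_class}")
# In the full study a clear validation/generalization gap appears: the net
# learns features tied to the trained polygons (3-5 sides) rather than the
# abstract more-fewer relation, so accuracy collapses on doubled sides.
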