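"""Run relational and conjunctive observer cohorts through the behavioral design.

Six simulated subjects per cohort complete 150 feedback trials and a 40-trial
novel-shape generalization phase; the blocked analysis (three 50-trial
blocks, t-tests vs chance, paired block-3 vs generalization tests) is then
applied identically to both cohorts.
"""

from relbench.analysis import summarize_experiment
from relbench.datasets import (
    build_same_different_generalization,
    build_same_different_train,
)
from relbench.observers import ObserverSpec, make_trial_sequence, simulate_cohort

train = build_same_different_train(n_shapes=20, n_per_class=100, seed=11)
gen = build_same_different_generalization("new_amoeboids", n_per_class=20, seed=12)
seq = make_trial_sequence(train, {"novel_shapes": gen}, seed=7)

for strategy in ("relational", "conjunctive"):
    logs = simulate_cohort(ObserverSpec(strategy=strategy), seq, n_subjects=6, seed=3)
    report = summarize_experiment(logs, ["novel_shapes"])
    blocks = " ".join(f"{b.proportion:.2f}±{b.sem:.2f}" for b in report.blocks)
    gen_acc = report.generalization["novel_shapes"]["proportion"]
    drop = report.tests[report.tests.comparison == "block3_vs_novel_shapes"].iloc[0]
    print(f"\n{strategy} cohort (n=6):")
    print(f"  learning blocks (prop ± SEM): {blocks}")
    print(f"  novel-shape generalization:   {gen_acc:.2f}")
    print(
        f"  block-3 vs generalization:    t({drop['df']}) = {drop['t']:.2f}, "
        f"p = {drop['p']:.4f}"
    )
# The relational cohort keeps its accuracy on novel shapes (no significant
# drop); the conjunctive cohort collapses to chance — the learned bindings
# never match shapes it has not seen.
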