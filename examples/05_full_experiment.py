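"""One-command end-to-end run: generate, train, evaluate, simulate, report.

Uses a deliberately small configuration so the whole run finishes in about
a minute; the run directory contains the datasets, training trace,
evaluation results for validation and every generalization set, and the
behavioral reports for both observer cohorts.
"""

import json
from pathlib import Path

from relbench.experiment import ExperimentConfig, run_experiment
from relbench.training import TrainConfig

cfg = ExperimentConfig(
    task="more_fewer",
    out_dir="example_output/run_more_fewer",
    seed=5,
    n_per_class=100,
    gen_n_per_class=25,
    n_learning_trials=60,
    n_generalization_trials=20,
    train=TrainConfig(
        batch_size=50, learning_rate=0.05, momentum=0.9, max_epochs=8, seed=0
    ),
    observers=("relational", "conjunctive"),
    n_subjects=4,
)
out = run_experiment(cfg)
evals = json.loads((out / "eval_results.json").read_text())
print(f"run directory: {out}")
for name, res in evals.items():
    print(f"  {name}: accuracy {res['accuracy']:.3f} (n={res['n']})")
print("  behavioral reports:", sorted(p.name for p in (out / "behavior").iterdir()))
# eval_results.json holds the classifier's accuracies; behavior/*/report.json
# holds each cohort's blocked accuracies and t-tests.
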