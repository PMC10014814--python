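"""Desk-scale replication studies bundling the package's headline analyses.

Two qualitative dissociations are packaged as reusable studies:

* :func:`more_fewer_network_dissociation` — train the reference CNN from
  scratch on the polygon more-fewer task ({3,4,5} sides) and test on the
  doubled-sides set ({6,8,10}).  The expectation is directional: solid
  within-distribution validation accuracy, collapse toward chance on the
  changed polygons.
* :func:`observer_dissociation` — run relational and conjunctive observer
  cohorts through the same-different design (150 feedback trials, 40-trial
  novel-shape generalization) and compare their block-3 vs generalization
  behavior with the blocked t-test pipeline.

Study conditions (dataset sizes, optimizer settings, epoch budgets) are
fixed here so tests, scripts, and examples all run the same study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .analysis import summarize_experiment
from .backends import SmallCNN
from .datasets import (
    build_more_fewer,
    build_same_different_generalization,
    build_same_different_train,
)
from .observers import ObserverSpec, make_trial_sequence, simulate_cohort
from .training import TrainConfig, evaluate, load_images, split_dataset, train_with_early_stopping

# conditions of the scaled-down more-fewer study: 2,000 training images
# (1,000 per class), 80/20 split, minibatch 50, momentum SGD from scratch
MF_N_PER_CLASS = 1000
MF_GEN_N_PER_CLASS = 50
MF_DATA_SEED = 11
MF_GEN_SEED = 12
MF_TRAIN = dict(
    batch_size=50, learning_rate=0.05, momentum=0.9, max_epochs=120, patience=6
)


@dataclass
class DissociationRun:
    seed: int
    val_accuracy: float
    gen_accuracy: float
    stop_epoch: int
    stop_reason: str

    @property
    def gap(self) -> float:
        return self.val_accuracy - self.gen_accuracy


def more_fewer_network_dissociation(
    seeds=range(5),
    n_per_class: int = MF_N_PER_CLASS,
    data_seed: int = MF_DATA_SEED,
    gen_seed: int = MF_GEN_SEED,
    verbose: bool = False,
) -> list[DissociationRun]:
    """Train-from-scratch runs of the polygon counting task, one per seed.

    The stimulus corpus sizes and the training protocol are fixed study
    conditions; the seeds vary the stimulus draws, network initialization,
    and batch order.
    """
    train = build_more_fewer(n_per_class=n_per_class, seed=data_seed)
    gen = build_more_fewer(
        sides_set=(6, 8, 10), n_per_class=MF_GEN_N_PER_CLASS, seed=gen_seed
    )
    tr, val = split_dataset(train, 0.2, seed=0)
    Xtr, ytr = load_images(tr, size=56)
    Xv, yv = load_images(val, size=56)
    Xg, yg = load_images(gen, size=56)
    runs = []
    for seed in seeds:
        net = SmallCNN(seed=seed)
        cfg = TrainConfig(seed=seed, **MF_TRAIN)
        net, trace = train_with_early_stopping(net, (Xtr, ytr), (Xv, yv), cfg)
        v = evaluate(net, (Xv, yv))
        g = evaluate(net, (Xg, yg))
        run = DissociationRun(
            seed=seed,
            val_accuracy=v.accuracy,
            gen_accuracy=g.accuracy,
            stop_epoch=trace.stop_epoch,
            stop_reason=trace.stop_reason,
        )
        runs.append(run)
        if verbose:
            print(
                f"seed {seed}: validation {v.accuracy:.3f}, doubled-sides "
                f"{g.accuracy:.3f} (epoch {trace.stop_epoch}, {trace.stop_reason})"
            )
    return runs


# observer-study conditions: 20-shape library, balanced sampling pools large
# enough for 150 learning + 40 generalization trials per replication
OBS_N_PER_CLASS = 100
OBS_GEN_N_PER_CLASS = 20


@dataclass
class ObserverReplication:
    seed: int
    relational_block3: float
    relational_gen: float
    relational_drop_p: float  # paired block3-vs-gen p for the relational cohort
    conjunctive_block3: float
    conjunctive_gen: float
    conjunctive_drop_p: float

    def dissociates(self, alpha: float = 0.01, n_gen_trials: int = 240) -> bool:
        """Relational shows no drop; conjunctive generalization sits in the
        99% binomial band of chance."""
        lo, hi = sps.binom.ppf([0.005, 0.995], n_gen_trials, 0.5) / n_gen_trials
        return (
            self.relational_drop_p > alpha
            and lo <= self.conjunctive_gen <= hi
        )


def observer_dissociation(
    n_replications: int = 20,
    base_seed: int = 1000,
    n_subjects: int = 6,
    data_seed: int = MF_DATA_SEED,
    gen_seed: int = MF_GEN_SEED,
) -> list[ObserverReplication]:
    """Replicated relational-vs-conjunctive cohort comparisons.

    One stimulus environment (training corpus + novel-shape generalization
    set) is shared; each replication redraws the trial sequence and the
    observers.
    """
    train = build_same_different_train(
        n_shapes=20, n_per_class=OBS_N_PER_CLASS, seed=data_seed
    )
    gen = build_same_different_generalization(
        "new_amoeboids", n_per_class=OBS_GEN_N_PER_CLASS, seed=gen_seed
    )
    out = []
    for rep in range(n_replications):
        seed = base_seed + rep
        seq = make_trial_sequence(train, {"gen_new_shapes": gen}, seed=seed)
        summaries = {}
        for strategy in ("relational", "conjunctive"):
            logs = simulate_cohort(
                ObserverSpec(strategy=strategy),
                seq,
                n_subjects=n_subjects,
                seed=seed * 2 + (strategy == "conjunctive"),
            )
            report = summarize_experiment(logs, ["gen_new_shapes"])
            drop = report.tests[
                report.tests.comparison == "block3_vs_gen_new_shapes"
            ].iloc[0]
            summaries[strategy] = (
                report.blocks[-1].proportion,
                report.generalization["gen_new_shapes"]["proportion"],
                float(drop["p"]),
            )
        out.append(
            ObserverReplication(
                seed=seed,
                relational_block3=summaries["relational"][0],
                relational_gen=summaries["relational"][1],
                relational_drop_p=summaries["relational"][2],
                conjunctive_block3=summaries["conjunctive"][0],
                conjunctive_gen=summaries["conjunctive"][1],
                conjunctive_drop_p=summaries["conjunctive"][2],
            )
        )
    return out
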