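"""Simulated observers: human-like relational learners vs. network-like
conjunctive memorizers.

Each observer runs through a trial sequence (a learning phase with feedback
followed by one or more no-feedback generalization phases) and produces a
response log with the same schema used for imported human data, so the
behavioral analysis applies to both without modification.

Strategies
----------
``relational``
    Responds with the true relation, recomputed from the stimulus geometry,
    after an initial acquisition delay; occasional lapses respond at random.
    This is the idealized human signature: once the rule is found it
    transfers to any stimulus that instantiates the relation.
``conjunctive``
    Memorizes bindings from concrete shape-identity combinations to labels
    during feedback trials and answers from that memory; combinations never
    seen (e.g. any novel-shape generalization item) get a coin flip.  This
    idealizes the network signature: learning that binds the relation to its
    concrete argument fillers and therefore fails to transfer.
``biased_constant``
    Always gives the same response (the positive class), reproducing the
    degenerate all-"Same"/all-"More" patterns.
``random``
    Uniform guessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datasets import (
    DatasetManifest,
    StimulusRecord,
    TASK_CLASSES,
    recompute_label,
)

STRATEGIES = ("relational", "conjunctive", "biased_constant", "random")


@dataclass(frozen=True)
class ObserverSpec:
    strategy: str = "relational"
    lapse_rate: float = 0.02
    learn_delay_trials: int = 25  # random responding before the strategy engages
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate must be in [0, 1]")
        if self.learn_delay_trials < 0:
            raise ValueError("learn_delay_trials must be >= 0")


@dataclass
class TrialSequence:
    """Ordered stimuli with phase tags; feedback only in the learning phase."""

    trials: list[tuple[StimulusRecord, str]]  # (record, phase tag)
    manifests: dict[str, DatasetManifest]  # phase tag -> source manifest
    task: str
    learning_phase: str = "learning"

    def __len__(self) -> int:
        return len(self.trials)


def make_trial_sequence(
    train_manifest: DatasetManifest,
    generalization: dict[str, DatasetManifest],
    n_learning: int = 150,
    n_generalization: int = 40,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> TrialSequence:
    """Sample a balanced learning phase and balanced generalization phases.

    Defaults follow the behavioral design: 150 feedback trials then 40-trial
    generalization phases, each balanced across the two classes.
    """
    rng = rng or np.random.default_rng(seed)

    def sample_balanced(manifest: DatasetManifest, n: int) -> list[StimulusRecord]:
        by_class: dict[str, list[StimulusRecord]] = {}
        for r in manifest.records:
            by_class.setdefault(r.label, []).append(r)
        half, rem = divmod(n, 2)
        counts = dict(
            zip(sorted(by_class), [half + rem, half])
        )  # odd n: one extra in first class
        chosen: list[StimulusRecord] = []
        for label, recs in sorted(by_class.items()):
            k = counts[label]
            if len(recs) < k:
                raise ValueError(
                    f"not enough {label!r} records ({len(recs)} < {k})"
                )
            idx = rng.choice(len(recs), size=k, replace=False)
            chosen.extend(recs[i] for i in idx)
        order = rng.permutation(len(chosen))
        return [chosen[i] for i in order]

    trials = [(r, "learning") for r in sample_balanced(train_manifest, n_learning)]
    manifests = {"learning": train_manifest}
    for tag, manifest in generalization.items():
        trials.extend((r, tag) for r in sample_balanced(manifest, n_generalization))
        manifests[tag] = manifest
    return TrialSequence(trials=trials, manifests=manifests, task=train_manifest.task)


def _conjunctive_key(record: StimulusRecord) -> tuple:
    """Concrete-feature binding key: the identities of the shapes on screen."""
    meta = record.shape_meta
    if record.task == "same_different":
        if "shape_id_a" in meta:
            return tuple(sorted((meta["shape_id_a"], meta["shape_id_b"])))
        # rectangle items: identity = aspect pair (rounded to rendering precision)
        return tuple(sorted((round(meta["aspect_a"], 3), round(meta["aspect_b"], 3))))
    if record.task == "more_fewer":
        return (meta["n_sides_dotted"], meta["n_sides_other"])
    # enclosure: every closed shape is unique, so key on the image itself —
    # the purest form of item memorization
    return (record.image_id,)


def simulate_observer(
    spec: ObserverSpec,
    seq: TrialSequence,
    rng: Optional[np.random.Generator] = None,
    subject_id: str = "sim",
) -> pd.DataFrame:
    """Run one observer through the sequence; returns a response log.

    Columns: trial, phase, image_id, true_label, response, correct, subject.
    """
    rng = rng or np.random.default_rng(spec.seed)
    neg, pos = TASK_CLASSES[seq.task]
    memory: dict[tuple, str] = {}
    rows = []
    for t, (record, phase) in enumerate(seq.trials):
        truth = recompute_label(record, seq.manifests[phase])
        in_learning = phase == seq.learning_phase
        engaged = (not in_learning) or t >= spec.learn_delay_trials

        if spec.strategy == "relational":
            response = truth if engaged else rng.choice((neg, pos))
        elif spec.strategy == "conjunctive":
            key = _conjunctive_key(record)
            if engaged and key in memory:
                response = memory[key]
            else:
                response = rng.choice((neg, pos))
        elif spec.strategy == "biased_constant":
            response = pos
        else:  # random
            response = rng.choice((neg, pos))

        if spec.lapse_rate > 0 and rng.random() < spec.lapse_rate:
            response = rng.choice((neg, pos))

        if in_learning and spec.strategy == "conjunctive":
            memory[_conjunctive_key(record)] = truth  # feedback reveals the label

        rows.append(
            {
                "trial": t + 1,
                "phase": phase,
                "image_id": record.image_id,
                "true_label": truth,
                "response": response,
                "correct": int(response == truth),
                "subject": subject_id,
            }
        )
    return pd.DataFrame(rows)


def simulate_cohort(
    spec: ObserverSpec,
    seq: TrialSequence,
    n_subjects: int = 6,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Independent observers sharing a strategy (fresh lapses and memories)."""
    rng = rng or np.random.default_rng(seed)
    logs = []
    for s in range(n_subjects):
        sub_rng = np.random.default_rng(int(rng.integers(2**31 - 1)))
        logs.append(
            simulate_observer(
                spec, seq, rng=sub_rng, subject_id=f"{spec.strategy}_{s:02d}"
            )
        )
    return logs
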