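"""End-to-end experiment orchestration from a single YAML config.

One config describes a full run for one task: generate the training corpus
and generalization sets, train a backend under the requested transfer
protocol, evaluate on the validation split and every generalization set,
optionally probe-sweep example scenes (enclosure), simulate observer
cohorts, and emit the behavioral report.  Every stage's seed derives
deterministically from the master seed, so a config + seed pair pins the
whole run.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import datasets as ds
from .backends import make_backend, CapabilityError
from .training import TrainConfig, split_dataset, train_with_early_stopping, evaluate
from .observers import ObserverSpec, make_trial_sequence, simulate_cohort
from .analysis import summarize_experiment, plot_report
from .probe import sweep_probe, render_probe_map, OracleEnclosureModel
from .render import TASK_STYLES, save_png

logger = logging.getLogger("relbench")

CONFIG_VERSION = 1

_TASKS = ("same_different", "enclosure", "more_fewer")

_KNOWN_KEYS = {
    "version", "task", "out_dir", "seed", "n_per_class", "n_shapes",
    "generalization", "train", "backend", "backend_options", "observers",
    "n_subjects", "probe_sweep", "sides_set", "gen_sides_set",
    "gen_n_per_class", "n_learning_trials", "n_generalization_trials",
}


class ConfigError(ValueError):
    pass


@dataclass
class ExperimentConfig:
    task: str
    out_dir: str
    seed: int = 0
    n_per_class: int = 500
    n_shapes: int = 20  # same-different library size
    sides_set: tuple = (3, 4, 5)
    gen_sides_set: tuple = (6, 8, 10)
    generalization: tuple = ()  # task-specific kinds; empty = task defaults
    gen_n_per_class: int = 30
    train: TrainConfig = field(default_factory=TrainConfig)
    backend: str = "smallcnn"
    backend_options: dict = field(default_factory=dict)
    observers: tuple = ("relational", "conjunctive")
    n_subjects: int = 6
    probe_sweep: bool = False
    n_learning_trials: int = 150
    n_generalization_trials: int = 40

    def __post_init__(self) -> None:
        if self.task not in _TASKS:
            raise ConfigError(f"unknown task {self.task!r}")
        if not self.generalization:
            self.generalization = {
                "same_different": ("new_amoeboids", "rectangles"),
                "enclosure": ("cp16", "squares", "big_contour"),
                "more_fewer": ("doubled",),
            }[self.task]

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        version = raw.get("version", CONFIG_VERSION)
        if version != CONFIG_VERSION:
            raise ConfigError(f"unsupported config version {version}")
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        train_raw = raw.pop("train", {})
        bad = set(train_raw) - set(TrainConfig.__dataclass_fields__)
        if bad:
            raise ConfigError(f"unknown train keys: {sorted(bad)}")
        raw.pop("version", None)
        kwargs = dict(raw)
        for key in ("generalization", "observers", "sides_set", "gen_sides_set"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(train=TrainConfig(**train_raw), **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["version"] = CONFIG_VERSION
        return d


def _stage_seeds(master: int, names: list[str]) -> dict[str, int]:
    ss = np.random.SeedSequence(master)
    children = ss.spawn(len(names))
    return {
        n: int(c.generate_state(1)[0] % (2**31 - 1)) for n, c in zip(names, children)
    }


def _build_datasets(cfg: ExperimentConfig, seeds: dict) -> tuple:
    task = cfg.task
    if task == "same_different":
        train = ds.build_same_different_train(
            n_shapes=cfg.n_shapes, n_per_class=cfg.n_per_class, seed=seeds["train_data"]
        )
        gens = {
            kind: ds.build_same_different_generalization(
                kind, n_per_class=cfg.gen_n_per_class, seed=seeds[f"gen_{kind}"]
            )
            for kind in cfg.generalization
        }
    elif task == "enclosure":
        config = ds.EnclosureConfig(n_per_class=cfg.n_per_class)
        train = ds.build_enclosure_train(config, seed=seeds["train_data"])
        gens = {
            kind: ds.build_enclosure_generalization(
                kind, n_per_class=cfg.gen_n_per_class, config=config,
                seed=seeds[f"gen_{kind}"],
            )
            for kind in cfg.generalization
        }
    else:
        train = ds.build_more_fewer(
            sides_set=cfg.sides_set, n_per_class=cfg.n_per_class,
            seed=seeds["train_data"],
        )
        gens = {
            "doubled": ds.build_more_fewer(
                sides_set=cfg.gen_sides_set, n_per_class=cfg.gen_n_per_class,
                seed=seeds["gen_doubled"],
            )
        }
    return train, gens


def run_experiment(cfg: ExperimentConfig) -> Path:
    """Execute all stages; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_names = (
        ["train_data", "split", "train", "observers", "trials"]
        + [f"gen_{k}" for k in cfg.generalization]
        + ["gen_doubled"]
    )
    seeds = _stage_seeds(cfg.seed, stage_names)
    (out / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict()))
    log_lines = []

    def stage(name):
        t0 = time.time()
        logger.info("stage %s (seed %s)", name, seeds.get(name))

        def done():
            log_lines.append(f"{name}: {time.time() - t0:.1f}s seed={seeds.get(name)}")

        return done

    try:
        done = stage("datasets")
        train_full, gens = _build_datasets(cfg, seeds)
        train_full.save(out / "data" / "train")
        for kind, g in gens.items():
            g.save(out / "data" / f"gen_{kind}")
        done()

        done = stage("train")
        train_m, val_m = split_dataset(
            train_full, cfg.train.val_fraction, seed=seeds["split"]
        )
        backend = make_backend(cfg.backend, seed=seeds["train"], **cfg.backend_options)
        backend, trace = train_with_early_stopping(backend, train_m, val_m, cfg.train)
        import pandas as pd

        pd.DataFrame(
            {
                "epoch": range(1, len(trace.val_errors) + 1),
                "train_error": trace.train_errors,
                "val_error": trace.val_errors,
            }
        ).to_csv(out / "training_trace.csv", index=False)
        done()

        done = stage("evaluate")
        evals = {"validation": evaluate(backend, val_m).to_dict()}
        for kind, g in gens.items():
            evals[kind] = evaluate(backend, g).to_dict()
        (out / "eval_results.json").write_text(json.dumps(evals, indent=2))
        done()

        if cfg.probe_sweep and cfg.task == "enclosure":
            done = stage("probe_sweep")
            rec = train_full.records[0]
            scene_full = train_full.scene(rec)
            closed = next(c for c in scene_full if c.closed)
            for name, scene in (("isolated", [closed]), ("cluttered", scene_full)):
                pmap = sweep_probe(backend, scene, grid_step=4, scene_id=name)
                binary, gray = render_probe_map(pmap, [closed])
                sweep_dir = out / "probe_maps"
                sweep_dir.mkdir(exist_ok=True)
                save_png(binary, sweep_dir / f"{name}_binary.png")
                save_png(gray, sweep_dir / f"{name}_scores.png")
                np.savetxt(sweep_dir / f"{name}_scores.csv", pmap.scores, delimiter=",")
            done()

        done = stage("observers")
        seq = make_trial_sequence(
            train_full,
            gens,
            n_learning=cfg.n_learning_trials,
            n_generalization=cfg.n_generalization_trials,
            seed=seeds["trials"],
        )
        obs_rng = np.random.default_rng(seeds["observers"])
        for strategy in cfg.observers:
            spec = ObserverSpec(strategy=strategy)
            logs = simulate_cohort(
                spec, seq, n_subjects=cfg.n_subjects,
                seed=int(obs_rng.integers(2**31 - 1)),
            )
            report = summarize_experiment(
                logs, list(gens), block_size=max(1, cfg.n_learning_trials // 3)
            )
            rep_dir = out / "behavior" / strategy
            report.save(rep_dir)
            plot_report(report, rep_dir / "figure.png")
            for log in logs:
                log.to_csv(rep_dir / f"{log['subject'].iloc[0]}.csv", index=False)
        done()
    except Exception as exc:  # annotate failures with stage context
        (out / "run_log.txt").write_text("\n".join(log_lines + [f"FAILED: {exc}"]))
        raise
    (out / "run_log.txt").write_text("\n".join(log_lines))
    return out
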