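"""Blocked behavioral statistics for response logs.

The analysis mirrors the study design: the 150-trial learning phase is
split into three 50-trial blocks; per-subject proportions correct are
aggregated to mean ± SEM across subjects; one-sample t-tests compare each
block against chance (0.5) and paired t-tests compare the final learning
block with each generalization phase.  Tests are two-sided and reported
uncorrected (a Holm-adjusted column is added for transparency); degrees of
freedom are ``n_subjects - 1``.

The same pipeline applies to simulated observers, imported human logs, and
network response logs — any table with the response-log schema.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

LOG_COLUMNS = ["trial", "phase", "image_id", "true_label", "response", "correct", "subject"]
CHANCE = 0.5


@dataclass
class BlockSummary:
    block: int
    n_trials: int
    proportion: float  # mean across subjects
    sem: float
    per_subject: list[float] = field(default_factory=list)


@dataclass
class TestResult:
    t: float
    df: int
    p: float
    mean_diff: float
    degenerate: bool = False  # zero variance: t is infinite by convention

    def to_dict(self) -> dict:
        return asdict(self)


class DegenerateVarianceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# blocked accuracies
# ---------------------------------------------------------------------------


def _phase_frame(log: pd.DataFrame, phase: str) -> pd.DataFrame:
    sub = log[log["phase"] == phase]
    if sub.empty:
        raise ValueError(f"log has no trials in phase {phase!r}")
    return sub.sort_values("trial").reset_index(drop=True)


def block_accuracies(
    logs: Sequence[pd.DataFrame], phase: str, block_size: int = 50
) -> list[BlockSummary]:
    """Per-block proportion correct, aggregated across subjects (mean ± SEM)."""
    per_subject_blocks: list[list[float]] = []
    n_blocks = None
    block_sizes = None
    for log in logs:
        sub = _phase_frame(log, phase)
        if len(sub) < block_size:
            raise ValueError(
                f"phase {phase!r} has {len(sub)} trials < block_size {block_size}"
            )
        correct = sub["correct"].to_numpy()
        bounds = list(range(0, len(correct), block_size))
        props = [float(correct[b : b + block_size].mean()) for b in bounds]
        sizes = [len(correct[b : b + block_size]) for b in bounds]
        if n_blocks is None:
            n_blocks, block_sizes = len(props), sizes
        elif len(props) != n_blocks:
            raise ValueError("subjects disagree on phase length")
        per_subject_blocks.append(props)
    arr = np.asarray(per_subject_blocks)  # (subjects, blocks)
    out = []
    for b in range(arr.shape[1]):
        vals = arr[:, b]
        sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        out.append(
            BlockSummary(
                block=b + 1,
                n_trials=block_sizes[b],
                proportion=float(vals.mean()),
                sem=sem,
                per_subject=vals.tolist(),
            )
        )
    return out


def phase_accuracies(logs: Sequence[pd.DataFrame], phase: str) -> np.ndarray:
    """Per-subject proportion correct over a whole phase."""
    return np.array(
        [float(_phase_frame(log, phase)["correct"].mean()) for log in logs]
    )


# ---------------------------------------------------------------------------
# t-tests (explicit formulas, cross-checked against scipy in the test suite)
# ---------------------------------------------------------------------------


def _one_sample_t(values: np.ndarray, popmean: float) -> TestResult:
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 observations")
    mean = x.mean()
    sd = x.std(ddof=1)
    diff = mean - popmean
    if sd == 0.0:
        # all subjects identical: the statistic is infinite; flag, don't hide
        t = float("inf") if diff > 0 else (float("-inf") if diff < 0 else 0.0)
        p = 0.0 if diff != 0 else 1.0
        return TestResult(t=t, df=n - 1, p=p, mean_diff=float(diff), degenerate=True)
    t = diff / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return TestResult(t=float(t), df=n - 1, p=float(p), mean_diff=float(diff))


def t_vs_chance(per_subject_props: Sequence[float], chance: float = CHANCE) -> TestResult:
    """One-sample t of per-subject proportions against chance."""
    return _one_sample_t(np.asarray(per_subject_props), chance)


def paired_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Paired t on per-subject differences a - b."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    return _one_sample_t(a - b, 0.0)


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


# ---------------------------------------------------------------------------
# full experiment report
# ---------------------------------------------------------------------------


@dataclass
class Report:
    task: str
    blocks: list[BlockSummary]
    generalization: dict[str, dict]  # phase -> {proportion, sem, per_subject}
    tests: pd.DataFrame  # one row per comparison
    n_subjects: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "task": self.task,
                "n_subjects": self.n_subjects,
                "blocks": [asdict(b) for b in self.blocks],
                "generalization": self.generalization,
                "tests": self.tests.to_dict(orient="records"),
            },
            indent=2,
        )

    def save(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(self.to_json())
        self.tests.to_csv(outdir / "tests.csv", index=False)


def summarize_experiment(
    logs: Sequence[pd.DataFrame],
    gen_phase_names: Sequence[str],
    learning_phase: str = "learning",
    block_size: int = 50,
    chance: float = CHANCE,
) -> Report:
    """Blocked accuracies, chance tests, and learning-vs-generalization tests."""
    phases_seen = [set(log["phase"].unique()) for log in logs]
    if any(ph != phases_seen[0] for ph in phases_seen[1:]):
        raise ValueError("subjects have mismatched phases")

    blocks = block_accuracies(logs, learning_phase, block_size)
    rows = []
    for b in blocks:
        res = t_vs_chance(b.per_subject, chance)
        rows.append(
            {
                "comparison": f"block{b.block}_vs_chance",
                **res.to_dict(),
            }
        )
    last_block = np.asarray(blocks[-1].per_subject)
    gen_summaries: dict[str, dict] = {}
    for name in gen_phase_names:
        props = phase_accuracies(logs, name)
        sem = float(props.std(ddof=1) / np.sqrt(len(props))) if len(props) > 1 else 0.0
        gen_summaries[name] = {
            "proportion": float(props.mean()),
            "sem": sem,
            "per_subject": props.tolist(),
        }
        rows.append(
            {"comparison": f"{name}_vs_chance", **t_vs_chance(props, chance).to_dict()}
        )
        rows.append(
            {
                "comparison": f"block{len(blocks)}_vs_{name}",
                **paired_t(last_block, props).to_dict(),
            }
        )
    tests = pd.DataFrame(rows)
    tests["p_holm"] = holm_adjust(tests["p"].to_numpy())
    task = str(logs[0].get("task", pd.Series(["unknown"])).iloc[0]) if "task" in logs[0] else "unknown"
    return Report(
        task=task,
        blocks=blocks,
        generalization=gen_summaries,
        tests=tests,
        n_subjects=len(logs),
    )


def plot_report(report: Report, path=None):
    """Bar chart in the benchmark's figure layout: blue learning blocks,
    orange generalization bars, ± 1 SEM error bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [f"Block {b.block}" for b in report.blocks] + list(report.generalization)
    values = [b.proportion for b in report.blocks] + [
        g["proportion"] for g in report.generalization.values()
    ]
    errs = [b.sem for b in report.blocks] + [
        g["sem"] for g in report.generalization.values()
    ]
    colors = ["tab:blue"] * len(report.blocks) + ["tab:orange"] * len(
        report.generalization
    )
    fig, ax = plt.subplots(figsize=(1.2 * len(labels) + 2, 4))
    ax.bar(range(len(labels)), values, yerr=errs, capsize=4, color=colors)
    ax.axhline(CHANCE, color="k", ls="--", lw=1)
    ax.set_xticks(range(len(labels)), labels, rotation=30, ha="right")
    ax.set_ylabel("Proportion correct")
    ax.set_ylim(0, 1.05)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
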