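"""Figure rendering and machine-readable summaries of curve tables.

Consumes the long-format CSV written by the experiment module (columns
``environment, strategy, replicate, step, performance``) and produces
per-figure plots plus a JSON summary of per-curve milestones: performance at
fixed checkpoints and the first step at which the replicate-mean curve
reaches the milestone level (0.75 by default, mirroring the headline
comparison of learning times).  Summaries are pure functions of the input
tables; rendering a fixed input twice gives identical summaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["FigureSpec", "curve_milestones", "render_figure"]

REQUIRED_COLUMNS = ("environment", "strategy", "replicate", "step", "performance")


@dataclass(frozen=True)
class FigureSpec:
    """What to render: input curve tables plus axis/legend metadata."""

    figure_id: str
    csv_paths: tuple[str, ...]
    title: str = ""
    milestone: float = 0.75
    checkpoints: tuple[int, ...] = ()
    out_dir: str = "figures"
    formats: tuple[str, ...] = ("png",)


def _load(csv_paths) -> pd.DataFrame:
    frames = []
    for path in csv_paths:
        df = pd.read_csv(path)
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
        frames.append(df)
    if not frames:
        raise ValueError("no input CSV paths given")
    return pd.concat(frames, ignore_index=True)


def curve_milestones(
    df: pd.DataFrame,
    milestone: float = 0.75,
    checkpoints: tuple[int, ...] = (),
) -> dict:
    """Per (environment, strategy) milestones of the replicate-mean curve."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"curve table is missing required columns {missing}")
    summary: dict = {}
    grouped = df.groupby(["environment", "strategy"], sort=True)
    for (env, strategy), block in grouped:
        mean = block.groupby("step", sort=True)["performance"].mean()
        reached = mean[mean >= milestone]
        entry = {
            "final_step": int(mean.index[-1]),
            "final_performance": round(float(mean.iloc[-1]), 6),
            f"trials_to_{milestone}": (
                int(reached.index[0]) if len(reached) else None
            ),
        }
        for step in checkpoints:
            if step in mean.index:
                entry[f"performance_at_{step}"] = round(float(mean.loc[step]), 6)
        summary.setdefault(env, {})[strategy] = entry
    return summary


def render_figure(spec: FigureSpec) -> dict:
    """Render mean learning curves and write the milestone summary.

    Writes one plot file per requested format plus ``<figure_id>_summary.json``
    into ``spec.out_dir``; returns the summary dict.
    """
    df = _load(spec.csv_paths)
    out_dir = Path(spec.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    environments = df["environment"].unique()
    fig, axes = plt.subplots(
        1, len(environments), figsize=(5 * len(environments), 3.6), squeeze=False
    )
    for ax, env in zip(axes[0], environments):
        block = df[df["environment"] == env]
        for strategy, curves in block.groupby("strategy", sort=True):
            mean = curves.groupby("step", sort=True)["performance"].mean()
            ax.plot(mean.index, mean.values, label=strategy)
        ax.axhline(spec.milestone, color="grey", lw=0.6, ls="--")
        ax.set_ylim(0.0, 1.02)
        ax.set_xlabel("time-steps")
        ax.set_ylabel("fraction correct on test set")
        ax.set_title(env)
        ax.legend(fontsize=7)
    if spec.title:
        fig.suptitle(spec.title)
    fig.tight_layout()
    for fmt in spec.formats:
        fig.savefig(out_dir / f"{spec.figure_id}.{fmt}", dpi=150)
    plt.close(fig)

    summary = curve_milestones(df, spec.milestone, spec.checkpoints)
    with open(out_dir / f"{spec.figure_id}_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
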