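"""Diagnostic figures: condition-average trajectories and the
compensation–adaptation scatter."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .pipeline import PipelineResult, pair_responses

__all__ = ["plot_condition_averages", "plot_relationship", "save_figures"]

_COLORS = {"up": "#2166ac", "down": "#b2182b"}


def _stack(trajs: list[np.ndarray]) -> np.ndarray:
    n = max(len(t) for t in trajs)
    out = np.full((len(trajs), n), np.nan)
    for i, t in enumerate(trajs):
        out[i, : len(t)] = t
    return out


def plot_condition_averages(result: PipelineResult) -> plt.Figure:
    """Grand-average normalized F1 per condition with SE bands, one panel
    per measure, with significant cluster extents marked underneath."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.6), sharey=True)
    for ax, measure in zip(axes, ("compensation", "adaptation")):
        for d in ("up", "down"):
            trajs = [v for (pid, m, dd), v in
                     result.participant_avg_trajectories.items()
                     if m == measure and dd == d]
            if not trajs:
                continue
            mat = _stack(trajs)
            t = np.arange(mat.shape[1]) * result.step_ms
            mean = np.nanmean(mat, axis=0)
            n = np.sum(np.isfinite(mat), axis=0)
            se = np.nanstd(mat, axis=0, ddof=1) / np.sqrt(np.maximum(n, 1))
            ax.plot(t, mean, color=_COLORS[d], label=f"{d} shift")
            ax.fill_between(t, mean - se, mean + se, color=_COLORS[d], alpha=0.25)
        for i, d in enumerate(("up", "down")):
            cr = result.cluster_tests.get(f"{measure}_{d}_vs_zero")
            if cr is None:
                continue
            for c in cr.significant():
                y = ax.get_ylim()[0] * (0.92 + 0.05 * i)
                ax.plot([c.start_ms, c.end_ms], [y, y], color=_COLORS[d], lw=3)
        ax.axhline(0, color="0.5", lw=0.8)
        ax.set_title(measure)
        ax.set_xlabel("time from vowel onset (ms)")
    axes[0].set_ylabel("normalized F1 (mels)")
    axes[0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig


def plot_relationship(result: PipelineResult) -> plt.Figure:
    """Sign-corrected compensation vs subsequent adaptation, trial level."""
    pairs = pair_responses(result.comp_trials, result.adapt_trials)
    fig, ax = plt.subplots(figsize=(4.2, 4))
    ax.scatter(pairs["compensation"], pairs["adaptation"], s=6, alpha=0.3,
               color="0.3", edgecolors="none")
    if result.relationship_trial is not None:
        b0 = result.relationship_trial.term("Intercept").estimate
        b1 = result.relationship_trial.term("compensation").estimate
        x = np.linspace(pairs["compensation"].min(), pairs["compensation"].max(), 10)
        ax.plot(x, b0 + b1 * x, color="crimson")
    ax.set_xlabel("compensation (mels, sign-corrected)")
    ax.set_ylabel("one-shot adaptation (mels, sign-corrected)")
    fig.tight_layout()
    return fig


def save_figures(result: PipelineResult, out_dir: str | Path) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, fn in (("condition_averages.png", plot_condition_averages),
                     ("relationship.png", plot_relationship)):
        try:
            fig = fn(result)
        except (KeyError, ValueError):
            continue
        p = out / name
        fig.savefig(p, dpi=150)
        plt.close(fig)
        paths.append(p)
    return paths
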