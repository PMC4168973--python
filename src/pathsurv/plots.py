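"""Figure helpers: Kaplan-Meier curves with censor ticks, ROC with AUC inset,
and per-fraction sensitivity boxplots."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluation import ROCResult
from .harness import SensitivityResult
from .io import SurvivalOutcome

__all__ = ["plot_km_groups", "plot_roc", "plot_sensitivity"]


def _km_steps(time, event):
    from .evaluation import km_estimate

    km = km_estimate((time, event))
    xs = np.concatenate([[0.0], np.repeat(km.event_times, 2)])
    ys = np.concatenate([[1.0, 1.0], np.repeat(km.survival, 2)[:-1]]) if len(km.event_times) else np.array([1.0])
    if len(km.event_times) == 0:
        xs = np.array([0.0, max(np.max(time), 1.0)])
        ys = np.array([1.0, 1.0])
    return xs, ys, km


def plot_km_groups(survival: SurvivalOutcome, high_mask, path: str | Path, p_value: float | None = None) -> None:
    """Two-group KM plot (high vs low risk) with censor ticks."""
    t, e = survival.time, survival.event
    high = np.asarray(high_mask, dtype=bool)
    fig, ax = plt.subplots(figsize=(5, 4))
    for mask, label, color in [(high, "high risk", "tab:red"), (~high, "low risk", "tab:blue")]:
        if mask.sum() == 0:
            continue
        xs, ys, km = _km_steps(t[mask], e[mask])
        ax.plot(xs, ys, label=f"{label} (n={int(mask.sum())})", color=color)
        cens = t[mask][e[mask] == 0]
        sf = np.array([km.at(c) for c in cens])
        ax.plot(cens, sf, "+", color=color, markersize=5)
    if p_value is not None:
        ax.text(0.55, 0.1, f"log-rank p = {p_value:.3g}", transform=ax.transAxes)
    ax.set_xlabel("years")
    ax.set_ylabel("relapse-free survival")
    ax.set_ylim(0, 1.02)
    ax.legend(loc="lower left", frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_roc(roc: ROCResult, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(4.2, 4))
    ax.plot(roc.fpr, roc.tpr, color="tab:red")
    ax.plot([0, 1], [0, 1], ":", color="grey")
    ax.text(0.6, 0.1, f"AUC = {roc.auc:.2f}")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_sensitivity(results: Sequence[SensitivityResult], path: str | Path) -> None:
    """Boxplots of AUC and -log10 p per pathway fraction."""
    fractions = sorted({r.fraction for r in results}, reverse=True)
    aucs = [[r.auc for r in results if r.fraction == f] for f in fractions]
    logps = [[-np.log10(max(r.logrank_p, 1e-300)) for r in results if r.fraction == f] for f in fractions]
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.6))
    for ax, data, title in [(axes[0], aucs, "AUC"), (axes[1], logps, "-log10 p")]:
        ax.boxplot(data, tick_labels=[f"{f:g}" for f in fractions])
        ax.set_xlabel("pathway fraction")
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
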