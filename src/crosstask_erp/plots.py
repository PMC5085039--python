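"""Figures: midline ERP time courses, channel x time maps, scalp topographies."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .discriminability import DiscriminabilityMap, GrandAverage, bootstrap_ci
from .montage import positions_2d

MIDLINE = ("Fz", "Cz", "Pz")


def plot_midline_timecourses(ga: GrandAverage, condition: str,
                             path: str | Path, n_boot: int = 200,
                             seed: int = 0) -> None:
    """Target and distractor grand averages at Fz, Cz and Pz with 68%
    bootstrap CIs over participants."""
    fig, axes = plt.subplots(1, len(MIDLINE), figsize=(12, 3.2), sharey=True)
    t = ga.times_ms
    for ax, ch in zip(axes, MIDLINE):
        ci = ga.channel_names.index(ch)
        for label, name, color in ((1, "targets", "tab:red"), (0, "distractors", "tab:blue")):
            key = (condition, label)
            if key not in ga.mean:
                continue
            ax.plot(t, ga.mean[key][ci], color=color, label=name)
            pm = ga.participant_means[key][:, ci, :]
            if pm.shape[0] > 1:
                band = np.array([
                    bootstrap_ci(pm[:, j], n_boot=n_boot, seed=seed)
                    for j in range(pm.shape[1])
                ])
                ax.fill_between(t, band[:, 0], band[:, 1], color=color, alpha=0.2)
        ax.axvline(0, color="k", lw=0.5)
        ax.set_title(f"{ch} ({condition})")
        ax.set_xlabel("time (ms)")
    axes[0].set_ylabel("potential (uV)")
    axes[0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_channel_time_matrix(map_: DiscriminabilityMap, path: str | Path,
                             title: str = "") -> None:
    """Signed-r2 (or voltage) values for every channel over time, color
    coded."""
    fig, ax = plt.subplots(figsize=(8, 8))
    vmax = np.nanmax(np.abs(map_.values)) or 1.0
    im = ax.imshow(map_.values, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                   extent=[map_.times_ms[0], map_.times_ms[-1],
                           len(map_.channel_names) - 0.5, -0.5])
    ax.set_yticks(range(len(map_.channel_names)))
    ax.set_yticklabels(map_.channel_names, fontsize=4)
    ax.set_xlabel("time (ms)")
    ax.set_title(title or f"signed r2 ({map_.condition})")
    fig.colorbar(im, ax=ax, shrink=0.6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_topography_grid(map_: DiscriminabilityMap, path: str | Path,
                         window_centers_ms: np.ndarray | None = None,
                         half_width_ms: float = 25.0) -> None:
    """Scalp maps (head from above, nose up) of values averaged over 50 ms
    windows centered at 100, 200, ..., 800 ms post-stimulus."""
    if window_centers_ms is None:
        window_centers_ms = np.arange(100, 801, 100)
    pos = positions_2d(map_.channel_names)
    vmax = np.nanmax(np.abs(map_.values)) or 1.0
    n = len(window_centers_ms)
    fig, axes = plt.subplots(1, n, figsize=(2.0 * n, 2.4))
    for ax, tc in zip(np.atleast_1d(axes), window_centers_ms):
        m = (map_.times_ms >= tc - half_width_ms) & (map_.times_ms < tc + half_width_ms)
        vals = map_.values[:, m].mean(axis=1)
        sc = ax.scatter(pos[:, 0], pos[:, 1], c=vals, cmap="RdBu_r",
                        vmin=-vmax, vmax=vmax, s=28)
        circle = plt.Circle((0, 0), np.abs(pos).max() * 1.15, fill=False, lw=0.8)
        ax.add_patch(circle)
        ax.set_title(f"{tc:g} ms", fontsize=8)
        ax.set_aspect("equal")
        ax.axis("off")
    fig.colorbar(sc, ax=axes, shrink=0.7)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_learning_curve(curve, path: str | Path) -> None:
    """Across-participant AUC versus number of training subjects with the
    68% bootstrap band."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(curve.n_train_subjects, curve.mean_auc, "o-", color="tab:green")
    if curve.ci68 is not None:
        ax.fill_between(curve.n_train_subjects, curve.ci68[0], curve.ci68[1],
                        color="tab:green", alpha=0.25)
    ax.axhline(0.5, color="k", lw=0.5, ls="--")
    ax.set_xlabel("number of training subjects (n)")
    ax.set_ylabel("AUC")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
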