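"""Optional plot exports: collision-recall and correlogram-error panels.

matplotlib is imported lazily so the rest of the package works without a
plotting backend installed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .collision_metrics import CollisionProfile, CorrelogramErrorProfile

__all__ = ["plot_collision_profiles", "plot_ccg_error"]


def plot_collision_profiles(
    pooled: dict[tuple[float, float], CollisionProfile],
    out_path: str | Path,
    title: str = "Collision recall by lag and template similarity",
) -> None:
    """Recall-vs-lag curves, one per similarity bin (colour-coded)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    cmap = plt.get_cmap("viridis")
    keys = sorted(pooled)
    for k, (lo, hi) in enumerate(keys):
        p = pooled[(lo, hi)]
        color = cmap(k / max(1, len(keys) - 1))
        ax.plot(p.lag_bin_centers_ms, p.recall, "o-", color=color,
                label=f"[{lo:.1f}, {hi:.1f})")
    ax.set_xlabel("lag (ms)")
    ax.set_ylabel("collision recall")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title(title)
    ax.legend(title="similarity", fontsize=7, title_fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def plot_ccg_error(
    profile: CorrelogramErrorProfile,
    out_path: str | Path,
    title: str = "Cross-correlogram relative error",
) -> None:
    """Mean relative CCG error versus lag for matched pairs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(profile.lags_ms, 100.0 * np.asarray(profile.mean_relative_error),
            "k-o", ms=3)
    ax.set_xlabel("lag (ms)")
    ax.set_ylabel("relative error (%)")
    ax.set_title(f"{title} (n={profile.n_pairs} pairs)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
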