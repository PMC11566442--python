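"""Projection figures: actual + projected conditional probabilities on a
log scale with shaded 95% prediction intervals, one panel per education
level, lines by obesity status."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

_COLORS = {0: "#1f77b4", 1: "#d62728"}
_LABEL = {0: "non-obese", 1: "obese"}


def plot_aggregate_projection(aggregate, projections_aggregate, sex, path):
    """One figure per sex: panels low/middle/high education, per-100k rates."""
    obs = aggregate[aggregate["sex"] == sex]
    proj = projections_aggregate[projections_aggregate["sex"] == sex]
    levels = ["low", "middle", "high"]
    fig, axes = plt.subplots(1, 3, figsize=(12, 4), sharey=True)
    for ax, edu in zip(axes, levels):
        for ob in (0, 1):
            o = obs[(obs["education"] == edu) & (obs["obesity"] == ob)].sort_values("year")
            p = proj[(proj["education"] == edu) & (proj["obesity"] == ob)].sort_values("year")
            ax.plot(o["year"], o["prob_per_100k"], color=_COLORS[ob], label=_LABEL[ob])
            ax.plot(p["year"], p["prob_per_100k"], color=_COLORS[ob], ls="--")
            ax.fill_between(
                p["year"], p["lower_per_100k"], p["upper_per_100k"],
                color=_COLORS[ob], alpha=0.2, lw=0,
            )
        ax.set_yscale("log")
        ax.set_title(f"{edu} education")
        ax.set_xlabel("year")
    axes[0].set_ylabel("CVD deaths per 100,000")
    axes[0].legend(frameon=False)
    fig.suptitle(f"Pr(CVD | O, E), all ages 35-74, {sex}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
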