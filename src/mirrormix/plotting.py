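"""Small matplotlib helpers for layouts and posterior summaries."""

from __future__ import annotations

import numpy as np

from .layouts import Layout

__all__ = ["plot_layout", "plot_memory_rates"]


def plot_layout(layout: Layout, ax=None):
    """Overhead sketch of one arena: boundary, landmark ellipses, targets."""
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle, Ellipse

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.add_patch(Circle((0, 0), layout.arena_radius, fill=False, ls="--",
                        color="grey"))
    for lm in layout.landmarks:
        ax.add_patch(Ellipse(lm.center, 2 * lm.semi_major, 2 * lm.semi_minor,
                             angle=np.degrees(lm.orientation), alpha=0.4,
                             label=lm.label))
        ax.annotate(lm.label, lm.center, ha="center", va="center", fontsize=8)
    for t in layout.targets:
        ax.plot(*t.position, "x", color="tab:blue")
        ax.annotate(str(t.id), t.position, textcoords="offset points",
                    xytext=(4, 4), fontsize=7)
    r = layout.arena_radius * 1.1
    ax.set(xlim=(-r, r), ylim=(-r, r), aspect="equal",
           title=f"{layout.name} layout", xlabel="x (m)", ylabel="y (m)")
    return ax


def plot_memory_rates(rates_by_group, ax=None, level: float = 0.95):
    """Posterior memory rates (median, credible band) across age groups.

    ``rates_by_group`` maps a group label (e.g. bin midpoint) to a DataFrame
    of memory-rate draws, one column per stage parameter.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    a = (1.0 - level) / 2.0
    labels = sorted(rates_by_group)
    stages = list(next(iter(rates_by_group.values())).columns)
    for stage in stages:
        med = [rates_by_group[g][stage].median() for g in labels]
        lo = [rates_by_group[g][stage].quantile(a) for g in labels]
        hi = [rates_by_group[g][stage].quantile(1 - a) for g in labels]
        x = np.arange(len(labels))
        ax.errorbar(x, med,
                    yerr=[np.subtract(med, lo), np.subtract(hi, med)],
                    marker="o", capsize=3, label=stage)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xticks(np.arange(len(labels)), [str(g) for g in labels])
    ax.set(ylabel="memory rate", xlabel="age group")
    ax.legend()
    return ax
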