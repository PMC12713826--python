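"""Hypnodensity graph rendering.

Stacked per-epoch probability bands in the fixed stage order, using the
conventional colors: W gray, R red, N1 cyan, N2 blue, N3 green (four-stage
data: W gray, LS blue, DS green, R red).  An optional consensus hypnogram
is overlaid as a step line.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .core import Hypnodensity, Hypnogram
from .errors import AlignmentError

__all__ = ["STAGE_COLORS", "plot_hypnodensity"]

STAGE_COLORS = {
    "W": "0.6",        # gray
    "N1": "cyan",
    "N2": "blue",
    "N3": "green",
    "R": "red",
    "LS": "blue",
    "DS": "green",
}


def plot_hypnodensity(
    h: Hypnodensity,
    consensus: Hypnogram | None = None,
    path=None,
    ax: plt.Axes | None = None,
):
    """Render the stacked probability bands; write to ``path`` if given."""
    created = ax is None
    if created:
        fig, ax = plt.subplots(figsize=(10, 2.5))
    t = np.arange(h.n_epochs) * h.epoch_minutes / 60.0  # hours
    stacks = [h.probs[:, i] for i in range(len(h.vocabulary))]
    colors = [STAGE_COLORS[s] for s in h.vocabulary.stages]
    ax.stackplot(t, *stacks, colors=colors, labels=h.vocabulary.stages, step="post")
    if consensus is not None:
        if consensus.n_epochs != h.n_epochs:
            raise AlignmentError("consensus hypnogram is not aligned")
        # map stages to descending levels so wake plots on top
        order = list(consensus.vocabulary.stages)
        levels = {s: 1.0 - i / len(order) for i, s in enumerate(order)}
        y = [levels[s] for s in consensus.stages]
        ax.step(t, y, where="post", color="black", linewidth=0.8, label="consensus")
    ax.set_xlim(0, t[-1] if t.size > 1 else 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("probability")
    ax.legend(loc="upper right", fontsize="x-small", ncol=len(h.vocabulary) + 1)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight",
                          metadata={"Software": None} if str(path).endswith(".png") else None)
    if created:
        plt.close(ax.figure)
    return ax
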