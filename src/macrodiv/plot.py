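"""Lineage-through-time plotting."""

from __future__ import annotations

import numpy as np

from .tree import TimeTree

__all__ = ["plot_ltt"]


def plot_ltt(trees, ax=None, log_lineages: bool = True, **kwargs):
    """Plot lineage-through-time curves for one or more chronograms.

    Each curve steps from 2 lineages at the crown age to n at the present;
    the lineage axis is logarithmic by default (a constant-rate pure-birth
    history is then a straight line).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if isinstance(trees, TimeTree):
        trees = [trees]
    for tree in trees:
        x = tree.branching_times()
        ages = np.concatenate([x, [0.0]])
        n_lin = np.arange(2, x.size + 3)
        ax.step(-ages, n_lin, where="post", **kwargs)
    ax.set_xlabel("time before present (My)")
    ax.set_ylabel("lineages")
    if log_lineages:
        ax.set_yscale("log")
    return ax
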