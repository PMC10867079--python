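"""Minimal matplotlib helpers for delta plots and CAFs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers may switch backends first

import matplotlib.pyplot as plt  # noqa: E402


def plot_delta(dp, ax=None, **kw):
    """Delta plot: per-quantile RT difference against mean RT."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(dp.x, dp.delta, marker="o", **kw)
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.set_xlabel("mean RT (ms)")
    ax.set_ylabel("incongruent − congruent RT (ms)")
    return ax


def plot_caf(caf, ax=None):
    """Conditional accuracy function, one line per condition."""
    if ax is None:
        _, ax = plt.subplots()
    for cond, accs in caf.accuracy.items():
        ax.plot(range(1, len(accs) + 1), accs, marker="o", label=cond)
    ax.set_xlabel("RT bin (fast → slow)")
    ax.set_ylabel("accuracy")
    ax.set_ylim(0, 1.02)
    ax.legend()
    return ax
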