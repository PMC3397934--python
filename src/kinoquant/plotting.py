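"""Matplotlib views of likelihood curves and RF distributions."""

from __future__ import annotations

import numpy as np

from .protein import DifferentialCall, rf_distribution


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_likelihood_curves(curves, labels=None, ax=None):
    """Peptide/protein relative-likelihood curves over the ratio axis.

    The vertical line at RF = 1 is the no-regulation reference a
    significant curve must separate from.
    """
    ax = _axes(ax)
    labels = labels or [None] * len(curves)
    for curve, label in zip(curves, labels):
        ax.plot(curve.grid, curve.rel_likelihood, label=label, lw=1)
    ax.axvline(1.0, color="0.4", ls="--", lw=1)
    ax.set_xscale("log")
    ax.set_xlabel("regulation ratio (Treg/Teff)")
    ax.set_ylabel("relative likelihood")
    if any(l is not None for l in labels):
        ax.legend(fontsize=7)
    return ax


def plot_rf_histogram(calls: list[DifferentialCall], bins=None, ax=None):
    """Histogram of log2 median expression ratios over the catalog."""
    ax = _axes(ax)
    values, counts, edges = rf_distribution(calls, bins=bins)
    ax.bar(0.5 * (edges[:-1] + edges[1:]), counts,
           width=np.diff(edges), color="0.6", edgecolor="0.2")
    ax.axvline(0.0, color="0.3", ls="--", lw=1)
    ax.set_xlabel("log2 RF (Treg/Teff)")
    ax.set_ylabel("proteins")
    return ax
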