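"""Minimal matplotlib views of profiles and occupancy comparisons."""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt


def plot_tss_enrichment(profile, groups=None, ax=None, path=None):
    """Mean 5hmC enrichment around the TSS, optionally per gene group.

    ``groups`` maps a label to a boolean row mask over the profile.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    if groups:
        for label, mask in groups.items():
            ax.plot(profile.bin_centers, profile.pooled_enrichment(mask), label=label)
        ax.legend(frameon=False)
    else:
        ax.plot(profile.bin_centers, profile.pooled_enrichment())
    ax.set_xlabel("distance from TSS (bp)")
    ax.set_ylabel("5hmC reads per CCGG site")
    if path:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax


def plot_occupancy_comparison(comparison, ax=None, path=None):
    """Mean scaled TF occupancy over 5hmC-positive vs -negative regions."""
    if comparison.profile_positive is None:
        raise ValueError(f"nothing to plot: {comparison.status}")
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    x = np.arange(len(comparison.profile_positive))
    ax.plot(x, comparison.profile_positive,
            label=f"5hmC+ (n={comparison.n_positive})", color="crimson")
    ax.plot(x, comparison.profile_negative,
            label=f"5hmC- (n={comparison.n_negative})", color="steelblue")
    if comparison.ks is not None:
        ax.set_title(f"KS D = {comparison.ks.D:.2f}, p = {comparison.ks.p:.1e}")
    ax.set_xlabel("scaled region bin")
    ax.set_ylabel("mean TF coverage")
    ax.legend(frameon=False)
    if path:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax
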