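"""Protein-ideogram rendering of a gene's mutational pattern.

Missense mutations are drawn as a Gaussian-smoothed density along the
protein, truncating mutations as tick marks — the landscape view in which
a tumor suppressor shows diffuse truncating marks and an oncogene a sharp
missense hotspot. The legend reports the counts of truncating sites
(distinct positions) and missense mutations.
"""

from __future__ import annotations

import numpy as np

from .functional_step import default_bandwidth, kernel_density
from .maf_io import GeneAggregate

__all__ = ["pattern_summary", "render_pattern"]


def pattern_summary(agg: GeneAggregate, bandwidth: float | None = None) -> dict:
    """Numeric summary of a gene's pattern: density, ticks and counts."""
    L = agg.protein_length or 1
    bw = bandwidth or default_bandwidth(L)
    if len(agg.mis_positions) >= 1 and L >= 2:
        density = kernel_density(agg.mis_positions, agg.mis_weights, L, bw)
    else:
        density = np.zeros(L)
    return {
        "gene": agg.gene,
        "protein_length": L,
        "density": density,
        "trunc_positions": sorted(agg.trunc_positions),
        "n_truncating_sites": len(set(agg.trunc_positions)),
        "n_truncating": agg.k_trunc,
        "n_missense": agg.k_mis,
        "mode_position": int(np.argmax(density)) + 1 if density.any() else None,
    }


def render_pattern(agg: GeneAggregate, bandwidth: float | None = None, ax=None):
    """Plot the pattern on a matplotlib axis (created if not given)."""
    import matplotlib

    if ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    summ = pattern_summary(agg, bandwidth)
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 2.5))
    L = summ["protein_length"]
    ax.fill_between(np.arange(1, L + 1), summ["density"], color="tab:blue", alpha=0.6, label=f"{summ['n_missense']} missense mutations")
    top = summ["density"].max() if summ["density"].any() else 1.0
    for i, pos in enumerate(summ["trunc_positions"]):
        ax.axvline(pos, color="tab:red", ymax=0.25, lw=1.2, label=f"{summ['n_truncating_sites']} truncating sites" if i == 0 else None)
    if not summ["trunc_positions"] and summ["n_truncating"]:
        # truncating mutations without a protein position still appear in the legend
        ax.plot([], [], color="tab:red", label=f"{summ['n_truncating']} truncating (no position)")
    ax.set_xlim(1, max(2, L))
    ax.set_ylim(bottom=0, top=max(top * 1.1, 1e-9))
    ax.set_xlabel("amino acid position")
    ax.set_ylabel("missense density")
    ax.set_title(agg.gene)
    ax.legend(loc="upper right", fontsize=8)
    return ax
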