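"""Optional figures: a three-set Venn of the selection branches and box
plots of qPCR fold changes.  Matplotlib only; figures are written to file
rather than shown."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

# fixed layout for a symmetric three-circle Venn
_CENTERS = {"bal": (-0.45, 0.3), "mepo": (0.45, 0.3), "sputum": (0.0, -0.5)}
_LABEL_POS = {
    "bal_only": (-0.75, 0.5), "mepo_only": (0.75, 0.5), "sputum_only": (0.0, -0.85),
    "bal_mepo": (0.0, 0.55), "bal_sputum": (-0.5, -0.25), "sputum_mepo": (0.5, -0.25),
    "all_three": (0.0, 0.0),
}


def plot_venn(result, path, title: str = "Selection branch overlap") -> None:
    """Draw the 7 disjoint region counts of a :class:`GeneSelectionResult`."""
    counts = result.region_counts()
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, (x, y) in _CENTERS.items():
        ax.add_patch(plt.Circle((x, y), 0.85, fill=False, lw=1.5))
    for region, (x, y) in _LABEL_POS.items():
        ax.text(x, y, str(counts[region]), ha="center", va="center", fontsize=12)
    ax.text(-1.1, 1.1, f"BAL up ({len(result.bal_up)})", fontsize=10)
    ax.text(0.55, 1.1, f"mepolizumab down ({len(result.mepo_down)})", fontsize=10)
    ax.text(0.0, -1.5, f"sputum EOS-associated ({len(result.sputum_assoc)})",
            ha="center", fontsize=10)
    ax.set_xlim(-1.8, 1.8)
    ax.set_ylim(-1.8, 1.8)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(title)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_fold_change_boxes(results, path, gene_order=None) -> None:
    """Box plots of 2^-ΔΔCt fold changes per gene and group.

    ``results`` is the output of ``delta_delta_ct_by_subject`` (must carry
    ``compartment`` and ``visit`` columns); groups mirror the validation
    figure: BAL V2, BAL V4 and purified EOS, all relative to BAL V1.
    """
    groups = [("BAL", "V2"), ("BAL", "V4"), ("purified_EOS", "V2")]
    genes = gene_order or sorted(results["gene"].unique())
    fig, axes = plt.subplots(1, len(genes), figsize=(2.2 * len(genes), 3.2),
                             sharey=False, squeeze=False)
    for ax, gene in zip(axes[0], genes):
        data, labels = [], []
        for comp, visit in groups:
            sel = results[(results["gene"] == gene)
                          & (results["compartment"] == comp)
                          & (results["visit"] == visit)]
            data.append(sel["fold_change"].to_numpy())
            labels.append("EOS" if comp == "purified_EOS" else visit)
        ax.boxplot(data, tick_labels=labels)
        ax.set_yscale("log")
        ax.set_title(gene, fontsize=10)
    axes[0][0].set_ylabel("fold change vs BAL V1 (2^-ΔΔCt)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
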