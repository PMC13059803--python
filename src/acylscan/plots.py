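"""Optional figures: UpSet-style intersections, conserved-prey dot plot,
replicate PCA scatter. All functions write a file and return its path;
matplotlib's Agg backend is forced so they work headless."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .conservation import PCAResult, PreyMembership, upset_counts


def plot_upset(membership: PreyMembership, path: str | Path, max_combos: int = 20) -> Path:
    """Exclusive-intersection bars over a membership dot matrix."""
    exclusive, marginals = upset_counts(membership)
    combos = sorted(exclusive.items(), key=lambda kv: -kv[1])[:max_combos]
    baits = list(membership.baits)

    fig, (ax_bar, ax_dots) = plt.subplots(
        2, 1, figsize=(max(6, 0.45 * len(combos)), 6),
        gridspec_kw={"height_ratios": [2, 1]}, sharex=True,
    )
    xs = np.arange(len(combos))
    ax_bar.bar(xs, [c for _, c in combos], color="0.25")
    ax_bar.set_ylabel("proteins in exclusive intersection")
    for x, (_, c) in zip(xs, combos):
        ax_bar.text(x, c, str(c), ha="center", va="bottom", fontsize=8)
    for x, (combo, _) in zip(xs, combos):
        for y, bait in enumerate(baits):
            inside = bait in combo
            ax_dots.plot(x, y, "o", color="0.1" if inside else "0.85", ms=6)
    ax_dots.set_yticks(range(len(baits)), baits)
    ax_dots.set_xticks([])
    ax_dots.set_ylim(-0.5, len(baits) - 0.5)
    ax_dots.invert_yaxis()
    fig.suptitle(f"prey intersections (marginals: {sum(marginals.values())} memberships)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_dotplot(table: pd.DataFrame, path: str | Path, adjp_max: float = 0.1) -> Path:
    """Dot plot of conserved prey: dot size ~ log2 fold change, color ~ adj-P;
    rows above the gate drawn gray."""
    proteins = list(dict.fromkeys(table["protein"]))
    baits = list(dict.fromkeys(table["bait"]))
    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * len(baits) + 2), max(3, 0.25 * len(proteins) + 1))
    )
    pi = {p: i for i, p in enumerate(proteins)}
    bi = {b: i for i, b in enumerate(baits)}
    ok = table[table["adj_p"] <= adjp_max]
    gray = table[table["adj_p"] > adjp_max]
    size = lambda lfc: 10 + 25 * np.clip(lfc, 0, None)
    sc = ax.scatter(
        [bi[b] for b in ok["bait"]], [pi[p] for p in ok["protein"]],
        s=size(ok["log2fc"]), c=ok["adj_p"], cmap="viridis_r", vmin=0, vmax=adjp_max,
    )
    ax.scatter(
        [bi[b] for b in gray["bait"]], [pi[p] for p in gray["protein"]],
        s=size(gray["log2fc"].clip(lower=0)), color="0.8",
    )
    fig.colorbar(sc, ax=ax, label="adjusted P")
    ax.set_xticks(range(len(baits)), baits, rotation=45, ha="right")
    ax.set_yticks(range(len(proteins)), proteins, fontsize=6)
    ax.invert_yaxis()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_pca(result: PCAResult, sample_conditions: dict[str, str], path: str | Path) -> Path:
    """PC1 vs PC2 scatter of replicates, colored by condition."""
    fig, ax = plt.subplots(figsize=(6, 5))
    conditions = list(dict.fromkeys(sample_conditions.values()))
    cmap = plt.get_cmap("tab10")
    for i, cond in enumerate(conditions):
        ids = [s for s, c in sample_conditions.items() if c == cond]
        sub = result.scores.loc[ids]
        ax.scatter(sub["PC1"], sub["PC2"], label=cond, color=cmap(i % 10), s=30)
    vf = result.variance_fraction
    ax.set_xlabel(f"PC1 ({100 * vf[0]:.1f}% of variance)")
    ax.set_ylabel(f"PC2 ({100 * vf[1]:.1f}% of variance)")
    ax.legend(fontsize=7, ncols=2)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
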