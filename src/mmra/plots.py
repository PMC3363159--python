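"""Basic Manhattan and LD-heatmap plots."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["manhattan", "ld_heatmap"]


def manhattan(records: pd.DataFrame, bonferroni_p: float | None = None,
              perm_p: float | None = None, path: str | None = None):
    """-log10(p) against cumulative map position, one colour per chromosome.

    Optional dotted lines mark the Bonferroni and permutation thresholds.
    """
    fig, ax = plt.subplots(figsize=(10, 4))
    offset = 0.0
    ticks, labels = [], []
    rec = records[records["tested"]] if "tested" in records else records
    for chrom, grp in rec.groupby("chromosome", sort=True):
        x = grp["pos_cm"].to_numpy() + offset
        ax.scatter(x, -np.log10(grp["p_raw"]), s=4)
        ticks.append(offset + grp["pos_cm"].mean())
        labels.append(str(chrom))
        offset += grp["pos_cm"].max() + 5
    if bonferroni_p is not None:
        ax.axhline(-np.log10(bonferroni_p), ls=":", c="magenta",
                   label="Bonferroni")
    if perm_p is not None:
        ax.axhline(-np.log10(perm_p), ls=":", c="black", label="permutation")
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10} p$")
    if bonferroni_p is not None or perm_p is not None:
        ax.legend(frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def _pair_colour(d_prime: float, lod: float) -> tuple:
    # Haploview scheme: LOD>2 & D'=1 red; LOD>2 & D'<1 pink; LOD<2 & D'=1 blue
    if np.isnan(d_prime):
        return (0.85, 0.85, 0.85)
    strong_d = d_prime > 0.99
    if lod > 2 and strong_d:
        return (1.0, 0.0, 0.0)
    if lod > 2:
        return (1.0, 1.0 - 0.7 * d_prime, 1.0 - 0.7 * d_prime)
    if strong_d:
        return (0.6, 0.75, 1.0)
    return (1.0, 1.0, 1.0)


def ld_heatmap(pairs: pd.DataFrame, snp_order: list[str],
               path: str | None = None):
    """Upper-triangle D' heatmap coloured by the Haploview LOD/D' scheme."""
    m = len(snp_order)
    pos = {s: i for i, s in enumerate(snp_order)}
    img = np.ones((m, m, 3))
    for _, r in pairs.iterrows():
        if r["snp_i"] not in pos or r["snp_j"] not in pos:
            continue
        i, j = pos[r["snp_i"]], pos[r["snp_j"]]
        img[min(i, j), max(i, j)] = _pair_colour(r["d_prime"], r["lod"])
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(img, interpolation="nearest")
    ax.set_xticks(range(m), snp_order, rotation=90, fontsize=6)
    ax.set_yticks(range(m), snp_order, fontsize=6)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
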