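"""Basic plotting: a Manhattan plot for association-scan results."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["manhattan"]


def manhattan(scan: pd.DataFrame, snp_map: pd.DataFrame | None = None,
              out_path=None, alpha: float = 0.05):
    """-log10(p) per SNP, colored by chromosome, with the Bonferroni line.

    Parameters
    ----------
    scan : DataFrame
        Association results with columns ``id`` and ``p_value``.
    snp_map : DataFrame, optional
        Columns ``snp``, ``chrom``, ``pos``; without it SNPs are plotted in
        scan order on one pseudo-chromosome.
    out_path : path, optional
        Written as PNG when given; the figure is returned either way.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = scan[["id", "p_value"]].copy()
    if snp_map is not None:
        m = snp_map.set_index("snp")
        df["chrom"] = m.reindex(df["id"])["chrom"].values
        df["pos"] = m.reindex(df["id"])["pos"].values
        df = df.sort_values(["chrom", "pos"])
    else:
        df["chrom"] = 1
        df["pos"] = np.arange(len(df))

    fig, ax = plt.subplots(figsize=(9, 3))
    x0 = 0
    for i, (_, grp) in enumerate(df.groupby("chrom", sort=True)):
        x = x0 + np.arange(len(grp))
        ax.scatter(x, -np.log10(np.maximum(grp["p_value"], 1e-300)),
                   s=4, color="C0" if i % 2 == 0 else "C1")
        x0 += len(grp)
    threshold = alpha / len(df)
    ax.axhline(-np.log10(threshold), color="red", lw=0.8, ls="--")
    ax.set_xlabel("SNP index (by chromosome)")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig
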