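"""Manhattan plot of the association scan."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["manhattan_plot"]


def manhattan_plot(results: pd.DataFrame, path=None, threshold: float = 1e-13,
                   ax=None):
    """-log10(P) against cumulative genome position, chromosomes in
    alternating shades, candidate threshold as a dashed line. ``results``
    is an association scan table; filtered-out sites are skipped."""
    tested = results[results["passed_filters"]].copy()
    tested["neglog10p"] = -np.log10(np.clip(tested["pvalue"], 1e-300, None))
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3.2))
    offset = 0
    ticks, labels = [], []
    for i, (chrom, grp) in enumerate(tested.groupby("chrom", sort=False)):
        x = grp["pos"].to_numpy() + offset
        ax.scatter(x, grp["neglog10p"], s=4,
                   color="#30507a" if i % 2 == 0 else "#7a9cc4", rasterized=True)
        ticks.append(offset + grp["pos"].max() / 2)
        labels.append(str(chrom))
        offset += int(grp["pos"].max())
    ax.axhline(-np.log10(threshold), ls="--", color="firebrick", lw=1)
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10} P$")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
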