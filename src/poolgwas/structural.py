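"""Coverage-window screen for structural polymorphisms.

Copy-number regions collapsed onto a single-copy reference show up in
Pool-Seq as excess coverage in the carrier pool, so the screen tiles each
chromosome into fixed windows (default 200 bp), compares mean per-site
total depth between the two merged groups, and flags windows where a large
coverage difference co-occurs with significant allele-frequency divergence.
Because a high-copy amplification in a single pooled individual can mimic a
group-wide CNV, flagged windows are checked against single-fly coverage
profiles: a window driven by one outlier individual is demoted.

Unlike the SNP filters, depth here includes all six count fields (it is
read depth, not allele evidence), and the scan is meant to run on sync data
without repeat masking or high-coverage removal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .syncio import SyncData

__all__ = [
    "window_coverage",
    "flag_divergent_windows",
    "individual_heterogeneity",
    "HeterogeneityVerdict",
]


def window_coverage(sync: SyncData, window: int = 200,
                    sig_threshold: float = 1e-13,
                    association: pd.DataFrame | None = None,
                    chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Tile each chromosome into ``window``-bp windows (0-based half-open,
    starting at the chromosome start) and average per-site total depth of
    the merged D and ND groups; positions absent from the sync contribute
    zero depth. ``association`` (a scan run without the high-coverage and
    repeat filters) supplies the significant-SNP count per window.

    Returns chrom, start, end, mean_cov_D, mean_cov_ND, diff, n_sig_snps.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if sync.n_libraries != 2:
        raise ValueError("window_coverage expects merged (D, ND) data")
    depth = sync.counts.sum(axis=2)  # all 6 fields: read depth
    sig_pos: dict[str, np.ndarray] = {}
    if association is not None:
        sig = association[association["passed_filters"]
                          & (association["pvalue"] < sig_threshold)]
        for chrom, grp in sig.groupby("chrom"):
            sig_pos[chrom] = grp["pos"].to_numpy()
    chroms = dict.fromkeys(sync.chrom.tolist())  # order of appearance
    rows = []
    for chrom in chroms:
        on = sync.chrom == chrom
        pos = sync.pos[on]
        length = (chrom_lengths or {}).get(chrom, int(pos.max()))
        edges = np.arange(0, length + window, window)
        edges[-1] = min(edges[-1], length)
        if edges[-1] == edges[-2]:
            edges = edges[:-1]
        widx = (pos - 1) // window
        d_sum = np.bincount(widx, weights=depth[on, 0], minlength=len(edges) - 1)
        nd_sum = np.bincount(widx, weights=depth[on, 1], minlength=len(edges) - 1)
        widths = np.diff(edges).astype(float)
        sp = sig_pos.get(chrom, np.empty(0, dtype=int))
        n_sig = np.bincount((sp - 1) // window, minlength=len(edges) - 1) \
            if sp.size else np.zeros(len(edges) - 1, dtype=int)
        for w in range(len(edges) - 1):
            mean_d = d_sum[w] / widths[w]
            mean_nd = nd_sum[w] / widths[w]
            rows.append({"chrom": chrom, "start": int(edges[w]), "end": int(edges[w + 1]),
                         "mean_cov_D": mean_d, "mean_cov_ND": mean_nd,
                         "diff": mean_d - mean_nd, "n_sig_snps": int(n_sig[w])})
    return pd.DataFrame(rows)


def flag_divergent_windows(windows: pd.DataFrame, min_abs_diff: float = 30.0,
                           require_sig: bool = True) -> pd.DataFrame:
    """Windows with |coverage difference| >= ``min_abs_diff`` and, when
    ``require_sig``, at least one significant SNP inside."""
    flagged = windows[windows["diff"].abs() >= min_abs_diff]
    if require_sig:
        flagged = flagged[flagged["n_sig_snps"] >= 1]
    return flagged.reset_index(drop=True)


@dataclass
class HeterogeneityVerdict:
    verdict: str  # single_individual_driven | shared | inconclusive
    outliers: list  # individual ids with depth > ratio * median


def individual_heterogeneity(depths, ratio: float = 3.0) -> HeterogeneityVerdict:
    """Classify a flagged window from single-fly depths.

    ``depths``: per-individual mean window depth (Series keyed by individual
    id, or array). An individual is an outlier if its depth exceeds
    ``ratio`` times the median of all individuals. Exactly one outlier:
    single_individual_driven (the pooled signal comes from one fly's
    amplification); two or more: shared; none: inconclusive.
    """
    s = pd.Series(depths)
    if len(s) < 3:
        raise ValueError("need at least 3 individuals")
    med = float(s.median())
    outliers = s[s > ratio * med]
    if len(outliers) == 1:
        verdict = "single_individual_driven"
    elif len(outliers) >= 2:
        verdict = "shared"
    else:
        verdict = "inconclusive"
    return HeterogeneityVerdict(verdict, list(outliers.index))
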