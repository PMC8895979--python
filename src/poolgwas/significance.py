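"""Label-permutation null distribution and empirical false discovery rate.

Shuffling the Dormant / Non-Dormant labels of the 8 replicate libraries
before merging yields every way chance alone could have produced the
observed contrast: for 2k libraries split k/k there are C(2k, k)/2 - 1
distinct relabelings once a partition and its mirror image are identified
and the real assignment is excluded (34 for the 8-library design). Each
relabeled dataset is pushed through the identical merge-filter-test
pipeline; the resulting null P-value distributions absorb whatever
overdispersion the real data carry, which is what makes the empirical FDR
honest where the nominal chi-squared null is not.

An alternative parametric null (binomial resampling of both groups from the
pooled allele frequency at the observed coverages) is provided for designs
where exhaustive permutation is too coarse.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from .association import association_scan
from .syncio import SyncData, extract_biallelic, merge_groups

__all__ = [
    "Partition",
    "NullDistribution",
    "enumerate_partitions",
    "permutation_null",
    "parametric_null",
    "empirical_fdr",
    "snp_q_values",
    "bh_adjust",
]


@dataclass(frozen=True)
class Partition:
    """Unordered split of the libraries into two equal pseudo-groups,
    canonicalized so group1 contains the lexicographically smallest id."""

    group1: frozenset
    group2: frozenset

    @classmethod
    def make(cls, group1, group2) -> "Partition":
        g1, g2 = frozenset(group1), frozenset(group2)
        if g1 & g2:
            raise ValueError("groups overlap")
        if min(g2) < min(g1):
            g1, g2 = g2, g1
        return cls(g1, g2)

    def assignment(self) -> dict:
        return {**{lib: "D" for lib in self.group1},
                **{lib: "ND" for lib in self.group2}}


def enumerate_partitions(library_ids, group_size: int,
                         original=None) -> list[Partition]:
    """All distinct k/k relabelings of the libraries, one per
    partition/complement pair, excluding ``original`` (an iterable of the
    libraries in one real group) when given. 8 libraries, k = 4 -> 34."""
    libs = list(library_ids)
    if len(set(libs)) != len(libs):
        raise ValueError("duplicate library ids")
    if len(libs) != 2 * group_size:
        raise ValueError(f"{len(libs)} libraries cannot split into two "
                         f"groups of {group_size}")
    all_libs = set(libs)
    skip = None
    if original is not None:
        orig = set(original)
        if not orig < all_libs or len(orig) != group_size:
            raise ValueError("original group must be a size-k subset of the libraries")
        skip = Partition.make(orig, all_libs - orig)
    anchor = min(libs)  # fixing the smallest id in group1 kills the mirror image
    rest = sorted(all_libs - {anchor})
    parts = []
    for combo in combinations(rest, group_size - 1):
        g1 = {anchor, *combo}
        part = Partition.make(g1, all_libs - g1)
        if part != skip:
            parts.append(part)
    return parts


@dataclass
class NullDistribution:
    """Per-partition null P-value vectors from the relabeled datasets."""

    partitions: list[Partition]
    pvalues: list[np.ndarray]

    @property
    def min_pvalues(self) -> np.ndarray:
        return np.array([v.min() if v.size else np.nan for v in self.pvalues])

    @property
    def n_tested(self) -> np.ndarray:
        return np.array([v.size for v in self.pvalues])

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "partition": ["|".join(sorted(p.group1)) for p in self.partitions],
            "n_snps": self.n_tested,
            "min_pvalue": self.min_pvalues,
        })


def permutation_null(sync: SyncData, partitions: list[Partition],
                     original=None, **scan_kwargs) -> NullDistribution:
    """Re-run merge + biallelic extraction + filters + chi-squared for every
    permuted label assignment, with the same parameters as the observed
    scan. ``original`` (one real group's libraries) is rejected if present
    among the partitions."""
    if original is not None:
        skip = Partition.make(set(original), set(sync.libraries) - set(original))
        if any(p == skip for p in partitions):
            raise ValueError("partition list contains the original assignment")
    pvals = []
    for part in partitions:
        unknown = (part.group1 | part.group2) - set(sync.libraries)
        if unknown:
            raise ValueError(f"partition references unknown libraries: {sorted(unknown)}")
        merged = merge_groups(sync, part.assignment())
        res = association_scan(extract_biallelic(merged), **scan_kwargs)
        pvals.append(res.loc[res["passed_filters"], "pvalue"].to_numpy())
    return NullDistribution(list(partitions), pvals)


def parametric_null(bi: pd.DataFrame, n_datasets: int = 34, seed: int = 0,
                    n_chrom: float | None = None,
                    **scan_kwargs) -> NullDistribution:
    """Simulated null: both groups redrawn at their observed coverages from
    the pooled allele frequency of each site, then filtered and tested as
    usual.

    ``n_chrom`` adds the pool's own sampling layer: each group's latent
    frequency is first drawn as Binomial(n_chrom, pooled)/n_chrom before
    reads are sampled, so the null carries the same overdispersion as a
    design with that many effective chromosomes per group; it is also
    forwarded to the scan, so ``adjusted=True`` tests the null datasets
    exactly as the observed one. Without it the null is pure read sampling.
    """
    if n_chrom:
        scan_kwargs.setdefault("n_chrom", n_chrom)
    rng = np.random.default_rng(seed)
    cov_d = (bi["d_major"] + bi["d_minor"]).to_numpy()
    cov_nd = (bi["nd_major"] + bi["nd_minor"]).to_numpy()
    pooled = (bi["d_major"] + bi["nd_major"]).to_numpy() / np.maximum(cov_d + cov_nd, 1)
    pvals = []
    for _ in range(n_datasets):
        if n_chrom:
            m = int(round(n_chrom))
            p_d = rng.binomial(m, pooled) / m
            p_nd = rng.binomial(m, pooled) / m
        else:
            p_d = p_nd = pooled
        d_major = rng.binomial(cov_d, p_d)
        nd_major = rng.binomial(cov_nd, p_nd)
        null_bi = bi.assign(d_major=d_major, d_minor=cov_d - d_major,
                            nd_major=nd_major, nd_minor=cov_nd - nd_major)
        res = association_scan(null_bi, **scan_kwargs)
        pvals.append(res.loc[res["passed_filters"], "pvalue"].to_numpy())
    return NullDistribution([], pvals)


def empirical_fdr(observed_p, null_pvalues, thresholds) -> pd.DataFrame:
    """q(t) = mean null discovery count at t / observed discovery count at t.

    ``null_pvalues`` is a list of per-dataset null P-value vectors (sets may
    differ in size after filtering; only counts enter). q is capped at 1 and
    NaN where the observed scan has no discovery at t. Ties count
    inclusively (p <= t).
    """
    observed_p = np.asarray(observed_p, dtype=float)
    if observed_p.size == 0:
        raise ValueError("empty observed P-value vector")
    if not null_pvalues:
        raise ValueError("need at least one null P-value vector")
    thresholds = np.atleast_1d(np.asarray(thresholds, dtype=float))
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie in (0, 1)")
    obs_sorted = np.sort(observed_p)
    null_sorted = [np.sort(np.asarray(v, dtype=float)) for v in null_pvalues]
    rows = []
    for t in thresholds:
        n_obs = int(np.searchsorted(obs_sorted, t, side="right"))
        mean_null = float(np.mean([np.searchsorted(v, t, side="right")
                                   for v in null_sorted]))
        q = min(1.0, mean_null / n_obs) if n_obs > 0 else np.nan
        rows.append({"threshold": t, "n_observed": n_obs,
                     "mean_null": mean_null, "q": q})
    return pd.DataFrame(rows)


def smallest_threshold(qtable: pd.DataFrame, alpha: float = 0.05) -> float | None:
    """Smallest tested threshold with q <= alpha, or None."""
    ok = qtable.dropna(subset=["q"])
    ok = ok[ok["q"] <= alpha]
    return float(ok["threshold"].min()) if len(ok) else None


def snp_q_values(observed_p, null_pvalues) -> np.ndarray:
    """Per-SNP empirical q: q evaluated at each observed P-value."""
    observed_p = np.asarray(observed_p, dtype=float)
    obs_sorted = np.sort(observed_p)
    null_sorted = [np.sort(np.asarray(v, dtype=float)) for v in null_pvalues]
    n_obs = np.searchsorted(obs_sorted, observed_p, side="right")
    mean_null = np.mean([np.searchsorted(v, observed_p, side="right")
                         for v in null_sorted], axis=0)
    return np.minimum(1.0, mean_null / n_obs)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted P-values (convenience report only; the
    study's multiple-testing control is the empirical FDR above)."""
    return false_discovery_control(np.asarray(pvalues, dtype=float), method="bh")
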