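"""Allele-count association between the merged Dormant / Non-Dormant pools.

The scan filters biallelic SNPs (minimum per-group coverage, minor-allele
count, removal of the highest-coverage tail), tests each 2x2 allele-count
table with a Pearson chi-squared test (df = 1, no continuity correction),
and reports the natural-log odds ratio with the Haldane-Anscombe zero-cell
correction as the SNP effect proxy. Coverage here means the sum of the two
allele counts — third alleles, Ns and deletions never count.

Pooled extreme-group designs are overdispersed relative to binomial read
sampling: the pool contains a finite number of founder chromosomes, so the
two groups differ in true allele frequency even under the null. The
``adjusted=True`` variant rescales each group's counts to the effective
sample size n_eff = n_chrom * cov / (n_chrom + cov), which restores the
nominal chi-squared null when n_chrom reflects the design (see
:func:`effective_chromosomes` for isofemale-strain pools).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

__all__ = [
    "apply_snp_filters",
    "chi_squared_test",
    "log_odds_ratio",
    "effective_chromosomes",
    "association_scan",
    "call_candidates",
    "genes_with_multiple_candidates",
    "read_gene_intervals",
]

FILTER_OK = "ok"
FILTER_LOW_COVERAGE = "low_coverage"
FILTER_LOW_MINOR = "low_minor"
FILTER_HIGH_TAIL = "high_coverage_tail"


def apply_snp_filters(bi: pd.DataFrame, min_cov: int = 15, min_minor: int = 8,
                      tail: float = 0.02) -> pd.DataFrame:
    """Flag SNPs for the association test.

    Keeps a site iff both groups have coverage (major + minor count) of at
    least ``min_cov`` and the minor allele count reaches ``min_minor`` in at
    least one group; then removes the ceil(tail * n_passing) passing sites
    with the highest combined coverage (ties broken by coverage, chrom, pos
    so exactly that many go). Adds ``passed_filters`` and ``filter_reason``
    columns; does not drop rows.
    """
    if min_cov < 0 or min_minor < 0 or tail < 0:
        raise ValueError("filter thresholds must be nonnegative")
    out = bi.copy()
    cov_d = out["d_major"] + out["d_minor"]
    cov_nd = out["nd_major"] + out["nd_minor"]
    reason = np.full(len(out), FILTER_OK, dtype=object)
    low_minor = ~((out["d_minor"] >= min_minor) | (out["nd_minor"] >= min_minor))
    reason[low_minor.to_numpy()] = FILTER_LOW_MINOR
    low_cov = (cov_d < min_cov) | (cov_nd < min_cov)
    reason[low_cov.to_numpy()] = FILTER_LOW_COVERAGE
    passing = reason == FILTER_OK
    n_remove = math.ceil(tail * int(passing.sum()))
    if n_remove > 0:
        total_cov = (cov_d + cov_nd).to_numpy()
        idx = np.flatnonzero(passing)
        order = sorted(idx, key=lambda i: (-total_cov[i], out["chrom"].iat[i],
                                           out["pos"].iat[i]))
        reason[order[:n_remove]] = FILTER_HIGH_TAIL
    out["filter_reason"] = reason
    out["passed_filters"] = reason == FILTER_OK
    return out


def chi_squared_test(a, b, c, d):
    """Pearson chi-squared (df = 1, no continuity correction) on the 2x2
    table [[a, b], [c, d]] via the closed form N(ad - bc)^2 / (r1 r2 c1 c2).

    Accepts scalars or aligned arrays; a zero margin yields statistic 0 and
    P = 1 with a warning. Returns (statistic, pvalue).
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    den = (a + b) * (c + d) * (a + c) * (b + d)
    degenerate = den == 0
    if np.any(degenerate):
        warnings.warn("degenerate 2x2 table (zero margin): statistic 0, P = 1")
    num = n * (a * d - b * c) ** 2
    stat = np.where(degenerate, 0.0, num / np.where(degenerate, 1.0, den))
    pval = stats.chi2.sf(stat, df=1)
    pval = np.where(degenerate, 1.0, pval)
    if stat.ndim == 0:
        return float(stat), float(pval)
    return stat, pval


def log_odds_ratio(a, b, c, d, ha_correction: bool = True,
                   unconditional: bool = False):
    """Natural-log odds ratio ln((a d)/(b c)) of the 2x2 table.

    With ``ha_correction`` (default) the Haldane-Anscombe 0.5 is added to
    all four cells of any table containing a zero count, so the ratio stays
    finite; ``unconditional=True`` adds 0.5 everywhere. All-zero tables are
    undefined.
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    if np.any(a + b + c + d == 0):
        raise ValueError("log odds ratio undefined for all-zero table")
    any_zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    adj = 0.5 * (any_zero | unconditional) if ha_correction or unconditional else 0.0
    adj = np.asarray(adj, dtype=float)
    lor = np.log(((a + adj) * (d + adj)) / ((b + adj) * (c + adj)))
    return float(lor) if lor.ndim == 0 else lor


def effective_chromosomes(pool_strains: int, pool_replicates: int,
                          founder_haplotypes: int = 4) -> float:
    """Effective number of independently sampled chromosomes per merged
    group in an isofemale-strain pool design.

    With s strains carrying at most h founder haplotypes and one fly per
    strain in each of r replicate pools, the variance of the merged pool
    allele frequency is pq/s * (1/h + (1 - 1/h)/(2r)); the reciprocal of the
    bracket times s is the effective chromosome count (72.7 for the default
    25 strains, 4 haplotypes, 4 replicates).
    """
    s, h, r = pool_strains, founder_haplotypes, pool_replicates
    if min(s, h, r) <= 0:
        raise ValueError("design counts must be positive")
    return s / (1.0 / h + (1.0 - 1.0 / h) / (2.0 * r))


def association_scan(bi: pd.DataFrame, min_cov: int = 15, min_minor: int = 8,
                     tail: float = 0.02, adjusted: bool = False,
                     n_chrom: float | None = None,
                     ha_unconditional: bool = False) -> pd.DataFrame:
    """Filter + test every biallelic SNP; the Manhattan table.

    Returns the input with filter flags plus chi2, pvalue and ln_or columns
    (NaN for filtered-out sites). ``adjusted=True`` rescales counts to the
    effective sample size before testing (requires ``n_chrom``); the log
    odds ratio always uses the raw counts.
    """
    if adjusted and not n_chrom:
        raise ValueError("adjusted test requires n_chrom (see effective_chromosomes)")
    res = apply_snp_filters(bi, min_cov=min_cov, min_minor=min_minor, tail=tail)
    ok = res["passed_filters"].to_numpy()
    a = res["d_major"].to_numpy(float)[ok]
    b = res["d_minor"].to_numpy(float)[ok]
    c = res["nd_major"].to_numpy(float)[ok]
    d = res["nd_minor"].to_numpy(float)[ok]
    if adjusted:
        s_d = n_chrom / (n_chrom + a + b)
        s_nd = n_chrom / (n_chrom + c + d)
        stat, pval = chi_squared_test(a * s_d, b * s_d, c * s_nd, d * s_nd)
    else:
        stat, pval = chi_squared_test(a, b, c, d)
    lor = log_odds_ratio(a, b, c, d, unconditional=ha_unconditional)
    for col in ("chi2", "pvalue", "ln_or"):
        res[col] = np.nan
    res.loc[ok, "chi2"] = stat
    res.loc[ok, "pvalue"] = pval
    res.loc[ok, "ln_or"] = lor
    return res


def call_candidates(results: pd.DataFrame, threshold: float = 1e-13) -> pd.DataFrame:
    """Candidate SNPs: filtered sites with P strictly below ``threshold``.

    Adds ``or_percentile``, the percentile rank of each candidate's |ln OR|
    among all filtered SNPs (100 = largest effect).
    """
    tested = results[results["passed_filters"]].copy()
    if tested.empty:
        return tested.assign(or_percentile=pd.Series(dtype=float))
    ranks = stats.rankdata(tested["ln_or"].abs(), method="average")
    tested["or_percentile"] = 100.0 * ranks / len(tested)
    return tested[tested["pvalue"] < threshold].copy()


def read_gene_intervals(gff_path) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees of gene bodies ([start, end] 1-based
    inclusive) from a GFF3 file, keyed for point queries at SNP positions."""
    import gffutils

    # gffutils is lenient; reject structurally broken lines with a location
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"GFF3 line {lineno}: expected 9 tab-separated "
                                 f"fields, got {len(parts)}")
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError:
                raise ValueError(f"GFF3 line {lineno}: non-integer coordinates") from None
            if start < 1 or end < start:
                raise ValueError(f"GFF3 line {lineno}: invalid interval "
                                 f"{start}-{end}")
    try:
        db = gffutils.create_db(str(gff_path), ":memory:", force=True,
                                keep_order=True,
                                merge_strategy="create_unique")
    except Exception as e:  # gffutils raises assorted types on bad input
        raise ValueError(f"cannot parse GFF3 file {gff_path}: {e}") from e
    trees: dict[str, IntervalTree] = {}
    for gene in db.features_of_type("gene"):
        gene_id = gene.attributes.get("ID", [gene.id])[0]
        trees.setdefault(gene.seqid, IntervalTree()).addi(
            gene.start, gene.end + 1, gene_id)
    return trees


def genes_with_multiple_candidates(candidates: pd.DataFrame, gff_path,
                                   min_snps: int = 2) -> pd.DataFrame:
    """Genes carrying at least ``min_snps`` candidate SNPs inside the gene
    body (strand-agnostic; a SNP in overlapping genes counts for each).
    Returns gene_id, n_candidates, positions, min_pvalue sorted by min P."""
    trees = read_gene_intervals(gff_path) if not isinstance(gff_path, dict) else gff_path
    hits: dict[str, dict] = {}
    for _, row in candidates.iterrows():
        tree = trees.get(row["chrom"])
        if tree is None:
            continue
        for iv in tree[int(row["pos"])]:
            h = hits.setdefault(iv.data, {"positions": [], "pvalues": []})
            h["positions"].append(int(row["pos"]))
            h["pvalues"].append(float(row["pvalue"]))
    rows = [{"gene_id": g, "n_candidates": len(h["positions"]),
             "positions": sorted(h["positions"]), "min_pvalue": min(h["pvalues"])}
            for g, h in hits.items() if len(h["positions"]) >= min_snps]
    out = pd.DataFrame(rows, columns=["gene_id", "n_candidates", "positions",
                                      "min_pvalue"])
    return out.sort_values("min_pvalue", ignore_index=True) if len(out) else out
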