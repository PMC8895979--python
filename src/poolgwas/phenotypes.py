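"""Strain-level dormancy phenotype analysis.

Summarizes per-fly assays into strain dormancy levels (fraction of flies
with oogenesis blocked up to stage 9), compares the two temperature regimes
with Wilcoxon signed-rank tests, partitions binary-outcome variance between
and within strains (one-way method-of-moments ICC), computes the
fly-number/power formula, and selects the extreme Dormant / Non-Dormant
strain sets that seed the sequencing pools.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExtremeGroups",
    "compute_dormancy_levels",
    "required_sample_size",
    "compare_temperatures",
    "variance_between_strains",
    "select_extreme_groups",
]

TEMPERATURES = ("10C", "12C")


def compute_dormancy_levels(flies: pd.DataFrame) -> pd.DataFrame:
    """Per-strain dormancy profile.

    ``flies`` needs columns strain, temperature ('10C'/'12C'), dormant,
    eggs. The dormancy level is the fraction of assayed flies that are
    dormant; mean eggs uses only flies that produced eggs (NaN when no fly
    did). Returns one row per strain with level_10, level_12, n_10, n_12,
    mean_eggs_10, mean_eggs_12; a strain-temperature cell with no flies
    yields NaN level (excluded later from paired tests).
    """
    required = {"strain", "temperature", "dormant", "eggs"}
    if not required.issubset(flies.columns):
        raise ValueError(f"missing columns: {sorted(required - set(flies.columns))}")
    out = {}
    for temp in TEMPERATURES:
        sub = flies[flies["temperature"] == temp]
        grp = sub.groupby("strain")
        level = grp["dormant"].mean()
        n = grp["dormant"].size()
        producers = sub[sub["eggs"] > 0]
        mean_eggs = producers.groupby("strain")["eggs"].mean()
        t = temp[:2]
        out[f"level_{t}"] = level
        out[f"n_{t}"] = n
        out[f"mean_eggs_{t}"] = mean_eggs
    profiles = pd.DataFrame(out)
    profiles.index.name = "strain"
    profiles["n_10"] = profiles["n_10"].fillna(0).astype(int)
    profiles["n_12"] = profiles["n_12"].fillna(0).astype(int)
    return profiles.reset_index()


def required_sample_size(p: float, a: float) -> int:
    """Minimum number of flies to observe the minor phenotype at least once.

    Smallest integer n with 1 - (1-a)^n >= p, where p is the required
    detection power and a the minor-phenotype frequency, i.e. the ceiling of
    log(1-p)/log(1-a). p = 0 returns 0.
    """
    if p == 0:
        return 0
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    if not 0 < a < 1:
        raise ValueError("a must be in (0, 1)")
    n = max(0, math.ceil(math.log1p(-p) / math.log1p(-a)))
    # settle floating-point boundary cases against the defining inequality
    while n > 0 and 1 - (1 - a) ** (n - 1) >= p:
        n -= 1
    while 1 - (1 - a) ** n < p:
        n += 1
    return n


@dataclass
class PairedTestResult:
    statistic: float
    pvalue: float
    n_pairs: int
    median_diff: float  # median of (value at 10C - value at 12C)


def _signed_rank(x: np.ndarray, y: np.ndarray) -> PairedTestResult:
    diff = x - y
    nz = diff != 0
    n_eff = int(nz.sum())
    if n_eff == 0:
        warnings.warn("all paired differences are zero; degenerate test, P = 1")
        return PairedTestResult(0.0, 1.0, len(x), 0.0)
    # exact null distribution for small samples without ties, else normal approx
    ties = len(np.unique(np.abs(diff[nz]))) < n_eff
    method = "exact" if (n_eff <= 25 and not ties) else "approx"
    res = stats.wilcoxon(x, y, zero_method="wilcox", method=method)
    return PairedTestResult(float(res.statistic), float(res.pvalue), len(x),
                            float(np.median(diff)))


def compare_temperatures(profiles: pd.DataFrame) -> dict[str, PairedTestResult]:
    """Paired Wilcoxon signed-rank tests between 10 and 12 °C, one for
    strain dormancy levels and one for mean egg counts. Strains missing
    either temperature (or either egg mean) are dropped from the respective
    test; zero differences are dropped (Wilcoxon's rule)."""
    lv = profiles.dropna(subset=["level_10", "level_12"])
    if len(lv) < 6:
        raise ValueError("need at least 6 strains with both temperatures")
    out = {"dormancy": _signed_rank(lv["level_10"].to_numpy(float),
                                    lv["level_12"].to_numpy(float))}
    eg = profiles.dropna(subset=["mean_eggs_10", "mean_eggs_12"])
    if len(eg) >= 6:
        out["eggs"] = _signed_rank(eg["mean_eggs_10"].to_numpy(float),
                                   eg["mean_eggs_12"].to_numpy(float))
    return out


def variance_between_strains(flies: pd.DataFrame, temperature: str) -> float:
    """Between-strain fraction of binary-outcome variance at one temperature.

    One-way random-effects intraclass correlation on the per-fly dormant
    indicator, estimated by method-of-moments ANOVA (unbalanced designs use
    the n0 coefficient); negative estimates are clamped to 0.
    """
    sub = flies[flies["temperature"] == temperature]
    groups = [g["dormant"].to_numpy(float) for _, g in sub.groupby("strain")]
    if len(groups) < 2:
        raise ValueError("need at least 2 strains")
    if any(len(g) < 2 for g in groups):
        raise ValueError("need at least 2 flies per strain")
    k = len(groups)
    n_i = np.array([len(g) for g in groups], dtype=float)
    N = n_i.sum()
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    ssb = float((n_i * (means - grand) ** 2).sum())
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    msb = ssb / (k - 1)
    msw = ssw / (N - k)
    n0 = (N - (n_i ** 2).sum() / N) / (k - 1)
    if msw == 0:
        return 1.0 if msb > 0 else 0.0
    sigma_b = (msb - msw) / n0
    icc = sigma_b / (sigma_b + msw)
    return float(min(1.0, max(0.0, icc)))


@dataclass
class ExtremeGroups:
    """The k most dormant (at 12 °C) and k least dormant (at 10 °C) strains,
    with centered-PCA coordinates of (level_10, level_12) for reporting."""

    dormant_strains: list[str]
    nondormant_strains: list[str]
    pca_coordinates: pd.DataFrame = field(repr=False, default=None)

    def assignment_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "strain": self.dormant_strains + self.nondormant_strains,
            "group": ["D"] * len(self.dormant_strains) + ["ND"] * len(self.nondormant_strains),
        })


def _pca_2d(levels: pd.DataFrame) -> pd.DataFrame:
    x = levels[["level_10", "level_12"]].to_numpy(float)
    centered = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # deterministic sign: largest-magnitude loading of each component positive
    for j in range(vt.shape[0]):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    coords = u * s
    return pd.DataFrame({"strain": levels["strain"].to_numpy(),
                         "PC1": coords[:, 0], "PC2": coords[:, 1]})


def select_extreme_groups(profiles: pd.DataFrame, k: int = 25) -> ExtremeGroups:
    """Pick the extreme phenotype pools.

    Non-Dormant: the k strains with the lowest dormancy level at 10 °C (ties
    by lower level at 12 °C, then strain id). Dormant: the k strains with
    the highest level at 12 °C (ties by higher level at 10 °C, then strain
    id). If the greedy sets contest a strain it goes to the group where its
    rank is more extreme (ties favour Non-Dormant) and the other group takes
    its next strain. Input row order never matters.
    """
    eligible = profiles.dropna(subset=["level_10", "level_12"]).copy()
    if len(eligible) < 2 * k:
        raise ValueError(f"need at least {2 * k} strains with both temperatures, "
                         f"have {len(eligible)}")
    nd_order = eligible.sort_values(
        ["level_10", "level_12", "strain"],
        ascending=[True, True, True])["strain"].tolist()
    d_order = eligible.sort_values(
        ["level_12", "level_10", "strain"],
        ascending=[False, False, True])["strain"].tolist()
    nd_rank = {s: i for i, s in enumerate(nd_order)}
    d_rank = {s: i for i, s in enumerate(d_order)}

    banned_nd: set[str] = set()
    banned_d: set[str] = set()
    while True:
        nd_sel = [s for s in nd_order if s not in banned_nd][:k]
        d_sel = [s for s in d_order if s not in banned_d][:k]
        contested = set(nd_sel) & set(d_sel)
        if not contested:
            break
        s = min(contested, key=lambda t: (min(nd_rank[t], d_rank[t]), t))
        if nd_rank[s] <= d_rank[s]:
            banned_d.add(s)
        else:
            banned_nd.add(s)
    return ExtremeGroups(dormant_strains=d_sel, nondormant_strains=nd_sel,
                         pca_coordinates=_pca_2d(eligible))
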