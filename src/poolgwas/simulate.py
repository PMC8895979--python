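"""Synthetic isofemale-strain Pool-GWAS data.

Emulates a bulked-segregant extreme-phenotype design for reproductive
dormancy in *Drosophila simulans*: isofemale strains founded by single mated
females (at most four founder haplotypes per locus), each strain phenotyped
with ~13 flies at two dormancy-inducing temperatures (10 and 12 °C), the 25
most extreme strains per phenotypic tail sequenced as 4 replicate pools per
group, with ~93x merged coverage per group.

The binary per-fly outcome (oogenesis blocked up to stage 9) follows a
liability-threshold model: a strain-level logistic liability composed of a
temperature intercept, additive causal-SNP effects and a Gaussian strain
random effect. With no causal loci the strain random effect is calibrated so
that a chosen fraction of the binary-outcome variance (default 25%, the
empirical 23-25% regime) lies between strains.

Sites are unlinked; reads are sampled per library from the replicate pool's
allele frequency with a uniform per-read miscall rate. Copy-number regions
multiply the depth contribution of carrier strains and weight their allele
contribution accordingly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import expit, logit

from .syncio import BASE_ORDER, SyncData

__all__ = [
    "CNVRegion",
    "SimulationConfig",
    "StrainPopulation",
    "simulate_strains",
    "simulate_phenotypes",
    "generate_pool_counts",
    "simulate_individual_coverage",
    "strain_sd_for_icc",
    "write_toy_gff",
]

# fixed sub-stream labels so each stage can be re-run independently
_STAGES = {"strains": 11, "phenotypes": 23, "pools": 37, "individuals": 53}


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STAGES[stage]]))


@dataclass(frozen=True)
class CNVRegion:
    """Copy-number region: carrier strains contribute ``copy_ratio`` times the
    normal read depth (and allele weight) at positions in [start, end]
    (1-based, inclusive, matching sync coordinates)."""

    chrom: str
    start: int
    end: int
    carriers: tuple[str, ...]
    copy_ratio: float = 2.0

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid CNV region {self.chrom}:{self.start}-{self.end}")
        if self.copy_ratio <= 0:
            raise ValueError("copy_ratio must be positive")


def _default_chrom_lengths() -> dict[str, int]:
    return {"2L": 8000, "2R": 8000, "3L": 8000, "3R": 8000, "X": 8000}


@dataclass
class SimulationConfig:
    """Design parameters of the simulated dormancy Pool-GWAS.

    Defaults reproduce the study design: 562 strains screened with 13 flies
    per strain per temperature, 25 strains per extreme group sequenced as 4
    replicate pools, ~93x merged coverage per group.
    """

    n_strains: int = 562
    n_sites: int = 10_000
    chrom_lengths: dict[str, int] = field(default_factory=_default_chrom_lengths)
    maf_alpha: float = 0.2  # U-shaped neutral-like founder frequency spectrum
    maf_beta: float = 0.2
    n_causal: int = 0
    effect_sizes: tuple[float, ...] = ()
    causal_freq_range: tuple[float, float] = (0.2, 0.8)
    mu10: float = logit(0.60)  # dormancy incidence higher at 10 than at 12 °C
    mu12: float = logit(0.35)
    strain_sd: float | None = None  # None -> calibrated to target_icc
    target_icc: float = 0.25
    flies_per_strain: int = 13
    pool_strains: int = 25
    pool_replicates: int = 4
    mean_coverage: float = 93.0
    error_rate: float = 0.001
    egg_mean_10: float = 8.0
    egg_mean_12: float = 15.0
    founder_haplotypes: int = 4  # single mated foundress
    cnv_regions: tuple[CNVRegion, ...] = ()
    seed: int = 0

    def __post_init__(self):
        for name in ("n_strains", "n_sites", "flies_per_strain", "pool_strains",
                     "pool_replicates", "founder_haplotypes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.error_rate < 0.25:
            raise ValueError("error_rate must be in [0, 0.25)")
        if self.maf_alpha <= 0 or self.maf_beta <= 0:
            raise ValueError("Beta shape parameters must be positive")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        if len(self.effect_sizes) != self.n_causal:
            raise ValueError("effect_sizes length must equal n_causal")
        if any(length <= 0 for length in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if self.n_sites > sum(self.chrom_lengths.values()):
            raise ValueError("n_sites exceeds total genome length")
        self.effect_sizes = tuple(float(e) for e in self.effect_sizes)
        self.cnv_regions = tuple(self.cnv_regions)
        if self.strain_sd is None:
            self.strain_sd = strain_sd_for_icc(self.target_icc, self.mu10, self.mu12)

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


def _icc_binary(mu: float, sd: float) -> float:
    """Observed-scale ICC of Bernoulli(expit(mu + sd*Z)), Z ~ N(0,1)."""
    if sd == 0:
        return 0.0

    def _moment(k):
        f = lambda z: expit(mu + sd * z) ** k * np.exp(-z * z / 2) / np.sqrt(2 * np.pi)
        return quad(f, -9, 9, limit=200)[0]

    m1, m2 = _moment(1), _moment(2)
    total = m1 * (1 - m1)
    return 0.0 if total <= 0 else (m2 - m1 * m1) / total


def strain_sd_for_icc(icc: float, mu10: float, mu12: float) -> float:
    """Strain random-effect SD whose mean binary-scale ICC across the two
    temperature intercepts equals ``icc``.

    The between-strain fraction of binary-outcome variance for a logistic
    random-intercept model is Var(p_s) / (p̄(1-p̄)) with
    p_s = expit(mu + sd*Z); this inverts that relation numerically.
    """
    if not 0 <= icc < 1:
        raise ValueError("icc must be in [0, 1)")
    if icc == 0:
        return 0.0
    f = lambda sd: 0.5 * (_icc_binary(mu10, sd) + _icc_binary(mu12, sd)) - icc
    return float(brentq(f, 1e-6, 25.0, xtol=1e-6))


@dataclass
class StrainPopulation:
    """Founder-allele dosages (0..4 of ``founder_haplotypes``) per strain and
    site, plus the site catalog (chrom, pos, ref, alt, freq, is_causal, effect)."""

    strain_ids: list[str]
    dosages: np.ndarray  # (n_strains, n_sites) uint8
    sites: pd.DataFrame
    config: SimulationConfig

    @property
    def n_strains(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    def strain_index(self, strain_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.strain_ids)}
        try:
            return np.array([lookup[s] for s in strain_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown strain id {e.args[0]!r}") from None


def _site_positions(config: SimulationConfig, rng: np.random.Generator):
    """Distribute n_sites over the genome: chromosomes drawn proportional to
    length, distinct positions within each chromosome, sorted."""
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    n_per = rng.multinomial(config.n_sites, lengths / lengths.sum())
    # a chromosome cannot host more distinct sites than positions
    for _ in range(1000):
        over = n_per - lengths.astype(int)
        if (over <= 0).all():
            break
        excess = int(over[over > 0].sum())
        n_per = np.minimum(n_per, lengths.astype(int))
        room = lengths.astype(int) - n_per
        give = rng.multinomial(excess, room / room.sum())
        n_per = n_per + give
    chrom_col, pos_col = [], []
    for c, n in zip(chroms, n_per):
        if n == 0:
            continue
        pos = np.sort(rng.choice(config.chrom_lengths[c], size=int(n), replace=False)) + 1
        chrom_col.extend([c] * int(n))
        pos_col.extend(pos.tolist())
    return np.array(chrom_col, dtype=object), np.array(pos_col, dtype=np.int64)


def simulate_strains(config: SimulationConfig) -> StrainPopulation:
    """Found the isofemale strains.

    Population allele frequencies are Beta(maf_alpha, maf_beta); each strain
    dosage is the sum of ``founder_haplotypes`` Bernoulli(freq) founder
    haplotypes, held fixed thereafter (no within-strain drift).
    Deterministic given ``config.seed``.
    """
    rng = _stage_rng(config.seed, "strains")
    chrom, pos = _site_positions(config, rng)
    freq = rng.beta(config.maf_alpha, config.maf_beta, config.n_sites)
    base_idx = rng.integers(0, 4, size=config.n_sites)
    alt_off = rng.integers(1, 4, size=config.n_sites)
    ref = np.array([BASE_ORDER[i] for i in base_idx], dtype=object)
    alt = np.array([BASE_ORDER[(i + o) % 4] for i, o in zip(base_idx, alt_off)], dtype=object)

    dosages = rng.binomial(config.founder_haplotypes, freq,
                           size=(config.n_strains, config.n_sites)).astype(np.uint8)

    is_causal = np.zeros(config.n_sites, dtype=bool)
    effect = np.zeros(config.n_sites)
    if config.n_causal:
        lo, hi = config.causal_freq_range
        eligible = np.flatnonzero((freq >= lo) & (freq <= hi))
        if eligible.size < config.n_causal:
            eligible = np.arange(config.n_sites)
        chosen = rng.choice(eligible, size=config.n_causal, replace=False)
        is_causal[chosen] = True
        effect[chosen] = config.effect_sizes

    sites = pd.DataFrame({
        "chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "freq": freq,
        "is_causal": is_causal, "effect": effect,
    })
    strain_ids = [f"S{i + 1:04d}" for i in range(config.n_strains)]
    return StrainPopulation(strain_ids, dosages, sites, config)


def simulate_phenotypes(population: StrainPopulation,
                        config: SimulationConfig | None = None) -> pd.DataFrame:
    """Per-fly dormancy assay at both temperatures.

    Each fly is dormant with probability
    expit(mu_T + sum_i effect_i * dosage_i / founder_haplotypes + strain_effect);
    non-dormant flies lay Poisson(egg_mean_T) eggs (fewer at 10 °C), dormant
    flies lay none. Returns a long table:
    strain, temperature ('10C'/'12C'), fly_id, dormant, eggs.
    """
    config = config or population.config
    rng = _stage_rng(config.seed, "phenotypes")
    n_strains = population.n_strains
    strain_eff = rng.normal(0.0, config.strain_sd, n_strains)
    causal = population.sites["is_causal"].to_numpy()
    genetic = np.zeros(n_strains)
    if causal.any():
        dos = population.dosages[:, causal].astype(float) / config.founder_haplotypes
        genetic = dos @ population.sites.loc[causal, "effect"].to_numpy()

    frames = []
    nf = config.flies_per_strain
    for temp, mu, egg_mean in (("10C", config.mu10, config.egg_mean_10),
                               ("12C", config.mu12, config.egg_mean_12)):
        p = expit(mu + genetic + strain_eff)
        dormant = rng.random((n_strains, nf)) < p[:, None]
        eggs = rng.poisson(egg_mean, size=(n_strains, nf))
        eggs[dormant] = 0
        frames.append(pd.DataFrame({
            "strain": np.repeat(population.strain_ids, nf),
            "temperature": temp,
            "fly_id": np.tile(np.arange(1, nf + 1), n_strains),
            "dormant": dormant.ravel(),
            "eggs": eggs.ravel(),
        }))
    return pd.concat(frames, ignore_index=True)


def _scatter_errors(rng, counts_by_base: np.ndarray, error_rate: float) -> np.ndarray:
    """Per-read miscall: each read switches to one of the 3 other bases
    uniformly with probability error_rate. counts_by_base: (n_sites, 4)."""
    if error_rate == 0:
        return counts_by_base
    out = counts_by_base.copy()
    for src in range(4):
        mis = rng.binomial(counts_by_base[:, src], error_rate)
        out[:, src] -= mis
        targets = [t for t in range(4) if t != src]
        x1 = rng.binomial(mis, 1 / 3)
        rem = mis - x1
        x2 = rng.binomial(rem, 1 / 2)
        x3 = rem - x2
        for t, x in zip(targets, (x1, x2, x3)):
            out[:, t] += x
    return out


def _cnv_weights(population: StrainPopulation, strain_rows: np.ndarray,
                 config: SimulationConfig) -> np.ndarray:
    """Per selected strain and site depth/allele weight (copy_ratio inside
    carried CNV regions, 1 elsewhere)."""
    n_sel, n_sites = strain_rows.size, population.n_sites
    w = np.ones((n_sel, n_sites))
    if not config.cnv_regions:
        return w
    chrom = population.sites["chrom"].to_numpy()
    pos = population.sites["pos"].to_numpy()
    ids = [population.strain_ids[r] for r in strain_rows]
    for region in config.cnv_regions:
        in_reg = (chrom == region.chrom) & (pos >= region.start) & (pos <= region.end)
        if not in_reg.any():
            continue
        carrier = np.array([s in set(region.carriers) for s in ids])
        w[np.ix_(carrier, in_reg)] = region.copy_ratio
    return w


def generate_pool_counts(population: StrainPopulation,
                         dormant_strains, nondormant_strains,
                         config: SimulationConfig | None = None
                         ) -> tuple[SyncData, pd.DataFrame]:
    """Sequence the extreme pools: 4 replicate libraries per group, one fly
    per selected strain per replicate.

    Per replicate and site the fly genotype is Binomial(2, dosage/4); reads
    are Poisson(mean_coverage / pool_replicates) deep and drawn from the
    pool allele frequency (CNV carriers weighted by copy ratio), then pushed
    through the uniform miscall model. Returns the 8-library sync data
    (D1..D4, ND1..ND4) and a truth table of planted causal SNPs.
    """
    config = config or population.config
    d_set, nd_set = set(dormant_strains), set(nondormant_strains)
    if d_set & nd_set:
        raise ValueError(f"strains assigned to both groups: {sorted(d_set & nd_set)}")
    rng = _stage_rng(config.seed, "pools")
    n_sites = population.n_sites
    ref = population.sites["ref"].to_numpy()
    alt = population.sites["alt"].to_numpy()
    ref_idx = np.array([BASE_ORDER.index(b) for b in ref])
    alt_idx = np.array([BASE_ORDER.index(b) for b in alt])
    lib_cov = config.mean_coverage / config.pool_replicates

    libraries, columns = [], []
    for group, strains in (("D", list(dormant_strains)), ("ND", list(nondormant_strains))):
        rows = population.strain_index(strains)
        if rows.size != config.pool_strains:
            raise ValueError(f"group {group}: expected {config.pool_strains} strains, "
                             f"got {rows.size}")
        dos = population.dosages[rows].astype(float)  # (k, n_sites)
        w = _cnv_weights(population, rows, config)
        depth_scale = w.mean(axis=0)  # copy-number depth multiplier per site
        for rep in range(1, config.pool_replicates + 1):
            g = rng.binomial(2, dos / config.founder_haplotypes)  # fly alt copies
            pool_freq = (w * g).sum(axis=0) / (2.0 * w.sum(axis=0))
            depth = rng.poisson(lib_cov * depth_scale, n_sites)
            alt_reads = rng.binomial(depth, pool_freq)
            counts4 = np.zeros((n_sites, 4), dtype=np.int64)
            counts4[np.arange(n_sites), ref_idx] += depth - alt_reads
            counts4[np.arange(n_sites), alt_idx] += alt_reads
            counts4 = _scatter_errors(rng, counts4, config.error_rate)
            col = np.zeros((n_sites, 6), dtype=np.int64)
            col[:, :4] = counts4
            libraries.append(f"{group}{rep}")
            columns.append(col)

    counts = np.stack(columns, axis=1)  # (n_sites, 8, 6)
    sync = SyncData(chrom=population.sites["chrom"].to_numpy().copy(),
                    pos=population.sites["pos"].to_numpy().copy(),
                    ref=ref.copy(), counts=counts, libraries=libraries)
    truth = population.sites.loc[population.sites["is_causal"],
                                 ["chrom", "pos", "ref", "alt", "freq", "effect"]]
    return sync, truth.reset_index(drop=True)


def simulate_individual_coverage(n_individuals: int = 12, base_depth: float = 25.0,
                                 carrier_indices=(), copy_ratio: float = 2.0,
                                 window: int = 200, seed: int = 0) -> pd.Series:
    """Window mean depths for single sequenced flies (the verification step
    of the structural screen): carriers at copy_ratio * base_depth, others at
    base_depth, Poisson noise averaged over ``window`` positions."""
    rng = _stage_rng(seed, "individuals")
    mean = np.full(n_individuals, base_depth)
    mean[list(carrier_indices)] *= copy_ratio
    depths = rng.poisson(mean[:, None] * np.ones(window)).mean(axis=1)
    return pd.Series(depths, index=[f"fly{i + 1:02d}" for i in range(n_individuals)])


def write_toy_gff(chrom_lengths: dict[str, int], path, gene_length: int = 2000,
                  gap: int = 1000) -> int:
    """Write a toy GFF3 of non-overlapping genes tiling each chromosome.
    Returns the number of genes written."""
    n = 0
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in chrom_lengths.items():
            start = 1
            while start + gene_length - 1 <= length:
                n += 1
                end = start + gene_length - 1
                fh.write(f"{chrom}\ttoy\tgene\t{start}\t{end}\t.\t+\t.\t"
                         f"ID=gene{n:04d};Name=gene{n:04d}\n")
                start = end + gap + 1
    return n
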