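"""PoPoolation2 synchronized-pileup ("sync") I/O and count-level processing.

A sync file is tab-separated: chromosome, 1-based position, reference base,
then one colon-separated ``A:T:C:G:N:del`` count column per sequencing
library. This module reads and writes the format bit-exactly, masks
repeat/TE positions from a BED file, thins counts to emulate read
down-sampling, merges replicate libraries into phenotype groups, and
extracts the biallelic 2x2 count tables the association scan consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

BASE_ORDER = "ATCG"
FIELDS = ("A", "T", "C", "G", "N", "del")

__all__ = [
    "BASE_ORDER",
    "SyncData",
    "SyncParseError",
    "read_sync",
    "write_sync",
    "read_bed",
    "mask_sites",
    "downsample_library",
    "equalize_libraries",
    "merge_groups",
    "extract_biallelic",
]


class SyncParseError(ValueError):
    pass


@dataclass
class SyncData:
    """Columnar sync container: per-site chromosome, 1-based position,
    reference base and an integer count array of shape (n_sites, n_libraries, 6)
    in A,T,C,G,N,del order."""

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    counts: np.ndarray
    libraries: list[str]

    def __post_init__(self):
        if self.counts.ndim != 3 or self.counts.shape[2] != 6:
            raise ValueError("counts must have shape (n_sites, n_libraries, 6)")
        if self.counts.shape[0] != len(self.pos) or self.counts.shape[1] != len(self.libraries):
            raise ValueError("inconsistent sync dimensions")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def n_sites(self) -> int:
        return self.counts.shape[0]

    @property
    def n_libraries(self) -> int:
        return self.counts.shape[1]

    def library_index(self, library: str) -> int:
        try:
            return self.libraries.index(library)
        except ValueError:
            raise KeyError(f"unknown library {library!r}") from None

    def subset(self, mask: np.ndarray) -> "SyncData":
        return SyncData(self.chrom[mask], self.pos[mask], self.ref[mask],
                        self.counts[mask], list(self.libraries))

    def copy(self) -> "SyncData":
        return SyncData(self.chrom.copy(), self.pos.copy(), self.ref.copy(),
                        self.counts.copy(), list(self.libraries))


def read_sync(path, libraries: list[str] | None = None) -> SyncData:
    """Parse a sync file. Malformed lines raise :class:`SyncParseError`
    naming the 1-based line number."""
    chroms, poss, refs, rows = [], [], [], []
    n_libs = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise SyncParseError(f"line {lineno}: expected at least 4 fields, "
                                     f"got {len(parts)}")
            if n_libs is None:
                n_libs = len(parts) - 3
            elif len(parts) - 3 != n_libs:
                raise SyncParseError(f"line {lineno}: expected {n_libs} library "
                                     f"columns, got {len(parts) - 3}")
            try:
                pos = int(parts[1])
            except ValueError:
                raise SyncParseError(f"line {lineno}: non-integer position "
                                     f"{parts[1]!r}") from None
            site = np.empty((n_libs, 6), dtype=np.int64)
            for j, col in enumerate(parts[3:]):
                vals = col.split(":")
                if len(vals) != 6:
                    raise SyncParseError(f"line {lineno}: library column {j + 1} has "
                                         f"{len(vals)} colon-fields, expected 6")
                try:
                    site[j] = [int(v) for v in vals]
                except ValueError:
                    raise SyncParseError(f"line {lineno}: non-integer count in "
                                         f"column {j + 1}: {col!r}") from None
            chroms.append(parts[0])
            poss.append(pos)
            refs.append(parts[2])
            rows.append(site)
    if n_libs is None:
        n_libs = 0
        counts = np.zeros((0, 0, 6), dtype=np.int64)
    else:
        counts = np.stack(rows) if rows else np.zeros((0, n_libs, 6), dtype=np.int64)
    if libraries is None:
        libraries = [f"lib{i + 1}" for i in range(n_libs)]
    elif len(libraries) != n_libs:
        raise ValueError(f"{len(libraries)} library names for {n_libs} columns")
    return SyncData(np.array(chroms, dtype=object), np.array(poss, dtype=np.int64),
                    np.array(refs, dtype=object), counts, list(libraries))


def write_sync(sync: SyncData, path) -> None:
    with open(path, "w") as fh:
        for i in range(sync.n_sites):
            cols = "\t".join(":".join(map(str, sync.counts[i, j]))
                             for j in range(sync.n_libraries))
            fh.write(f"{sync.chrom[i]}\t{sync.pos[i]}\t{sync.ref[i]}\t{cols}\n")


def read_bed(path) -> dict[str, IntervalTree]:
    """Read a BED file (0-based, half-open) into per-chromosome interval trees."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"BED line {lineno}: fewer than 3 fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"BED line {lineno}: start {start} >= end {end}")
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def mask_sites(sync: SyncData, bed) -> SyncData:
    """Drop sites falling in masked intervals (repeats/TEs). ``bed`` is a
    path or the mapping returned by :func:`read_bed`. A site at 1-based
    ``pos`` is removed iff ``pos - 1`` lies in an interval on its chromosome."""
    trees = read_bed(bed) if not isinstance(bed, dict) else bed
    keep = np.ones(sync.n_sites, dtype=bool)
    for chrom, tree in trees.items():
        on_chrom = np.flatnonzero(sync.chrom == chrom)
        for i in on_chrom:
            if tree.overlaps(int(sync.pos[i]) - 1):
                keep[i] = False
    return sync.subset(keep)


def downsample_library(sync: SyncData, library: str, fraction: float,
                       seed: int = 0) -> SyncData:
    """Binomially thin one library's counts — the count-level equivalent of
    subsampling a fraction of reads (``samtools view -s``)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    out = sync.copy()
    if fraction == 1.0:
        return out
    j = sync.library_index(library)
    rng = np.random.default_rng(seed)
    out.counts[:, j, :] = rng.binomial(sync.counts[:, j, :], fraction)
    return out


def equalize_libraries(sync: SyncData, target: int | None = None,
                       seed: int = 0) -> SyncData:
    """Thin every library to the same total count (default: the smallest
    library), emulating the equal-read-count down-sampling applied before
    merging replicates."""
    totals = sync.counts.sum(axis=(0, 2))
    if target is None:
        target = int(totals.min())
    if target <= 0:
        raise ValueError("target must be positive")
    out = sync.copy()
    rng = np.random.default_rng(seed)
    for j, tot in enumerate(totals):
        if tot > target:
            out.counts[:, j, :] = rng.binomial(sync.counts[:, j, :], target / tot)
    return out


def merge_groups(sync: SyncData, assignment: dict[str, str]) -> SyncData:
    """Sum replicate libraries into two phenotype groups. ``assignment`` maps
    every library name to 'D' or 'ND'; output column order is (D, ND)."""
    missing = [lib for lib in sync.libraries if lib not in assignment]
    if missing:
        raise ValueError(f"libraries not assigned to a group: {missing}")
    unknown = set(assignment) - set(sync.libraries)
    if unknown:
        raise ValueError(f"assignment names unknown libraries: {sorted(unknown)}")
    bad = {lib: g for lib, g in assignment.items() if g not in ("D", "ND")}
    if bad:
        raise ValueError(f"groups must be 'D' or 'ND': {bad}")
    d_idx = [j for j, lib in enumerate(sync.libraries) if assignment[lib] == "D"]
    nd_idx = [j for j, lib in enumerate(sync.libraries) if assignment[lib] == "ND"]
    if not d_idx or not nd_idx:
        raise ValueError("both groups must contain at least one library")
    merged = np.stack([sync.counts[:, d_idx, :].sum(axis=1),
                       sync.counts[:, nd_idx, :].sum(axis=1)], axis=1)
    return SyncData(sync.chrom.copy(), sync.pos.copy(), sync.ref.copy(),
                    merged, ["D", "ND"])


def extract_biallelic(sync: SyncData, strict: bool = False) -> pd.DataFrame:
    """Reduce merged (D, ND) counts to biallelic 2x2 tables.

    The two alleles are the two of A,T,C,G with the highest combined (D+ND)
    counts, ties broken in sync column order A,T,C,G; N and deletions are
    never alleles. Reads of a third/fourth allele are dropped from the table
    (or, with ``strict=True``, the whole site is dropped). Sites with fewer
    than two observed alleles are omitted. The major allele carries the
    larger combined count (same tie rule).

    Returns a DataFrame with columns chrom, pos, major, minor, d_major,
    d_minor, nd_major, nd_minor.
    """
    if sync.n_libraries != 2:
        raise ValueError("extract_biallelic expects merged data with exactly "
                         "2 libraries (D, ND)")
    base_counts = sync.counts[:, :, :4]  # N/del never alleles
    combined = base_counts.sum(axis=1)
    # stable argsort of negated counts: ties resolve in A,T,C,G column order
    order = np.argsort(-combined, axis=1, kind="stable")
    maj, mino = order[:, 0], order[:, 1]
    rows = np.arange(sync.n_sites)
    minor_comb = combined[rows, mino]
    keep = minor_comb > 0
    if strict:
        third = np.take_along_axis(combined, order[:, 2:], axis=1).sum(axis=1)
        keep &= third == 0
    maj, mino, rows = maj[keep], mino[keep], rows[keep]
    bases = np.array(list(BASE_ORDER), dtype=object)
    return pd.DataFrame({
        "chrom": sync.chrom[keep],
        "pos": sync.pos[keep],
        "major": bases[maj],
        "minor": bases[mino],
        "d_major": base_counts[rows, 0, maj],
        "d_minor": base_counts[rows, 0, mino],
        "nd_major": base_counts[rows, 1, maj],
        "nd_minor": base_counts[rows, 1, mino],
    })
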