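import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import poolgwas as pg
from poolgwas.syncio import SyncParseError
from conftest import standard_assignment


class TestReadWriteSync:
    def test_parse_two_library_line(self, tmp_path):
        p = tmp_path / "a.sync"
        p.write_text("2R\t100\tA\t10:0:2:0:0:0\t8:0:4:0:0:0\n")
        sync = pg.read_sync(p)
        assert sync.n_sites == 1 and sync.n_libraries == 2
        assert sync.chrom[0] == "2R" and sync.pos[0] == 100 and sync.ref[0] == "A"
        assert sync.counts[0, 0].tolist() == [10, 0, 2, 0, 0, 0]
        assert sync.counts[0, 1].tolist() == [8, 0, 4, 0, 0, 0]

    def test_round_trip_is_byte_identical(self, tmp_path, small_study):
        p1, p2 = tmp_path / "a.sync", tmp_path / "b.sync"
        pg.write_sync(small_study["sync"], p1)
        pg.write_sync(pg.read_sync(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert len(p1.read_text().splitlines()) == small_study["sync"].n_sites

    @pytest.mark.parametrize("line,match", [
        ("2R\t100\tA\t1:0:0:0:0\n", "colon-fields"),
        ("2R\t100\tA\t1:0:0:0:0:x\n", "non-integer count"),
        ("2R\tq\tA\t1:0:0:0:0:0\n", "non-integer position"),
        ("2R\t100\n", "at least 4 fields"),
        ("2R\t1\tA\t1:0:0:0:0:0\t1:0:0:0:0:0\n2R\t2\tA\t1:0:0:0:0:0\n", "line 2"),
    ])
    def test_malformed_lines_named(self, tmp_path, line, match):
        p = tmp_path / "bad.sync"
        p.write_text(line)
        with pytest.raises(SyncParseError, match=match):
            pg.read_sync(p)

    def test_library_names(self, tmp_path):
        p = tmp_path / "a.sync"
        p.write_text("2R\t1\tA\t1:0:0:0:0:0\t2:0:0:0:0:0\n")
        assert pg.read_sync(p).libraries == ["lib1", "lib2"]
        assert pg.read_sync(p, libraries=["D", "ND"]).libraries == ["D", "ND"]
        with pytest.raises(ValueError):
            pg.read_sync(p, libraries=["onlyone"])


class TestMasking:
    def _write_bed(self, tmp_path, lines):
        p = tmp_path / "mask.bed"
        p.write_text("".join(f"{c}\t{s}\t{e}\n" for c, s, e in lines))
        return p

    def test_zero_based_half_open_convention(self, tmp_path, toy_sync):
        bed = self._write_bed(tmp_path, [("2R", 99, 100)])
        masked = pg.mask_sites(toy_sync, bed)
        # removes exactly 1-based position 100 on 2R
        assert masked.n_sites == 2
        assert 100 not in masked.pos[masked.chrom == "2R"]

    def test_empty_bed_is_identity(self, tmp_path, toy_sync):
        bed = self._write_bed(tmp_path, [])
        assert pg.mask_sites(toy_sync, bed).n_sites == toy_sync.n_sites

    def test_invalid_interval_rejected(self, tmp_path, toy_sync):
        bed = self._write_bed(tmp_path, [("2R", 100, 100)])
        with pytest.raises(ValueError, match="start"):
            pg.mask_sites(toy_sync, bed)

    def test_overlapping_intervals_act_as_union(self, tmp_path, small_study):
        sync = small_study["sync"]
        intervals = [("2L", 0, 600), ("2L", 400, 900), ("2R", 100, 101)]
        bed = self._write_bed(tmp_path, intervals)
        masked = pg.mask_sites(sync, bed)
        # brute-force membership oracle
        def in_union(chrom, pos):
            return any(c == chrom and s <= pos - 1 < e for c, s, e in intervals)
        expected = [i for i in range(sync.n_sites)
                    if not in_union(sync.chrom[i], sync.pos[i])]
        assert masked.n_sites == len(expected)
        assert np.array_equal(masked.pos, sync.pos[expected])

    def test_mask_then_merge_commutes(self, tmp_path, small_study):
        sync = small_study["sync"]
        bed = self._write_bed(tmp_path, [("2L", 0, 700)])
        assign = standard_assignment(sync.libraries)
        a = pg.merge_groups(pg.mask_sites(sync, bed), assign)
        b = pg.mask_sites(pg.merge_groups(sync, assign), bed)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.pos, b.pos)


class TestDownsampling:
    def test_full_fraction_is_identity(self, small_study):
        sync = small_study["sync"]
        out = pg.downsample_library(sync, "D1", 1.0, seed=1)
        assert np.array_equal(out.counts, sync.counts)

    def test_never_increases_and_zero_stays_zero(self, small_study):
        sync = small_study["sync"]
        out = pg.downsample_library(sync, "D2", 0.5, seed=2)
        j = sync.library_index("D2")
        assert (out.counts[:, j] <= sync.counts[:, j]).all()
        assert (out.counts[:, j][sync.counts[:, j] == 0] == 0).all()
        others = [i for i in range(sync.n_libraries) if i != j]
        assert np.array_equal(out.counts[:, others], sync.counts[:, others])

    def test_binomial_mean(self, small_study):
        sync = small_study["sync"]
        j = sync.library_index("ND1")
        total = sync.counts[:, j].sum()
        out = pg.downsample_library(sync, "ND1", 0.3, seed=3)
        kept = out.counts[:, j].sum()
        # Binomial(total, 0.3): 5 sigma band
        sd = np.sqrt(total * 0.3 * 0.7)
        assert abs(kept - 0.3 * total) < 5 * sd

    @pytest.mark.parametrize("f", [0.0, -0.2, 1.5])
    def test_fraction_domain(self, small_study, f):
        with pytest.raises(ValueError):
            pg.downsample_library(small_study["sync"], "D1", f)

    def test_equalize_to_smallest_library(self, small_study):
        out = pg.equalize_libraries(small_study["sync"], seed=4)
        totals = out.counts.sum(axis=(0, 2))
        target = small_study["sync"].counts.sum(axis=(0, 2)).min()
        assert totals.max() <= target * 1.02
        assert totals.min() >= target * 0.98


class TestMergeGroups:
    def test_elementwise_sum_and_order(self, small_study):
        sync = small_study["sync"]
        merged = pg.merge_groups(sync, standard_assignment(sync.libraries))
        assert merged.libraries == ["D", "ND"]
        d_cols = [j for j, l in enumerate(sync.libraries) if l.startswith("D")]
        assert np.array_equal(merged.counts[:, 0], sync.counts[:, d_cols].sum(axis=1))
        # conservation
        assert merged.counts.sum() == sync.counts.sum()

    def test_unassigned_library_rejected(self, small_study):
        assign = standard_assignment(small_study["sync"].libraries)
        assign.pop("ND4")
        with pytest.raises(ValueError, match="not assigned"):
            pg.merge_groups(small_study["sync"], assign)

    def test_unknown_library_and_bad_group_rejected(self, small_study):
        sync = small_study["sync"]
        assign = standard_assignment(sync.libraries)
        with pytest.raises(ValueError, match="unknown"):
            pg.merge_groups(sync, {**assign, "ghost": "D"})
        with pytest.raises(ValueError, match="'D' or 'ND'"):
            pg.merge_groups(sync, {**assign, "D1": "X"})

    def test_permuted_assignment_changes_sums(self, small_study):
        sync = small_study["sync"]
        a = pg.merge_groups(sync, standard_assignment(sync.libraries))
        swapped = standard_assignment(sync.libraries)
        swapped["D1"], swapped["ND1"] = "ND", "D"
        b = pg.merge_groups(sync, swapped)
        assert not np.array_equal(a.counts, b.counts)
        # direct recomputation oracle for the swapped assignment
        cols = [j for j, l in enumerate(sync.libraries) if swapped[l] == "D"]
        assert np.array_equal(b.counts[:, 0], sync.counts[:, cols].sum(axis=1))


class TestExtractBiallelic:
    def test_two_top_alleles(self, toy_sync):
        bi = pg.extract_biallelic(toy_sync)
        row = bi[bi["pos"] == 100].iloc[0]
        # combined A:T:C:G = 18:0:6:0
        assert (row["major"], row["minor"]) == ("A", "C")
        assert (row["d_major"], row["d_minor"]) == (10, 2)
        assert (row["nd_major"], row["nd_minor"]) == (8, 4)

    def test_third_allele_dropped_n_del_ignored(self, toy_sync):
        bi = pg.extract_biallelic(toy_sync)
        row = bi[bi["pos"] == 101].iloc[0]
        # combined T=21, G=9; N and del never alleles
        assert (row["major"], row["minor"]) == ("T", "G")
        assert row["d_major"] + row["d_minor"] == 15  # excludes the del read

    def test_column_order_tie_break(self, toy_sync):
        row = pg.extract_biallelic(toy_sync).set_index("pos").loc[5]
        assert (row["major"], row["minor"]) == ("A", "T")

    def test_third_allele_site_example(self):
        counts = np.array([[[20, 5, 8, 0, 0, 0], [10, 0, 4, 0, 0, 0]]])
        sync = pg.SyncData(np.array(["X"], dtype=object), np.array([7]),
                           np.array(["A"], dtype=object), counts, ["D", "ND"])
        row = pg.extract_biallelic(sync).iloc[0]
        assert (row["major"], row["minor"]) == ("A", "C")
        assert row["d_minor"] == 8 and row["nd_minor"] == 4
        # strict mode discards the site instead
        assert len(pg.extract_biallelic(sync, strict=True)) == 0

    def test_monomorphic_sites_dropped(self):
        counts = np.array([[[30, 0, 0, 0, 0, 0], [12, 0, 0, 0, 0, 0]]])
        sync = pg.SyncData(np.array(["X"], dtype=object), np.array([1]),
                           np.array(["A"], dtype=object), counts, ["D", "ND"])
        assert len(pg.extract_biallelic(sync)) == 0

    def test_group_swap_keeps_allele_identities(self, merged_small):
        bi = pg.extract_biallelic(merged_small)
        swapped = pg.SyncData(merged_small.chrom, merged_small.pos, merged_small.ref,
                              merged_small.counts[:, ::-1, :], ["D", "ND"])
        bi2 = pg.extract_biallelic(swapped)
        assert (bi["major"] == bi2["major"]).all()
        assert (bi["minor"] == bi2["minor"]).all()
        assert np.array_equal(bi["d_major"], bi2["nd_major"])

    def test_requires_two_libraries(self, small_study):
        with pytest.raises(ValueError, match="exactly"):
            pg.extract_biallelic(small_study["sync"])


@given(st.lists(st.tuples(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50),
                          st.integers(0, 50)), min_size=1, max_size=20))
@settings(max_examples=50, deadline=None)
def test_merge_conserves_counts_property(tables):
    n = len(tables)
    counts = np.zeros((n, 4, 6), dtype=np.int64)
    for i, (a, b, c, d) in enumerate(tables):
        counts[i, 0, 0], counts[i, 1, 1], counts[i, 2, 2], counts[i, 3, 3] = a, b, c, d
    sync = pg.SyncData(np.array(["X"] * n, dtype=object),
                       np.arange(1, n + 1, dtype=np.int64),
                       np.array(["A"] * n, dtype=object), counts,
                       ["D1", "D2", "ND1", "ND2"])
    merged = pg.merge_groups(sync, {"D1": "D", "D2": "D", "ND1": "ND", "ND2": "ND"})
    assert merged.counts.sum() == counts.sum()
    assert (merged.counts.sum(axis=1) == counts.sum(axis=1)).all()
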