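import numpy as np
import pandas as pd
import pytest

from pivarkit import cross_strain as xs
from pivarkit import synthetic_data as sd
from pivarkit.genomic_io import CountMatrix, GenomicInterval


def simple_map(blocks, strain="A"):
    return xs.StrainCoordinateMap(
        strain,
        pd.DataFrame(blocks, columns=xs.MAP_COLUMNS),
    )


class TestConvertIntervals:
    def test_offset_shift(self):
        smap = simple_map([("chr1", 0, 1000, "ref1", 1000)])
        conv, dropped = xs.convert_intervals(
            [GenomicInterval("chr1", 100, 200, "c1", "+")], smap
        )
        assert dropped == []
        assert (conv[0].chrom, conv[0].start, conv[0].end) == ("ref1", 1100, 1200)

    def test_length_preserved(self):
        smap = simple_map([("chr1", 0, 5000, "ref1", 777)])
        ivs = [GenomicInterval("chr1", s, s + ln, f"c{s}") for s, ln in ((10, 50), (100, 999))]
        conv, _ = xs.convert_intervals(ivs, smap)
        for src, dst in zip(ivs, conv):
            assert dst.length == src.length

    def test_split_block_with_target_gap_dropped(self):
        smap = simple_map([
            ("chr1", 0, 500, "ref1", 0),
            ("chr1", 500, 1000, "ref1", 550),  # 50-bp target gap
        ])
        conv, dropped = xs.convert_intervals(
            [GenomicInterval("chr1", 400, 600, "c1", "+")], smap
        )
        assert conv == []
        assert dropped[0][1] == "not_one_to_one"

    def test_contiguous_blocks_convert(self):
        smap = simple_map([
            ("chr1", 0, 500, "ref1", 100),
            ("chr1", 500, 1000, "ref1", 600),  # contiguous in source and target
        ])
        conv, dropped = xs.convert_intervals(
            [GenomicInterval("chr1", 400, 600, "c1", "+")], smap
        )
        assert dropped == []
        assert (conv[0].start, conv[0].end) == (500, 700)

    def test_gap_region_dropped(self):
        smap = simple_map([("chr1", 0, 500, "ref1", 0)])
        conv, dropped = xs.convert_intervals(
            [GenomicInterval("chr1", 600, 700, "c1", "+")], smap
        )
        assert conv == [] and dropped[0][1] == "not_one_to_one"

    def test_missing_chrom_no_alignment(self):
        smap = simple_map([("chr1", 0, 500, "ref1", 0)])
        conv, dropped = xs.convert_intervals(
            [GenomicInterval("chrX", 10, 20, "c1", "+")], smap
        )
        assert dropped[0][1] == "no_alignment"

    def test_identity_map_is_identity(self):
        genome = {"chr1": 50_000}
        smap = simple_map([("chr1", 0, 50_000, "chr1", 0)])
        ivs = [GenomicInterval("chr1", 5_000, 7_000, "c1", "+")]
        conv, dropped = xs.convert_intervals(ivs, smap)
        assert dropped == []
        assert (conv[0].start, conv[0].end, conv[0].chrom) == (5_000, 7_000, "chr1")

    def test_simulated_map_truth(self):
        genome = {"chr1": 200_000, "chr2": 200_000}
        table, kept = sd.simulate_strain_maps(genome, "CAST", seed=3)
        smap = xs.StrainCoordinateMap("CAST", table[xs.MAP_COLUMNS])
        rng = np.random.default_rng(0)
        ivs = []
        for i in range(200):
            chrom = "chr1" if i % 2 else "chr2"
            s = int(rng.integers(0, genome[chrom] - 3000))
            ivs.append(GenomicInterval(chrom, s, s + 2000, f"c{i}", "+"))
        conv, dropped = xs.convert_intervals(ivs, smap)
        converted_names = {iv.name for iv in conv}
        for iv in ivs:
            inside_kept = any(
                c == iv.chrom and s <= iv.start and iv.end <= e for c, s, e in kept
            )
            assert (iv.name in converted_names) == inside_kept


class TestMergeSameStrandUnion:
    def test_same_strand_merge(self):
        merged = xs.merge_same_strand_union({
            "A": [GenomicInterval("c", 100, 200, "a1", "+")],
            "B": [GenomicInterval("c", 150, 300, "b1", "+")],
        })
        assert len(merged.clusters) == 1
        cl = merged.clusters[0]
        assert (cl.start, cl.end, cl.strand) == (100, 300, "+")
        assert sorted(merged.provenance[cl.name]) == [("A", "a1"), ("B", "b1")]

    def test_opposite_strands_not_merged(self):
        merged = xs.merge_same_strand_union({
            "A": [GenomicInterval("c", 100, 200, "a1", "+")],
            "B": [GenomicInterval("c", 150, 300, "b1", "-")],
        })
        assert len(merged.clusters) == 2

    def test_transitive_chain(self):
        merged = xs.merge_same_strand_union({
            "A": [GenomicInterval("c", 0, 100, "a", "+"),
                  GenomicInterval("c", 90, 150, "b", "+"),
                  GenomicInterval("c", 140, 200, "d", "+")],
        })
        assert len(merged.clusters) == 1
        assert (merged.clusters[0].start, merged.clusters[0].end) == (0, 200)

    def test_both_is_its_own_class(self):
        merged = xs.merge_same_strand_union({
            "A": [GenomicInterval("c", 0, 100, "a", "both")],
            "B": [GenomicInterval("c", 50, 150, "b", "+")],
        })
        assert len(merged.clusters) == 2

    def test_idempotent_and_order_invariant(self, rng):
        ivs = []
        for i in range(60):
            s = int(rng.integers(0, 5_000))
            ivs.append(GenomicInterval("c", s, s + int(rng.integers(50, 400)), f"i{i}",
                                       str(rng.choice(["+", "-", "both"]))))
        m1 = xs.merge_same_strand_union({"A": ivs})
        m2 = xs.merge_same_strand_union({"A": list(reversed(ivs))})
        key = lambda c: (c.chrom, c.start, c.end, c.strand)
        assert sorted(map(key, m1.clusters)) == sorted(map(key, m2.clusters))
        m3 = xs.merge_same_strand_union({"A": m1.clusters})
        assert sorted(map(key, m3.clusters)) == sorted(map(key, m1.clusters))

    def test_connected_component_oracle(self, rng):
        # networkx connected components as the independent oracle
        import networkx as nx

        ivs = []
        for i in range(80):
            s = int(rng.integers(0, 8_000))
            ivs.append(GenomicInterval("c", s, s + int(rng.integers(50, 600)), f"i{i}",
                                       str(rng.choice(["+", "-"]))))
        merged = xs.merge_same_strand_union({"A": ivs})
        G = nx.Graph()
        G.add_nodes_from(range(len(ivs)))
        for i in range(len(ivs)):
            for j in range(i + 1, len(ivs)):
                a, b = ivs[i], ivs[j]
                if a.strand == b.strand and a.start < b.end and b.start < a.end:
                    G.add_edge(i, j)
        expected = sorted(
            (min(ivs[k].start for k in comp), max(ivs[k].end for k in comp),
             ivs[next(iter(comp))].strand)
            for comp in nx.connected_components(G)
        )
        got = sorted((c.start, c.end, c.strand) for c in merged.clusters)
        assert got == expected


class TestApplyClusterFilters:
    def _counts(self, names, rows):
        return CountMatrix(names, [f"s{i}" for i in range(len(rows[0]))],
                           np.array(rows))

    def test_repeat_overlap_removed_above_80(self):
        cl = GenomicInterval("c", 0, 1000, "m1", "+")
        merged = xs.MergedClusterSet([cl], {"m1": []})
        repeats = [GenomicInterval("c", 0, 850, "r")]
        out = xs.apply_cluster_filters(merged, repeats, [],
                                       self._counts(["m1"], [[100]]))
        assert out.clusters == [] and out.filter_log == [("m1", "repeat_overlap")]

    def test_exactly_80_retained(self):
        cl = GenomicInterval("c", 0, 1000, "m1", "+")
        merged = xs.MergedClusterSet([cl], {"m1": []})
        repeats = [GenomicInterval("c", 0, 800, "r")]
        out = xs.apply_cluster_filters(merged, repeats, [],
                                       self._counts(["m1"], [[100]]))
        assert out.clusters == [cl]

    def test_union_not_double_counted(self):
        # two repeats covering the same 850 bp: union is 850, not 1700
        cl = GenomicInterval("c", 0, 1000, "m1", "+")
        merged = xs.MergedClusterSet([cl], {"m1": []})
        repeats = [GenomicInterval("c", 0, 500, "r1"), GenomicInterval("c", 300, 850, "r2")]
        out = xs.apply_cluster_filters(merged, repeats, [],
                                       self._counts(["m1"], [[100]]))
        assert out.clusters == [] and out.filter_log[0][1] == "repeat_overlap"

    def test_bi_over_mono_removed(self):
        bi = GenomicInterval("c", 0, 1000, "b", "both")
        mono = GenomicInterval("c", 500, 1500, "m", "+")
        merged = xs.MergedClusterSet([bi, mono], {"b": [], "m": []})
        out = xs.apply_cluster_filters(merged, [], [],
                                       self._counts(["b", "m"], [[100], [100]]))
        assert [c.name for c in out.clusters] == ["m"]
        assert ("b", "bi_over_mono") in out.filter_log

    def test_bi_survives_when_mono_already_removed(self):
        # filter order matters: mono removed by repeats, bi then survives
        bi = GenomicInterval("c", 0, 1000, "b", "both")
        mono = GenomicInterval("c", 500, 1500, "m", "+")
        merged = xs.MergedClusterSet([bi, mono], {"b": [], "m": []})
        repeats = [GenomicInterval("c", 500, 1450, "r")]  # 95% of mono
        out = xs.apply_cluster_filters(merged, repeats, [],
                                       self._counts(["b", "m"], [[100], [100]]))
        assert [c.name for c in out.clusters] == ["b"]

    def test_low_count_boundary(self):
        a = GenomicInterval("c", 0, 1000, "a", "+")
        b = GenomicInterval("c", 2000, 3000, "b", "+")
        merged = xs.MergedClusterSet([a, b], {"a": [], "b": []})
        counts = self._counts(["a", "b"], [[4, 9, 3], [4, 12, 3]])
        out = xs.apply_cluster_filters(merged, [], [], counts)
        assert [c.name for c in out.clusters] == ["b"]
        assert ("a", "low_count") in out.filter_log

    def test_accounting_identity(self, rng):
        ivs, names = [], []
        for i in range(30):
            s = int(rng.integers(0, 100_000))
            iv = GenomicInterval("c", s, s + int(rng.integers(500, 2000)), f"m{i}",
                                 str(rng.choice(["+", "-", "both"])))
            ivs.append(iv)
            names.append(iv.name)
        merged = xs.MergedClusterSet(ivs, {n: [] for n in names})
        repeats = [GenomicInterval("c", int(s), int(s) + 1500, f"r{k}")
                   for k, s in enumerate(rng.integers(0, 100_000, size=15))]
        counts = self._counts(names, rng.integers(0, 30, size=(30, 4)).tolist())
        out = xs.apply_cluster_filters(merged, repeats, [], counts)
        assert len(out.clusters) + len(out.filter_log) == 30
        logged = {n for n, _ in out.filter_log}
        surviving = {c.name for c in out.clusters}
        assert logged | surviving == set(names)
        assert logged & surviving == set()


class TestTwelveIntervalFixture:
    """Hand-built 12-cluster fixture; expected outcome computed independently
    with a brute-force script before implementation and frozen here."""

    def _build(self):
        ivs = [
            GenomicInterval("c1", 0, 1000, "k01", "+"),       # survives
            GenomicInterval("c1", 2000, 3000, "k02", "+"),    # repeat 85% -> removed
            GenomicInterval("c1", 4000, 5000, "k03", "+"),    # repeat exactly 80% -> kept
            GenomicInterval("c1", 6000, 7000, "k04", "both"), # overlaps k05 -> bi_over_mono
            GenomicInterval("c1", 6500, 7500, "k05", "-"),    # survives
            GenomicInterval("c1", 9000, 10000, "k06", "both"),# no mono overlap -> survives
            GenomicInterval("c1", 11000, 12000, "k07", "+"),  # counts max 9 -> low_count
            GenomicInterval("c1", 13000, 14000, "k08", "+"),  # counts max 10 -> kept
            GenomicInterval("c2", 0, 2000, "k09", "-"),       # TEV union 82% -> removed
            GenomicInterval("c2", 3000, 4000, "k10", "+"),    # survives
            GenomicInterval("c2", 5000, 6000, "k11", "both"), # overlaps k10? no -> survives
            GenomicInterval("c2", 5500, 6500, "k12", "-"),    # mono overlapping k11 -> k11 removed
        ]
        repeats = [
            GenomicInterval("c1", 2000, 2850, "r1"),
            GenomicInterval("c1", 4000, 4800, "r2"),
        ]
        tevs = [
            GenomicInterval("c2", 0, 1000, "t1"),
            GenomicInterval("c2", 700, 1640, "t2"),  # union with t1 = 1640 of 2000
        ]
        counts = CountMatrix(
            [iv.name for iv in ivs], ["s1", "s2", "s3"],
            np.array([
                [50, 60, 70], [50, 60, 70], [50, 60, 70], [50, 60, 70],
                [50, 60, 70], [50, 60, 70], [4, 9, 3], [4, 10, 3],
                [50, 60, 70], [50, 60, 70], [50, 60, 70], [50, 60, 70],
            ]),
        )
        merged = xs.MergedClusterSet(ivs, {iv.name: [] for iv in ivs})
        return merged, repeats, tevs, counts

    def test_expected_survivors_and_log(self):
        merged, repeats, tevs, counts = self._build()
        out = xs.apply_cluster_filters(merged, repeats, tevs, counts)
        assert [c.name for c in out.clusters] == [
            "k01", "k03", "k05", "k06", "k08", "k10", "k12"
        ]
        assert sorted(out.filter_log) == [
            ("k02", "repeat_overlap"),
            ("k04", "bi_over_mono"),
            ("k07", "low_count"),
            ("k09", "repeat_overlap"),
            ("k11", "bi_over_mono"),
        ]
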