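"""Super-read graph assembly: joins, het screening, tips, path merging."""

import networkx as nx
import numpy as np

from haplobook.assembly import (
    Contig,
    _count_het_sites,
    build_super_read_graph,
    merge_simple_paths,
    polish_contigs,
    remove_spurious_edges_by_snps,
    remove_tips,
)
from haplobook.io import AssemblyParams, Read
from haplobook.superread import SuperRead

from conftest import random_dna


def _substitute(seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = "ACGT"[("ACGT".index(out[p]) + 1) % 4]
    return "".join(out)


def _tiles(prefix, seq, n, length):
    step = max(1, (len(seq) - length) // (n - 1))
    return [Read(f"{prefix}{i}", seq[i * step : i * step + length])
            for i in range(n)]


class TestCountHetSites:
    def _setup(self, rng, n_subs):
        joint = random_dna(rng, 6000)
        region = (2000, 4000)
        subs = [2300 + 340 * i for i in range(n_subs)]
        alt = _substitute(joint, subs)
        u_reads = [Read(f"u{i}", joint[:4000]) for i in range(6)]
        v_reads = [Read(f"v{i}", alt[2000:]) for i in range(6)]
        return joint, region, {"u": u_reads, "v": v_reads}

    def test_segregating_sites_counted(self, hifi_params):
        rng = np.random.default_rng(90)
        joint, region, groups = self._setup(rng, 3)
        assert _count_het_sites(joint, region, groups, "u", "v", hifi_params) == 3

    def test_identical_groups_count_zero(self, hifi_params):
        rng = np.random.default_rng(91)
        joint, region, groups = self._setup(rng, 0)
        assert _count_het_sites(joint, region, groups, "u", "v", hifi_params) == 0

    def test_within_group_split_not_counted(self, hifi_params):
        # a balanced candidate site that splits *inside* group u is noise,
        # not haplotype structure: it must not count as segregating
        rng = np.random.default_rng(92)
        joint = random_dna(rng, 6000)
        alt = _substitute(joint, [3000])
        u_reads = [Read(f"u{i}", (joint if i % 2 else alt)[:4000])
                   for i in range(6)]
        v_reads = [Read(f"v{i}", alt[2000:]) for i in range(6)]
        groups = {"u": u_reads, "v": v_reads}
        assert _count_het_sites(joint, (2000, 4000), groups, "u", "v",
                                hifi_params) == 0

    def test_sites_outside_region_ignored(self, hifi_params):
        rng = np.random.default_rng(93)
        joint = random_dna(rng, 6000)
        alt = _substitute(joint, [500])  # difference before the region
        u_reads = [Read(f"u{i}", joint[:4000]) for i in range(6)]
        v_reads = [Read(f"v{i}", alt[:4000]) for i in range(6)]
        groups = {"u": u_reads, "v": v_reads}
        assert _count_het_sites(joint, (2000, 4000), groups, "u", "v",
                                hifi_params) == 0

    def test_too_few_informative_reads_per_side(self, hifi_params):
        rng = np.random.default_rng(94)
        joint = random_dna(rng, 6000)
        alt = _substitute(joint, [3000])
        u_reads = [Read(f"u{i}", joint[:4000]) for i in range(11)]
        v_reads = [Read("v0", alt[2000:])]  # one private read: no call
        groups = {"u": u_reads, "v": v_reads}
        assert _count_het_sites(joint, (2000, 4000), groups, "u", "v",
                                hifi_params) == 0


def _hap_pair(rng):
    """Two haplotype sequences differing at five sites inside 4000-8000."""
    hapA = random_dna(rng, 12000)
    subs = [4500, 5300, 6100, 6900, 7700, 9000, 10500]
    hapB = _substitute(hapA, subs)
    return hapA, hapB


def _sr(name, seq):
    return SuperRead(name, 0, 1, seq, np.full(len(seq), 8, dtype=np.int64), ["x", "y"])


class TestSuperReadGraphAndSnpFilter:
    def _params(self):
        return AssemblyParams(platform="hifi", snp_edge_filter=True,
                              sr_min_ovlp_len=3000)

    def test_same_haplotype_join_survives(self):
        rng = np.random.default_rng(95)
        hapA, _ = _hap_pair(rng)
        sru = _sr("srU", hapA[:8000])
        srv = _sr("srV", hapA[4000:])
        groups = {"srU": _tiles("u", hapA[:8000], 14, 4000),
                  "srV": _tiles("v", hapA[4000:], 14, 4000)}
        params = self._params()
        g = build_super_read_graph([sru, srv], params, groups)
        assert ("srU", "srV") in g.edges
        g2 = remove_spurious_edges_by_snps(g, [sru, srv], groups, params)
        assert ("srU", "srV") in g2.edges

    def test_cross_haplotype_join_removed(self):
        rng = np.random.default_rng(96)
        hapA, hapB = _hap_pair(rng)
        sru = _sr("srU", hapA[:8000])
        srv = _sr("srV", hapB[4000:])
        groups = {"srU": _tiles("u", hapA[:8000], 14, 4000),
                  "srV": _tiles("v", hapB[4000:], 14, 4000)}
        params = self._params()
        g = build_super_read_graph([sru, srv], params, groups)
        # 5 substitutions in a 4000 bp overlap still clear the identity gate
        assert ("srU", "srV") in g.edges
        g2 = remove_spurious_edges_by_snps(g, [sru, srv], groups, params)
        assert ("srU", "srV") not in g2.edges
        assert set(g2.nodes) == {"srU", "srV"}

    def test_heterozygous_containment_keeps_both_nodes(self):
        # a full other-haplotype super read inside a container must not be
        # absorbed: the containment is genotyped and rejected
        rng = np.random.default_rng(97)
        hapA, hapB = _hap_pair(rng)
        big = _sr("srBig", hapA)
        inner = _sr("srInner", hapB[4000:9000])
        groups = {"srBig": _tiles("a", hapA, 20, 4000),
                  "srInner": _tiles("b", hapB[4000:9000], 10, 3500)}
        params = self._params()
        g = build_super_read_graph([big, inner], params, groups)
        assert set(g.nodes) == {"srBig", "srInner"}

    def test_homozygous_containment_absorbed(self):
        rng = np.random.default_rng(98)
        hapA, _ = _hap_pair(rng)
        big = _sr("srBig", hapA)
        inner = _sr("srInner", hapA[4000:9000])
        groups = {"srBig": _tiles("a", hapA, 20, 4000),
                  "srInner": _tiles("b", hapA[4000:9000], 10, 3500)}
        g = build_super_read_graph([big, inner], self._params(), groups)
        assert set(g.nodes) == {"srBig"}


def _chain_graph(names, seq_len=100, cut=50):
    g = nx.DiGraph()
    for n in names:
        g.add_node(n, ori=1, length=seq_len)
    for u, v in zip(names, names[1:]):
        g.add_edge(u, v, succ_cut=cut, ext=seq_len - cut)
    return g


class TestRemoveTips:
    def _params(self):
        return AssemblyParams(platform="hifi")

    def test_linear_chain_untouched(self):
        g = _chain_graph(list("abcd"))
        out = remove_tips(g, self._params())
        assert set(out.nodes) == set("abcd")

    def test_source_tip_removed(self):
        # main chain longer than tip_max_nodes on both sides of the junction
        g = _chain_graph(list("abcdefg"))
        g.add_node("t", ori=1, length=100)
        g.add_edge("t", "d", succ_cut=50, ext=50)  # d now has in-degree 2
        out = remove_tips(g, self._params())
        assert "t" not in out.nodes
        assert set(out.nodes) == set("abcdefg")

    def test_sink_tip_removed(self):
        g = _chain_graph(list("abcdefg"))
        g.add_node("t", ori=1, length=100)
        g.add_edge("d", "t", succ_cut=50, ext=50)
        out = remove_tips(g, self._params())
        assert "t" not in out.nodes
        assert set(out.nodes) == set("abcdefg")

    def test_long_branch_kept(self):
        params = AssemblyParams(platform="hifi", tip_max_nodes=1)
        g = _chain_graph(list("abcd"))
        for n in ("t1", "t2", "t3"):
            g.add_node(n, ori=1, length=100)
        g.add_edge("t1", "t2", succ_cut=50, ext=50)
        g.add_edge("t2", "t3", succ_cut=50, ext=50)
        g.add_edge("t3", "b", succ_cut=50, ext=50)
        out = remove_tips(g, params)
        assert {"t1", "t2", "t3"} <= set(out.nodes)

    def test_two_node_tip_removed(self):
        params = AssemblyParams(platform="hifi", tip_max_nodes=2)
        g = _chain_graph(list("abcdefg"))
        g.add_node("t1", ori=1, length=100)
        g.add_node("t2", ori=1, length=100)
        g.add_edge("t1", "t2", succ_cut=50, ext=50)
        g.add_edge("t2", "d", succ_cut=50, ext=50)
        out = remove_tips(g, params)
        assert set(out.nodes) == set("abcdefg")


class TestMergeSimplePaths:
    def _superreads(self, names, seqs=None):
        return [_sr(n, seqs[n] if seqs else "ACGT" * 25) for n in names]

    def test_chain_becomes_one_contig(self):
        rng = np.random.default_rng(99)
        genome = random_dna(rng, 250)
        seqs = {"a": genome[:100], "b": genome[50:150], "c": genome[100:200],
                "d": genome[150:250]}
        g = _chain_graph(list("abcd"))
        contigs = merge_simple_paths(g, self._superreads("abcd", seqs))
        assert len(contigs) == 1
        assert contigs[0].sequence == genome
        assert contigs[0].super_read_ids == list("abcd")

    def test_branching_node_stands_alone(self):
        g = _chain_graph(list("abc"))
        g.add_node("d", ori=1, length=100)
        g.add_edge("d", "b", succ_cut=50, ext=50)
        contigs = merge_simple_paths(g, self._superreads("abcd"))
        members = sorted(tuple(c.super_read_ids) for c in contigs)
        # b has in-degree 2, so it is not simple and stands alone; c cannot
        # merge backwards into a branching node
        assert members == [("a",), ("b",), ("c",), ("d",)]

    def test_partition_property_random(self):
        rng = np.random.default_rng(100)
        for trial in range(15):
            n = int(rng.integers(2, 12))
            names = [f"n{i}" for i in range(n)]
            g = nx.DiGraph()
            for name in names:
                g.add_node(name, ori=1, length=100)
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.25:
                        g.add_edge(names[i], names[j], succ_cut=50, ext=50)
            contigs = merge_simple_paths(g, self._superreads(names))
            seen = [m for c in contigs for m in c.super_read_ids]
            assert sorted(seen) == sorted(names)

    def test_isolated_nodes_each_emit(self):
        g = nx.DiGraph()
        for n in "ab":
            g.add_node(n, ori=1, length=100)
        contigs = merge_simple_paths(g, self._superreads("ab"))
        assert len(contigs) == 2


class TestPolishContigs:
    def test_short_contigs_dropped(self):
        params = AssemblyParams(platform="hifi", min_contig_len=5000,
                                polish_final=False)
        contigs = [Contig("c0", "A" * 6000, ["sr0"]),
                   Contig("c1", "A" * 4000, ["sr1"])]
        out = polish_contigs(contigs, [], {}, params)
        assert [c.id for c in out] == ["c0"]

    def test_final_polish_fixes_contig_errors(self):
        rng = np.random.default_rng(101)
        params = AssemblyParams(platform="hifi", min_contig_len=1000)
        genome = random_dna(rng, 9000)
        bad = _substitute(genome, [2000, 4500, 7000])
        contig = Contig("c0", bad, ["sr0"])
        groups = {"sr0": _tiles("r", genome, 10, 3500)}
        out = polish_contigs([contig], [], groups, params)
        assert out[0].sequence == genome
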