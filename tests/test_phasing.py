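"""SNP calling, allele matrices, and the weighted-MEC solver."""

import numpy as np
import pytest

from haplobook.consensus import map_reads
from haplobook.io import AssemblyParams, Read
from haplobook.phasing import (
    MISSING,
    AlleleMatrix,
    SNPSite,
    assign_unphased,
    build_allele_matrix,
    call_snps,
    solve_wmec,
)

from conftest import brute_force_wmec, random_allele_matrix, random_dna


def _het_reference(rng, length=6000, n_sites=12):
    """A reference plus two haplotype sequences differing at known sites."""
    ref = random_dna(rng, length)
    positions = np.sort(rng.choice(np.arange(300, length - 300), n_sites,
                                   replace=False))
    hapA = list(ref)
    hapB = list(ref)
    for p in positions:
        hapB[p] = "ACGT"[("ACGT".index(ref[p]) + 1) % 4]
    return ref, "".join(hapA), "".join(hapB), positions.tolist()


class TestCallSnps:
    def _mapped(self, rng, n_per_hap=8):
        ref, hapA, hapB, positions = _het_reference(rng)
        reads = [Read(f"a{i}", hapA) for i in range(n_per_hap)]
        reads += [Read(f"b{i}", hapB) for i in range(n_per_hap)]
        return map_reads(reads, ref), ref, positions

    def test_planted_sites_found_exactly(self, hifi_params):
        rng = np.random.default_rng(60)
        mapped, ref, positions = self._mapped(rng)
        sites = call_snps(mapped, ref, hifi_params)
        assert [s.position for s in sites] == positions
        for s in sites:
            assert s.ref_allele == ref[s.position]
            assert s.depth == 16 and s.alt_count == 8

    def test_depth_threshold(self, hifi_params):
        rng = np.random.default_rng(61)
        mapped, ref, _ = self._mapped(rng, n_per_hap=4)  # depth 8 < 10
        assert call_snps(mapped, ref, hifi_params) == []

    def test_allele_count_threshold(self, hifi_params):
        rng = np.random.default_rng(62)
        ref, hapA, hapB, _ = _het_reference(rng)
        reads = [Read(f"a{i}", hapA) for i in range(10)]
        reads += [Read(f"b{i}", hapB) for i in range(2)]  # alt count 2 < 3
        mapped = map_reads(reads, ref)
        assert call_snps(mapped, ref, hifi_params) == []

    def test_af_band(self, hifi_params):
        rng = np.random.default_rng(63)
        ref, hapA, hapB, _ = _het_reference(rng)
        reads = [Read(f"a{i}", hapA) for i in range(17)]
        reads += [Read(f"b{i}", hapB) for i in range(3)]  # af 0.15 < 0.2
        mapped = map_reads(reads, ref)
        assert call_snps(mapped, ref, hifi_params) == []


class TestBuildAlleleMatrix:
    def test_entries_match_haplotypes(self, hifi_params):
        rng = np.random.default_rng(64)
        ref, hapA, hapB, _ = _het_reference(rng)
        reads = [Read(f"a{i}", hapA) for i in range(8)]
        reads += [Read(f"b{i}", hapB) for i in range(8)]
        mapped = map_reads(reads, ref)
        sites = call_snps(mapped, ref, hifi_params)
        mat = build_allele_matrix(mapped, sites)
        for i, rid in enumerate(mat.read_ids):
            want = 0 if rid.startswith("a") else 1
            assert set(mat.entries[i].tolist()) == {want}
        assert np.all(mat.weights[mat.entries != MISSING] > 0)
        assert np.all(mat.weights[mat.entries == MISSING] == 0)

    def test_partial_read_has_missing_outside_span(self, hifi_params):
        rng = np.random.default_rng(65)
        ref, hapA, hapB, positions = _het_reference(rng)
        full = [Read(f"a{i}", hapA) for i in range(8)]
        full += [Read(f"b{i}", hapB) for i in range(8)]
        half = Read("half", hapA[: positions[3] + 50])
        mapped = map_reads(full + [half], ref)
        sites = call_snps(mapped, ref, hifi_params)
        mat = build_allele_matrix(mapped, sites)
        row = mat.entries[mat.read_ids.index("half")]
        assert MISSING in row.tolist() and 0 in row.tolist()

    def test_quality_used_as_weight(self, hifi_params):
        rng = np.random.default_rng(66)
        ref, hapA, hapB, _ = _het_reference(rng)
        reads = [Read(f"a{i}", hapA, quality=[17] * len(hapA)) for i in range(8)]
        reads += [Read(f"b{i}", hapB) for i in range(8)]
        mapped = map_reads(reads, ref)
        sites = call_snps(mapped, ref, hifi_params)
        mat = build_allele_matrix(mapped, sites)
        for i, rid in enumerate(mat.read_ids):
            expect = 17.0 if rid.startswith("a") else 10.0
            got = mat.weights[i][mat.entries[i] != MISSING]
            assert np.all(got == expect)


class TestSolveWmecOracle:
    def test_matches_brute_force(self, hifi_params):
        rng = np.random.default_rng(67)
        for trial in range(120):
            mat = random_allele_matrix(rng, int(rng.integers(2, 9)),
                                       int(rng.integers(1, 7)))
            ph = solve_wmec(mat, hifi_params)
            assert ph.mec_cost == pytest.approx(brute_force_wmec(mat))

    def test_assignment_achieves_reported_cost(self, hifi_params):
        rng = np.random.default_rng(68)
        for trial in range(30):
            mat = random_allele_matrix(rng, int(rng.integers(2, 9)),
                                       int(rng.integers(1, 7)))
            ph = solve_wmec(mat, hifi_params)
            cost = 0.0
            for j in range(mat.n_sites):
                for side in ("H1", "H2"):
                    w = [0.0, 0.0]
                    for i, rid in enumerate(mat.read_ids):
                        if ph.assignment[rid] == side and mat.entries[i, j] != MISSING:
                            w[mat.entries[i, j]] += mat.weights[i, j]
                    cost += min(w)
            assert cost == pytest.approx(ph.mec_cost)

    def test_column_flip_invariance(self, hifi_params):
        # flipping ref/alt labels of a column cannot change the optimal cost
        rng = np.random.default_rng(69)
        for trial in range(20):
            mat = random_allele_matrix(rng, 6, 5)
            flipped = AlleleMatrix(mat.sites, mat.read_ids,
                                   mat.entries.copy(), mat.weights.copy())
            col = flipped.entries[:, 2]
            col[col != MISSING] = 1 - col[col != MISSING]
            a = solve_wmec(mat, hifi_params)
            b = solve_wmec(flipped, hifi_params)
            assert a.mec_cost == pytest.approx(b.mec_cost)

    def test_canonical_h1_contains_smallest_read(self, hifi_params):
        rng = np.random.default_rng(70)
        for trial in range(10):
            mat = random_allele_matrix(rng, 6, 5, missing_frac=0.0)
            ph = solve_wmec(mat, hifi_params)
            phased = ph.group("H1") + ph.group("H2")
            if phased:
                assert min(phased) in ph.group("H1")


class TestSolveWmecStructure:
    def test_clean_split_recovered(self, hifi_params):
        # 2 haplotypes x 5 reads x 8 sites, no noise: cost 0 and exact groups
        entries = np.array([[i % 2] * 8 for i in range(10)], dtype=np.int8)
        weights = np.full((10, 8), 10.0)
        sites = [SNPSite(j, "A", "C", 10, 5, 5) for j in range(8)]
        mat = AlleleMatrix(sites, [f"r{i}" for i in range(10)], entries, weights)
        ph = solve_wmec(mat, hifi_params)
        assert ph.mec_cost == 0.0
        assert ph.group("H1") == [f"r{i}" for i in range(0, 10, 2)]
        assert ph.group("H2") == [f"r{i}" for i in range(1, 10, 2)]

    def test_single_flip_costs_its_weight(self, hifi_params):
        entries = np.array([[i % 2] * 6 for i in range(8)], dtype=np.int8)
        entries[0, 3] = 1  # one corrupted entry on an even (allele-0) read
        weights = np.full((8, 6), 1.0)
        weights[0, 3] = 2.5
        sites = [SNPSite(j, "A", "C", 8, 4, 4) for j in range(6)]
        mat = AlleleMatrix(sites, [f"r{i}" for i in range(8)], entries, weights)
        ph = solve_wmec(mat, hifi_params)
        assert ph.mec_cost == pytest.approx(2.5)

    def test_coverage_cap_respected_and_excluded_reads_assigned(self):
        params = AssemblyParams(platform="hifi", max_phasing_coverage=6)
        rng = np.random.default_rng(71)
        n = 30
        entries = np.array([[i % 2] * 5 for i in range(n)], dtype=np.int8)
        weights = np.full((n, 5), 10.0)
        sites = [SNPSite(j, "A", "C", n, n // 2, n // 2) for j in range(5)]
        mat = AlleleMatrix(sites, [f"r{i:02d}" for i in range(n)], entries, weights)
        ph = solve_wmec(mat, params)
        # every read assigned, and assigned consistently with its haplotype
        assert set(ph.assignment) == set(mat.read_ids)
        h1 = ph.group("H1")
        even = {f"r{i:02d}" for i in range(0, n, 2)}
        assert set(h1) in (even, set(mat.read_ids) - even)

    def test_empty_matrix(self, hifi_params):
        mat = AlleleMatrix([], ["r0", "r1"], np.zeros((2, 0), dtype=np.int8),
                           np.zeros((2, 0)))
        ph = solve_wmec(mat, hifi_params)
        assert ph.mec_cost == 0.0
        assert set(ph.assignment) == {"r0", "r1"}


class TestAssignUnphased:
    def test_missing_reads_labelled_both(self, hifi_params):
        entries = np.array([[i % 2] * 4 for i in range(6)], dtype=np.int8)
        weights = np.full((6, 4), 10.0)
        sites = [SNPSite(j, "A", "C", 6, 3, 3) for j in range(4)]
        mat = AlleleMatrix(sites, [f"r{i}" for i in range(6)], entries, weights)
        ph = solve_wmec(mat, hifi_params)
        out = assign_unphased([f"r{i}" for i in range(8)], ph)
        assert out.assignment["r6"] == "both"
        assert out.assignment["r7"] == "both"
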