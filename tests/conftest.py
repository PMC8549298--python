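"""Shared fixtures and oracle helpers for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from haplobook.io import AssemblyParams, Read
from haplobook.phasing import MISSING, AlleleMatrix, SNPSite
from haplobook.simulate import simulate_diploid, simulate_reads

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute a fraction ``rate`` of bases, each to a different base."""
    out = list(seq)
    for i in np.nonzero(rng.random(len(seq)) < rate)[0]:
        out[i] = BASES[(BASES.index(out[i]) + rng.integers(1, 4)) % 4]
    return "".join(out)


def brute_force_wmec(matrix: AlleleMatrix) -> float:
    """Exhaustive minimum over all read bipartitions of the wMEC cost."""
    n = matrix.n_reads
    best = np.inf
    for mask in range(2 ** n):
        cost = 0.0
        for j in range(matrix.n_sites):
            for side in (0, 1):
                w = [0.0, 0.0]
                for i in range(n):
                    if (mask >> i) & 1 == side and matrix.entries[i, j] != MISSING:
                        w[matrix.entries[i, j]] += matrix.weights[i, j]
                cost += min(w)
        best = min(best, cost)
    return best


def brute_force_transitive_removals(edges: set[tuple]) -> set[tuple]:
    """Edges (u, v) having a two-step witness u -> w -> v in the input set."""
    succ: dict = {}
    for u, v in edges:
        succ.setdefault(u, set()).add(v)
    return {
        (u, v)
        for u, v in edges
        if any(w != v and v in succ.get(w, ()) for w in succ.get(u, ()))
    }


def exhaustive_longest_path(graph) -> int:
    """Max over all simple paths of first-node length + summed extensions."""
    best = 0
    for start in graph.nodes:
        stack = [(start, graph.nodes[start]["length"], {start})]
        while stack:
            node, score, seen = stack.pop()
            best = max(best, score)
            for nxt in graph.successors(node):
                if nxt not in seen:
                    ext = graph.edges[node, nxt]["ext"]
                    stack.append((nxt, score + ext, seen | {nxt}))
    return best


def random_allele_matrix(rng: np.random.Generator, n_reads: int, n_sites: int,
                         missing_frac: float = 0.25) -> AlleleMatrix:
    entries = rng.integers(0, 2, size=(n_reads, n_sites)).astype(np.int8)
    entries[rng.random((n_reads, n_sites)) < missing_frac] = MISSING
    weights = rng.integers(1, 10, size=(n_reads, n_sites)).astype(np.float64)
    weights[entries == MISSING] = 0.0
    sites = [SNPSite(position=10 * j, ref_allele="A", alt_allele="C",
                     depth=n_reads, ref_count=n_reads // 2,
                     alt_count=n_reads - n_reads // 2) for j in range(n_sites)]
    return AlleleMatrix(
        sites=sites, read_ids=[f"r{i}" for i in range(n_reads)],
        entries=entries, weights=weights,
    )


@pytest.fixture(scope="session")
def hifi_params() -> AssemblyParams:
    return AssemblyParams(platform="hifi")


@pytest.fixture(scope="session")
def small_diploid():
    """A 20 kb diploid with 1% heterozygosity and error-free 5 kb reads, 10x."""
    truth = simulate_diploid(20_000, 0.01, 0.0005, seed=101)
    reads = simulate_reads(truth, coverage_per_hap=10, mean_len=5_000,
                           len_sd=1_000, seed=102)
    return truth, reads
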