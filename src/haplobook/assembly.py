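"""Global stage: assemble super reads into haplotigs.

Super reads from all clusters enter a second overlap graph under much
stricter thresholds (they are long and nearly error-free, so near-perfect
identity is demanded). Remaining cross-haplotype joins are caught by the
heterozygous-SNP edge filter: reads backing both endpoint groups are mapped
across the joined overlap, and any heterozygous site there marks the join as
spurious. After tip removal and transitive reduction, every maximal
non-branching path is merged into one contig, which is optionally polished.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .consensus import map_reads, polish
from .graph import (
    break_cycles,
    build_overlap_graph,
    concat_path,
    node_sequence,
    remove_transitive_edges,
)
from .io import AssemblyParams, Read
from .overlap import (
    OL_QUERY_CONTAINED,
    OL_TARGET_CONTAINED,
    classify_and_filter,
    compute_overlaps,
)
from .phasing import MISSING, build_allele_matrix, call_snps
from .superread import SuperRead

logger = logging.getLogger("haplobook")

__all__ = [
    "Contig",
    "build_super_read_graph",
    "remove_spurious_edges_by_snps",
    "remove_tips",
    "merge_simple_paths",
    "polish_contigs",
]


@dataclass
class Contig:
    id: str
    sequence: str
    super_read_ids: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)


def _strict_params(params: AssemblyParams) -> AssemblyParams:
    """Super reads are corrected, so overlap them like HiFi-grade sequence."""
    return dc_replace(
        params,
        platform="hifi",
        min_ovlp_len=params.sr_min_ovlp_len,
        min_identity=params.sr_min_identity,
        correct_raw_reads=False,
    )


def _count_het_sites(
    joint: str,
    region: tuple[int, int],
    group_reads: dict[str, list[Read]],
    u: str,
    v: str,
    params: AssemblyParams,
) -> int:
    """Group-segregating heterozygous sites inside ``region`` of ``joint``.

    Candidate sites are called from the pooled reads of groups ``u`` and ``v``
    with the join-specific allele-frequency band. A candidate only counts if
    its alleles segregate by group: reads private to each side must agree on
    an allele at a three-quarters supermajority (at least two informative
    reads per side), and the two sides' alleles must differ. A true
    cross-haplotype join segregates cleanly at its het sites, while noise and
    alignment-wobble candidates split *within* at least one group and are
    ignored. Reads must be as sequenced (errors
    independent across reads): self-corrected reads of one group share their
    correction consensus, so a residual consensus error would masquerade as a
    perfectly group-segregated site.
    """
    u_ids = {r.id for r in group_reads.get(u, [])}
    v_ids = {r.id for r in group_reads.get(v, [])}
    pooled = {r.id: r for r in group_reads.get(u, [])}
    for r in group_reads.get(v, []):
        pooled.setdefault(r.id, r)
    caller = dc_replace(
        params, snp_af_low=params.join_af_low, snp_af_high=params.join_af_high
    )
    mapped = map_reads(list(pooled.values()), joint, platform=params.platform)
    sites = [s for s in call_snps(mapped, joint, caller)
             if region[0] <= s.position < region[1]]
    if not sites:
        return 0
    matrix = build_allele_matrix(mapped, sites)
    side = np.zeros(len(matrix.read_ids), dtype=np.int8)  # +1 u-only, -1 v-only
    for i, rid in enumerate(matrix.read_ids):
        if rid in u_ids and rid not in v_ids:
            side[i] = 1
        elif rid in v_ids and rid not in u_ids:
            side[i] = -1
    n_seg = 0
    for j in range(matrix.n_sites):
        col = matrix.entries[:, j]
        call = {}
        for s in (1, -1):
            got = col[(side == s) & (col != MISSING)]
            if len(got) < 2:
                break
            ones = int((got == 1).sum())
            if 4 * ones >= 3 * len(got):
                call[s] = 1
            elif 4 * ones <= len(got):
                call[s] = 0
            else:  # side split within itself: not haplotype signal
                break
        if len(call) == 2 and call[1] != call[-1]:
            n_seg += 1
    return n_seg


def build_super_read_graph(
    superreads: Sequence[SuperRead],
    params: AssemblyParams,
    group_reads: Optional[dict[str, list[Read]]] = None,
) -> nx.DiGraph:
    """Overlap graph over super reads with the strict thresholds.

    Same construction as the read overlap graph; super reads contained in
    others are absorbed (they appear in no node). With the SNP edge filter
    active and ``group_reads`` supplied, containments are first genotyped:
    a contained super read whose span on the container is heterozygous is a
    local haplotype that merely passed the identity threshold, so that
    overlap is discarded and the super read keeps its own node.
    """
    strict = _strict_params(params)
    as_reads = [Read(sr.id, sr.sequence) for sr in superreads]
    raw = compute_overlaps(as_reads, strict)
    kept = classify_and_filter(raw, strict, keep_contained=True)
    if params.snp_edge_filter and group_reads is not None:
        seqs = {sr.id: sr.sequence for sr in superreads}
        screened = []
        for ov in kept:
            if ov.olclass == OL_QUERY_CONTAINED:
                inner, outer = ov.query_id, ov.target_id
            elif ov.olclass == OL_TARGET_CONTAINED:
                inner, outer = ov.target_id, ov.query_id
            else:
                screened.append(ov)
                continue
            region = (ov.target_start, ov.target_end) if outer == ov.target_id \
                else (ov.query_start, ov.query_end)
            n_het = _count_het_sites(
                seqs[outer], region, group_reads, inner, outer, params
            )
            logger.debug("containment %s in %s: %d het site(s) in %s",
                         inner, outer, n_het, region)
            if n_het <= params.snp_filter_k:
                screened.append(ov)
        kept = screened
    return build_overlap_graph(as_reads, kept, strict)


def remove_spurious_edges_by_snps(
    graph: nx.DiGraph,
    superreads: Sequence[SuperRead],
    group_reads: dict[str, list[Read]],
    params: AssemblyParams,
) -> nx.DiGraph:
    """Drop joins whose overlap region genotypes as heterozygous.

    For each edge the two super reads are concatenated along their overlap,
    the as-sequenced reads of both endpoint groups are mapped onto the joint
    sequence, and candidate heterozygous sites are called inside the overlap
    region. The edge survives iff the heterozygous-site count is at most
    ``snp_filter_k`` (default 0: any heterozygous site kills the join).
    Within-haplotype joins see reads of one haplotype only and stay clean;
    cross-haplotype joins expose the haplotypes' differences as het sites.
    """
    g = graph.copy()
    seqs = {sr.id: sr.sequence for sr in superreads}
    to_remove = []
    for u, v in sorted(g.edges):
        cut = g.edges[u, v]["succ_cut"]
        useq = node_sequence(g, u, seqs)
        vseq = node_sequence(g, v, seqs)
        joint = useq + vseq[cut:]
        region = (len(useq) - cut, len(useq))
        n_het = _count_het_sites(joint, region, group_reads, u, v, params)
        logger.debug("join %s -> %s: %d het site(s) in overlap %s", u, v, n_het, region)
        if n_het > params.snp_filter_k:
            to_remove.append((u, v))
    g.remove_edges_from(to_remove)
    return g


def remove_tips(graph: nx.DiGraph, params: AssemblyParams) -> nx.DiGraph:
    """Iteratively delete short dead-end branches hanging off branching nodes.

    A source-side tip is a chain of at most ``tip_max_nodes`` nodes starting
    at an in-degree-0 node and feeding a node with in-degree > 1; sink-side
    symmetric. Applied to fixpoint.
    """
    g = graph.copy()
    limit = params.tip_max_nodes
    changed = True
    while changed:
        changed = False
        for node in sorted(g.nodes):
            if node not in g:
                continue
            # source-side tip
            if g.in_degree(node) == 0 and g.out_degree(node) == 1:
                chain = [node]
                cur = node
                while len(chain) <= limit:
                    nxt = next(iter(g.successors(cur)))
                    if g.in_degree(nxt) > 1:
                        if len(chain) <= limit:
                            g.remove_nodes_from(chain)
                            changed = True
                        break
                    if g.out_degree(nxt) != 1 or g.in_degree(nxt) != 1:
                        break
                    chain.append(nxt)
                    cur = nxt
            if node not in g:
                continue
            # sink-side tip
            if g.out_degree(node) == 0 and g.in_degree(node) == 1:
                chain = [node]
                cur = node
                while len(chain) <= limit:
                    prv = next(iter(g.predecessors(cur)))
                    if g.out_degree(prv) > 1:
                        if len(chain) <= limit:
                            g.remove_nodes_from(chain)
                            changed = True
                        break
                    if g.in_degree(prv) != 1 or g.out_degree(prv) != 1:
                        break
                    chain.append(prv)
                    cur = prv
    return g


def merge_simple_paths(
    graph: nx.DiGraph,
    superreads: Sequence[SuperRead],
) -> list[Contig]:
    """One contig per maximal non-branching path and per isolated node.

    Nodes with in- and out-degree at most one are chained wherever the
    connecting edge is the unique choice on both sides; branching nodes stand
    alone. Every surviving node lands in exactly one contig. Sequences are
    overlap-aware concatenations along the path.
    """
    seqs = {sr.id: sr.sequence for sr in superreads}
    g = graph

    def simple(v) -> bool:
        return g.in_degree(v) <= 1 and g.out_degree(v) <= 1

    used: set[str] = set()
    contigs: list[Contig] = []

    def emit(path: list[str]) -> None:
        seq = concat_path(path, g, seqs)
        contigs.append(Contig(f"contig{len(contigs)}", seq, list(path)))

    for node in sorted(g.nodes):
        if node in used or not simple(node):
            continue
        # walk back to the start of this simple chain
        start = node
        seen = {start}
        while g.in_degree(start) == 1:
            prv = next(iter(g.predecessors(start)))
            if not simple(prv) or g.out_degree(prv) != 1 or prv in seen:
                break
            start = prv
            seen.add(start)
        path = [start]
        cur = start
        while g.out_degree(cur) == 1:
            nxt = next(iter(g.successors(cur)))
            if not simple(nxt) or g.in_degree(nxt) != 1 or nxt in path:
                break
            path.append(nxt)
            cur = nxt
        used.update(path)
        emit(path)
    for node in sorted(g.nodes):
        if node not in used:
            used.add(node)
            emit([node])
    return contigs


def polish_contigs(
    contigs: Sequence[Contig],
    superreads: Sequence[SuperRead],
    group_reads: dict[str, list[Read]],
    params: AssemblyParams,
) -> list[Contig]:
    """Pileup-polish each contig with its constituent groups' reads; drop short ones."""
    out: list[Contig] = []
    for contig in contigs:
        seq = contig.sequence
        if params.polish_final:
            reads: dict[str, Read] = {}
            for sr_id in contig.super_read_ids:
                for r in group_reads.get(sr_id, []):
                    reads.setdefault(r.id, r)
            if reads:
                seq, _, _ = polish(seq, list(reads.values()),
                                   platform=params.platform, rounds=1)
        if len(seq) >= params.min_contig_len:
            out.append(Contig(contig.id, seq, contig.super_read_ids))
    return out
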