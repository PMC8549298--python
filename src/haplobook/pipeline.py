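"""End-to-end orchestration: overlap, cluster, phase, super reads, haplotigs.

Per-cluster work (local assembly, phasing, super-read construction) is
independent across clusters and can run on several workers; results are
always combined in cluster-id order, so the output is identical for any
worker count at a fixed seed.
"""

from __future__ import annotations

import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .assembly import (
    Contig,
    build_super_read_graph,
    merge_simple_paths,
    polish_contigs,
    remove_spurious_edges_by_snps,
    remove_tips,
)
from .cluster import ReadCluster, build_clusters
from .consensus import map_reads
from .graph import break_cycles, build_ad_hoc_reference, remove_transitive_edges
from .io import AssemblyParams, Read
from .overlap import Overlap, classify_and_filter, compute_overlaps
from .phasing import assign_unphased, build_allele_matrix, call_snps, solve_wmec
from .superread import SuperRead, build_super_read, correct_group_reads, trim_super_read

logger = logging.getLogger("haplobook")

__all__ = ["AssemblyResult", "assemble", "process_cluster"]


@dataclass
class AssemblyResult:
    contigs: list[Contig]
    superreads: list[SuperRead]
    clusters: list[ReadCluster]
    overlaps: list[Overlap]
    manifest: dict = field(default_factory=dict)


@dataclass
class ClusterResult:
    cluster_id: int
    superreads: list[SuperRead]
    group_reads: dict[str, list[Read]]  # per super read, possibly corrected
    group_reads_raw: dict[str, list[Read]]  # per super read, as sequenced
    n_sites: int
    mec_cost: float


def process_cluster(
    cluster: ReadCluster,
    members: Sequence[Read],
    overlaps: Sequence[Overlap],
    params: AssemblyParams,
) -> ClusterResult:
    """Phase one cluster and assemble its (one or two) super reads."""
    members = sorted(members, key=lambda r: r.id)
    if len(members) == 1:
        read = members[0]
        srs = []
        group_reads = {}
        if read.length >= params.min_ovlp_len:
            sr = build_super_read(cluster.cluster_id, 0, members, params)
            if sr is not None:
                srs.append(sr)
                group_reads[sr.id] = list(members)
        return ClusterResult(cluster.cluster_id, srs, group_reads, dict(group_reads), 0, 0.0)

    backbone = build_ad_hoc_reference(cluster.cluster_id, members, overlaps, params)
    mapped = map_reads(members, backbone.sequence, platform=params.platform)
    sites = call_snps(mapped, backbone.sequence, params)
    matrix = build_allele_matrix(mapped, sites)
    phasing = solve_wmec(matrix, params)
    phasing = assign_unphased([r.id for r in members], phasing)

    by_id = {r.id: r for r in members}
    h1 = phasing.group("H1")
    h2 = phasing.group("H2")
    both = phasing.group("both")
    if h1 and h2:
        groups = [(1, h1 + both), (2, h2 + both)]
    elif h1 or h2:
        groups = [(0, sorted(set(h1 + h2 + both)))]
    else:
        groups = [(0, both)]

    srs: list[SuperRead] = []
    group_reads: dict[str, list[Read]] = {}
    group_reads_raw: dict[str, list[Read]] = {}
    for phase, ids in groups:
        raw_reads = [by_id[i] for i in sorted(set(ids))]
        if not raw_reads:
            continue
        if params.correct_raw_reads:
            reads = correct_group_reads(raw_reads, params)
            # corrected reads share one consensus (correlated errors); polish
            # with the raw reads, whose errors are independent
            sr = build_super_read(cluster.cluster_id, phase, reads, params,
                                  polish_reads=raw_reads)
        else:
            reads = raw_reads
            sr = build_super_read(cluster.cluster_id, phase, reads, params)
        if sr is None:
            continue
        sr = trim_super_read(sr, params)
        if sr is None:
            continue
        srs.append(sr)
        group_reads[sr.id] = reads
        group_reads_raw[sr.id] = raw_reads
    return ClusterResult(cluster.cluster_id, srs, group_reads, group_reads_raw,
                         len(sites), phasing.mec_cost)


def _cluster_task(args) -> ClusterResult:
    return process_cluster(*args)


def assemble(
    reads: Sequence[Read],
    params: AssemblyParams,
    paf_overlaps: Optional[Sequence[Overlap]] = None,
) -> AssemblyResult:
    """Run the whole pipeline on a read set.

    If ``paf_overlaps`` is given (e.g. from an external overlapper via PAF),
    overlap computation is skipped but filtering still applies.
    """
    reads = list(reads)
    if not reads:
        raise ValueError("no input reads")
    if paf_overlaps is not None:
        raw = list(paf_overlaps)
    else:
        logger.info("computing all-vs-all overlaps for %d reads", len(reads))
        raw = compute_overlaps(reads, params)
    kept = classify_and_filter(raw, params, keep_contained=True)
    logger.info("overlaps: %d raw, %d retained", len(raw), len(kept))
    clusters = build_clusters(reads, kept)
    logger.info("%d clusters", len(clusters))

    by_id = {r.id: r for r in reads}
    ovl_by_read: dict[str, list[Overlap]] = {}
    for ov in kept:
        ovl_by_read.setdefault(ov.query_id, []).append(ov)
    tasks = []
    for cl in clusters:
        members = [by_id[i] for i in sorted(cl.member_ids)]
        covl = [
            ov
            for rid in sorted(cl.member_ids)
            for ov in ovl_by_read.get(rid, [])
            if ov.target_id in cl.member_ids
        ]
        tasks.append((cl, members, covl, params))

    if params.threads > 1:
        with ProcessPoolExecutor(max_workers=params.threads) as ex:
            results = list(ex.map(_cluster_task, tasks, chunksize=1))
    else:
        results = [_cluster_task(t) for t in tasks]
    results.sort(key=lambda r: r.cluster_id)

    superreads: list[SuperRead] = []
    group_reads: dict[str, list[Read]] = {}
    group_reads_raw: dict[str, list[Read]] = {}
    for res in results:
        superreads.extend(res.superreads)
        group_reads.update(res.group_reads)
        group_reads_raw.update(res.group_reads_raw)
    logger.info("%d super reads", len(superreads))

    g = build_super_read_graph(superreads, params, group_reads_raw)
    if params.snp_edge_filter:
        g = remove_spurious_edges_by_snps(g, superreads, group_reads_raw, params)
    g = remove_tips(g, params)
    g = remove_transitive_edges(g)
    g = break_cycles(g)
    contigs = merge_simple_paths(g, superreads)
    contigs = polish_contigs(contigs, superreads, group_reads_raw, params)
    logger.info("%d final contigs", len(contigs))

    manifest = {
        "params": {
            "platform": params.platform,
            "min_ovlp_len": params.min_ovlp_len,
            "min_identity": params.min_identity,
            "snp_filter_k": params.snp_filter_k,
            "snp_edge_filter": params.snp_edge_filter,
            "correct_raw_reads": params.correct_raw_reads,
            "polish_final": params.polish_final,
            "rng_seed": params.rng_seed,
        },
        "n_reads": len(reads),
        "n_overlaps_raw": len(raw),
        "n_overlaps_kept": len(kept),
        "n_clusters": len(clusters),
        "cluster_sizes_total": sum(c.size for c in clusters),
        "n_snp_sites": sum(r.n_sites for r in results),
        "n_super_reads": len(superreads),
        "n_contigs": len(contigs),
        "total_contig_bases": sum(c.length for c in contigs),
    }
    return AssemblyResult(contigs, superreads, clusters, kept, manifest)
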