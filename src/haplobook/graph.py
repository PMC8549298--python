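"""Overlap-graph construction and layout: the shared OLC machinery.

Used twice: per-cluster on raw reads (to lay out an ad hoc reference) and
globally on super reads (to lay out haplotigs). Nodes are sequences with a
fixed orientation; a directed edge u -> v means the suffix of u (in its
oriented frame) matches the prefix of v, and carries the number of bases v
extends beyond u.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .align import revcomp
from .consensus import polish
from .io import AssemblyParams, Read
from .overlap import (
    OL_QUERY_CONTAINED,
    OL_TARGET_CONTAINED,
    Overlap,
)

__all__ = [
    "build_overlap_graph",
    "remove_transitive_edges",
    "break_cycles",
    "longest_path",
    "concat_path",
    "AdHocReference",
    "build_ad_hoc_reference",
]


def _oriented_coords(ov: Overlap, ori_q: int, ori_t: int) -> Optional[tuple[int, int, int, int]]:
    """Overlap coordinates in the two reads' oriented frames, or None on conflict."""
    s = -1 if ov.strand == "-" else 1
    if s * ori_q * ori_t != 1:
        return None
    qs, qe = ov.query_start, ov.query_end
    ts, te = ov.target_start, ov.target_end
    if ori_q == -1:
        qs, qe = ov.query_len - ov.query_end, ov.query_len - ov.query_start
    if ori_t == -1:
        ts, te = ov.target_len - ov.target_end, ov.target_len - ov.target_start
    return qs, qe, ts, te


def build_overlap_graph(
    members: Sequence[Read],
    overlaps: Sequence[Overlap],
    params: AssemblyParams,
) -> nx.DiGraph:
    """Directed overlap graph over the non-contained members.

    Each read gets a global orientation by breadth-first propagation over the
    overlap adjacency (seeded at the longest read, forward); an overlap whose
    strand disagrees with the propagated orientations is dropped. Containments
    contribute no node or edge: a contained read adds no extension.

    Node attrs: ``length``, ``ori`` (+1 forward / -1 reverse).
    Edge attrs: ``overlap``, ``succ_cut`` (end of the overlap on the successor,
    oriented frame), ``ext`` (bases the successor adds).
    """
    ids = {r.id for r in members}
    lengths = {r.id: r.length for r in members}
    contained: set[str] = set()
    usable: list[Overlap] = []
    for ov in overlaps:
        if ov.query_id not in ids or ov.target_id not in ids:
            continue
        if ov.olclass == OL_QUERY_CONTAINED:
            contained.add(ov.query_id)
        elif ov.olclass == OL_TARGET_CONTAINED:
            contained.add(ov.target_id)
        else:
            usable.append(ov)
    usable = [
        ov for ov in usable if ov.query_id not in contained and ov.target_id not in contained
    ]
    nodes = sorted(ids - contained, key=lambda i: (-lengths[i], i))
    # breadth-first orientation propagation
    adj: dict[str, list[tuple[str, int]]] = {n: [] for n in nodes}
    for ov in usable:
        s = -1 if ov.strand == "-" else 1
        adj[ov.query_id].append((ov.target_id, s))
        adj[ov.target_id].append((ov.query_id, s))
    ori: dict[str, int] = {}
    from collections import deque

    for start in nodes:
        if start in ori:
            continue
        ori[start] = 1
        dq = deque([start])
        while dq:
            u = dq.popleft()
            for v, s in adj[u]:
                if v not in ori:
                    ori[v] = ori[u] * s
                    dq.append(v)
    g = nx.DiGraph()
    for n in nodes:
        g.add_node(n, length=lengths[n], ori=ori[n])
    for ov in usable:
        coords = _oriented_coords(ov, ori[ov.query_id], ori[ov.target_id])
        if coords is None:
            continue  # orientation conflict; drop the later edge
        qs, qe, ts, te = coords
        if qs > ts:
            pred, succ = ov.query_id, ov.target_id
            succ_cut = te
            succ_len = ov.target_len
        elif ts > qs:
            pred, succ = ov.target_id, ov.query_id
            succ_cut = qe
            succ_len = ov.query_len
        else:
            continue  # no extension either way
        ext = succ_len - succ_cut
        if ext < 0 or pred == succ or g.has_edge(pred, succ):
            continue
        g.add_edge(pred, succ, overlap=ov, succ_cut=succ_cut, ext=ext)
    return g


def remove_transitive_edges(graph: nx.DiGraph) -> nx.DiGraph:
    """Drop every edge u->v that has a two-edge witness u->w->v.

    All witnesses are evaluated against the input edge set, then removals are
    applied at once; on a DAG this preserves reachability.
    """
    g = graph.copy()
    to_remove = []
    for u, v in g.edges:
        for w in g.successors(u):
            if w != v and g.has_edge(w, v):
                to_remove.append((u, v))
                break
    g.remove_edges_from(to_remove)
    return g


def break_cycles(graph: nx.DiGraph) -> nx.DiGraph:
    """Delete the lowest-extension edge of each remaining cycle until acyclic.

    Real overlap graphs are almost always acyclic; repeats and palindromes can
    produce rare cycles, which we break at their weakest (least-extending)
    link, ties by edge endpoints.
    """
    g = graph.copy()
    while True:
        try:
            cycle = nx.find_cycle(g, orientation="original")
        except nx.NetworkXNoCycle:
            return g
        worst = min(cycle, key=lambda e: (g.edges[e[0], e[1]]["ext"], e[0], e[1]))
        g.remove_edge(worst[0], worst[1])


def longest_path(graph: nx.DiGraph) -> list[str]:
    """Path maximizing assembled bases (first node length + summed extensions).

    The graph must be acyclic. Dynamic programming in topological order; ties
    broken towards lexicographically smaller predecessors for determinism.
    """
    if graph.number_of_nodes() == 0:
        return []
    best: dict[str, int] = {}
    pred: dict[str, Optional[str]] = {}
    for v in nx.topological_sort(graph):
        best[v] = graph.nodes[v]["length"]
        pred[v] = None
        for u in sorted(graph.predecessors(v)):
            score = best[u] + graph.edges[u, v]["ext"]
            if score > best[v]:
                best[v] = score
                pred[v] = u
    end = max(best, key=lambda v: (best[v], v))
    path = [end]
    while pred[path[-1]] is not None:
        path.append(pred[path[-1]])
    path.reverse()
    return path


def node_sequence(graph: nx.DiGraph, node: str, sequences: dict[str, str]) -> str:
    seq = sequences[node]
    return revcomp(seq) if graph.nodes[node]["ori"] == -1 else seq


def concat_path(path: Sequence[str], graph: nx.DiGraph, sequences: dict[str, str]) -> str:
    """Overlap-aware concatenation: first node plus each successor's unaligned suffix."""
    if not path:
        return ""
    out = [node_sequence(graph, path[0], sequences)]
    for u, v in zip(path, path[1:]):
        cut = graph.edges[u, v]["succ_cut"]
        out.append(node_sequence(graph, v, sequences)[cut:])
    return "".join(out)


@dataclass
class AdHocReference:
    """A cluster-local backbone used only to give reads shared coordinates."""

    cluster_id: int
    sequence: str
    source_path: list[str]
    coverage: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))


def build_ad_hoc_reference(
    cluster_id: int,
    members: Sequence[Read],
    overlaps: Sequence[Overlap],
    params: AssemblyParams,
    do_polish: bool = True,
) -> AdHocReference:
    """Lay out and (optionally) polish the cluster backbone.

    Graph construction, transitive-edge removal, cycle breaking, longest-path
    extraction, concatenation, then pileup polishing with all cluster reads.
    """
    seqs = {r.id: r.sequence for r in members}
    g = build_overlap_graph(members, overlaps, params)
    g = remove_transitive_edges(g)
    g = break_cycles(g)
    path = longest_path(g)
    if not path:
        # every member contained in another; fall back to the longest read
        longest = max(members, key=lambda r: (r.length, r.id))
        seq = longest.sequence
        path = [longest.id]
    else:
        seq = concat_path(path, g, seqs)
    coverage = np.ones(len(seq), dtype=np.int64)
    if do_polish:
        seq, coverage, _ = polish(seq, members, platform=params.platform, rounds=params.polish_rounds)
    return AdHocReference(cluster_id, seq, list(path), coverage)
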