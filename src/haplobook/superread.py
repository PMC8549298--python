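"""Per-haplotype-group read correction and super-read assembly.

After phasing, each cluster carries one or two haplotype-specific read groups
(plus reads assigned to both). For noisy platforms the group's reads are first
self-corrected against a group-local backbone — correcting within one
haplotype avoids averaging away true variation. Each group is then assembled
through the shared OLC machinery into a super read, polished with the
(corrected) group reads, and trimmed to its well-supported core.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .align import revcomp
from .consensus import build_pileup, consensus as pileup_consensus, map_reads, polish
from .graph import (
    break_cycles,
    build_ad_hoc_reference,
    build_overlap_graph,
    concat_path,
    longest_path,
    remove_transitive_edges,
)
from .io import AssemblyParams, Read
from .overlap import classify_and_filter, compute_overlaps

__all__ = ["SuperRead", "correct_group_reads", "build_super_read", "trim_super_read"]


@dataclass
class SuperRead:
    id: str
    cluster_id: int
    phase: int  # 1, 2, or 0 for unphased
    sequence: str
    coverage: np.ndarray
    constituent_ids: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)


def correct_group_reads(group_reads: Sequence[Read], params: AssemblyParams) -> list[Read]:
    """Self-correct a haplotype group against its own consensus backbone.

    The group's reads are laid out into a group-local backbone (longest read
    chain), the pileup majority is voted, and each read's aligned span is
    replaced by the corresponding consensus segment; unaligned read ends are
    left untouched. Groups of one read are returned unchanged.
    """
    if len(group_reads) <= 1:
        return list(group_reads)
    backbone = build_ad_hoc_reference(-1, group_reads, _group_overlaps(group_reads, params), params)
    mapped = map_reads(group_reads, backbone.sequence, platform=params.platform)
    placed = {mr.read.id: mr for mr in mapped}
    out: list[Read] = []
    for read in group_reads:
        mr = placed.get(read.id)
        if mr is None:
            out.append(read)
            continue
        seg = backbone.sequence[mr.aln.r_start : mr.aln.r_end]
        oriented = mr.oriented_seq
        corrected = oriented[: mr.aln.q_start] + seg + oriented[mr.aln.q_end :]
        if mr.aln.strand == "-":
            corrected = revcomp(corrected)
        out.append(Read(read.id, corrected))
    return out


def _group_overlaps(group_reads: Sequence[Read], params: AssemblyParams):
    raw = compute_overlaps(group_reads, params)
    return classify_and_filter(raw, params, keep_contained=True)


def build_super_read(
    cluster_id: int,
    phase: int,
    group_reads: Sequence[Read],
    params: AssemblyParams,
    polish_reads: Optional[Sequence[Read]] = None,
) -> Optional[SuperRead]:
    """Assemble one phase group into a polished super read.

    Overlap graph over the group, transitive reduction, longest path,
    concatenation, then pileup polishing; the polish-stage coverage profile is
    kept for trimming. A single-read group yields that read as its own super
    read.

    ``polish_reads`` are the reads voted in the polish (default: the group
    reads themselves). When the group reads were self-corrected, pass the
    original raw reads here: correction copies one consensus into every read,
    so corrected reads carry *correlated* errors and voting them cannot fix
    what the correction backbone got wrong, while raw-read errors are
    independent and majority vote drives them down.
    """
    if not group_reads:
        return None
    sr_id = f"sr{cluster_id}.{phase}"
    if len(group_reads) == 1:
        read = group_reads[0]
        return SuperRead(
            sr_id, cluster_id, phase, read.sequence,
            np.ones(read.length, dtype=np.int64), [read.id],
        )
    overlaps = _group_overlaps(group_reads, params)
    seqs = {r.id: r.sequence for r in group_reads}
    g = build_overlap_graph(group_reads, overlaps, params)
    g = remove_transitive_edges(g)
    g = break_cycles(g)
    path = longest_path(g)
    if not path:
        longest = max(group_reads, key=lambda r: (r.length, r.id))
        backbone = longest.sequence
        path = [longest.id]
    else:
        backbone = concat_path(path, g, seqs)
    voters = list(polish_reads) if polish_reads is not None else list(group_reads)
    seq, coverage, _ = polish(backbone, voters, platform=params.platform,
                              rounds=params.polish_rounds)
    return SuperRead(sr_id, cluster_id, phase, seq, coverage,
                     sorted(r.id for r in group_reads))


def trim_super_read(sr: SuperRead, params: AssemblyParams) -> Optional[SuperRead]:
    """Keep the longest contiguous stretch of adequately covered bases.

    Thinly supported ends dominate residual errors, so the longest run with
    coverage >= ``sr_trim_min_cov`` (2 for HiFi; 5 for noisy platforms, where
    fewer voters tie or let two coincident errors win) is retained; a super
    read built from a single read (coverage 1 throughout, nothing to vote
    with) is exempt. Returns None if the retained interval is shorter than
    the minimum overlap length.
    """
    threshold = params.sr_trim_min_cov if len(sr.constituent_ids) > 1 else 1
    ok = sr.coverage >= threshold
    if len(ok) != len(sr.sequence):  # defensive; profiles always match
        ok = np.ones(len(sr.sequence), dtype=bool)
    best_start = best_len = 0
    run_start = None
    for i, flag in enumerate(ok.tolist() + [False]):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if i - run_start > best_len:
                best_start, best_len = run_start, i - run_start
            run_start = None
    if best_len < params.min_ovlp_len:
        return None
    return SuperRead(
        sr.id, sr.cluster_id, sr.phase,
        sr.sequence[best_start : best_start + best_len],
        sr.coverage[best_start : best_start + best_len],
        sr.constituent_ids,
    )
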