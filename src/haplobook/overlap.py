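"""All-vs-all long-read overlap detection and dovetail filtering.

Candidate read pairs are found by shared minimizers, chained colinearly, and
the implied end-to-end overlap is verified by banded edit-distance alignment.
Raw overlaps are then classified (dovetail / containment / internal / self)
with the classic overhang rule used by miniasm-style filters, and only proper
dovetails of sufficient length and identity are kept for graph building.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional

import edlib

from .align import MinimizerIndex, chain_anchors, revcomp
from .io import AssemblyParams, Read

# dovetail classification constants (overhang rule defaults)
MAX_HANG = 1000
INTERNAL_FRAC = 0.8

OL_DOVETAIL_QT = "dovetail_qsuffix_tprefix"
OL_DOVETAIL_TQ = "dovetail_qprefix_tsuffix"
OL_QUERY_CONTAINED = "query_contained"
OL_TARGET_CONTAINED = "target_contained"
OL_INTERNAL = "internal"
OL_SELF = "self"


@dataclass
class Overlap:
    """A pairwise read overlap with PAF coordinate semantics.

    Coordinates are 0-based half-open on the forward strand of each read;
    for strand '-' the query's forward strand aligns to the target's reverse
    complement, with target coordinates still on the target's forward strand.
    """

    query_id: str
    target_id: str
    query_len: int
    target_len: int
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    strand: str
    n_matches: int
    block_len: int
    olclass: Optional[str] = None

    @property
    def identity(self) -> float:
        return self.n_matches / self.block_len if self.block_len else 0.0

    def swapped(self) -> "Overlap":
        """The same overlap with query and target roles exchanged."""
        return replace(
            self,
            query_id=self.target_id,
            target_id=self.query_id,
            query_len=self.target_len,
            target_len=self.query_len,
            query_start=self.target_start,
            query_end=self.target_end,
            target_start=self.query_start,
            target_end=self.query_end,
        )


def _sketch_params(platform: str) -> tuple[int, int]:
    # denser sketch for noisy platforms so true overlaps keep enough seeds
    return (15, 10) if platform == "hifi" else (15, 5)


def _band_frac(platform: str) -> float:
    return 0.05 if platform == "hifi" else 0.15


def _align_span(a: str, b: str, band_frac: float, min_identity: float) -> Optional[int]:
    """Global edit distance of two putative-overlap spans, or None if over band."""
    span = max(len(a), len(b))
    limit = int(span * max(band_frac * 1.5, (1.0 - min_identity) * 1.3)) + 20
    res = edlib.align(a, b, mode="NW", task="distance", k=limit)
    d = res["editDistance"]
    return None if d < 0 else d


def compute_overlaps(reads: Iterable[Read], params: AssemblyParams) -> list[Overlap]:
    """Detect pairwise overlaps among reads.

    For every unordered pair sharing at least 3 colinear minimizers in one
    relative orientation, the chain's median diagonal implies an end-to-end
    overlap; the two spans are aligned globally and the overlap is emitted
    with identity = 1 - edits / span. Each pair is reported at most once, with
    the lexicographically smaller id as query.
    """
    reads = list(reads)
    seqs = {r.id: r.sequence for r in reads}
    k, w = _sketch_params(params.platform)
    index = MinimizerIndex(seqs, k=k, w=w)
    band = _band_frac(params.platform)
    out: list[Overlap] = []
    done: set[tuple[str, str]] = set()
    for read in sorted(reads, key=lambda r: r.id):
        anch = index.anchors(read.sequence)
        # group candidate targets, best orientation each
        cands: dict[str, dict[int, list]] = {}
        for (tid, rel), pairs in anch.items():
            if tid == read.id:
                continue
            if (min(read.id, tid), max(read.id, tid)) in done:
                continue
            if read.id > tid:
                continue  # canonical: smaller id acts as query
            cands.setdefault(tid, {})[rel] = pairs
        for tid, by_rel in sorted(cands.items()):
            best_chain, best_rel = [], 0
            for rel, pairs in sorted(by_rel.items()):
                ch = chain_anchors(pairs)
                if len(ch) > len(best_chain):
                    best_chain, best_rel = ch, rel
            if len(best_chain) < 3:
                continue
            ov = _pair_overlap(
                read.id, tid, seqs[read.id], seqs[tid], best_chain, best_rel,
                band, params.min_identity,
            )
            if ov is not None:
                out.append(ov)
                done.add((min(read.id, tid), max(read.id, tid)))
    return out


def _pair_overlap(
    qid: str,
    tid: str,
    qseq: str,
    tseq: str,
    chain: list[tuple[int, int]],
    rel: int,
    band_frac: float,
    min_identity: float,
) -> Optional[Overlap]:
    """Turn a seed chain into a blunt-ended verified overlap (or None)."""
    qlen, tlen = len(qseq), len(tseq)
    # anchors are (qpos-in-oriented-frame, tpos); diagonal maps q -> t
    offs = sorted(t - q for q, t in chain)
    d = offs[len(offs) // 2]
    q_o = revcomp(qseq) if rel else qseq
    qs = max(0, -d)
    qe = min(qlen, tlen - d)
    if qe - qs < 50:
        return None
    ts, te = qs + d, qe + d
    dist = _align_span(q_o[qs:qe], tseq[ts:te], band_frac, min_identity)
    if dist is None:
        return None
    block = max(qe - qs, te - ts)
    if rel:
        # report query coords on its forward strand
        qs_f, qe_f = qlen - qe, qlen - qs
        strand = "-"
    else:
        qs_f, qe_f = qs, qe
        strand = "+"
    return Overlap(
        query_id=qid, target_id=tid,
        query_len=qlen, target_len=tlen,
        query_start=qs_f, query_end=qe_f,
        target_start=ts, target_end=te,
        strand=strand,
        n_matches=max(0, block - dist),
        block_len=block,
    )


def classify(ov: Overlap, max_hang: int = MAX_HANG, int_frac: float = INTERNAL_FRAC) -> str:
    """Assign an overlap class by the overhang rule.

    Overhang o = min(qs', ts) + min(qlen - qe', tlen - te), with the query
    coordinates flipped for '-' strand overlaps. Internal if o exceeds
    min(max_hang, int_frac * block_len); otherwise containment if one read's
    aligned span reaches (within the overhang) both of its ends; otherwise a
    dovetail whose direction follows which read provides the suffix.
    """
    if ov.query_id == ov.target_id:
        return OL_SELF
    if ov.strand == "-":
        qs = ov.query_len - ov.query_end
        qe = ov.query_len - ov.query_start
    else:
        qs, qe = ov.query_start, ov.query_end
    ts, te = ov.target_start, ov.target_end
    left = min(qs, ts)
    right = min(ov.query_len - qe, ov.target_len - te)
    overhang = left + right
    if overhang > min(max_hang, int(int_frac * ov.block_len)):
        return OL_INTERNAL
    if qs <= ts and ov.query_len - qe <= ov.target_len - te:
        return OL_QUERY_CONTAINED
    if qs >= ts and ov.query_len - qe >= ov.target_len - te:
        return OL_TARGET_CONTAINED
    if qs > ts:
        return OL_DOVETAIL_QT  # query suffix overlaps target prefix
    return OL_DOVETAIL_TQ


def classify_and_filter(
    overlaps: Iterable[Overlap],
    params: AssemblyParams,
    keep_contained: bool = False,
) -> list[Overlap]:
    """Reduce raw overlaps to usable ones.

    Order: self-overlaps out, duplicates out (canonical query = smaller id),
    classification, then length and identity thresholds. Internal matches are
    always dropped; containments are dropped unless ``keep_contained`` (the
    pipeline keeps them through clustering and phasing, where contained reads
    still carry haplotype information, and drops them at graph building).
    """
    seen: set[tuple[str, str, str]] = set()
    out: list[Overlap] = []
    for ov in overlaps:
        if ov.query_id == ov.target_id:
            continue
        if ov.query_id > ov.target_id:
            ov = ov.swapped()
        key = (ov.query_id, ov.target_id, ov.strand)
        if key in seen:
            continue
        seen.add(key)
        cls = classify(ov)
        if cls == OL_INTERNAL:
            continue
        if cls in (OL_QUERY_CONTAINED, OL_TARGET_CONTAINED) and not keep_contained:
            continue
        if ov.block_len < params.min_ovlp_len:
            continue
        if ov.identity < params.min_identity:
            continue
        ov = replace(ov, olclass=cls)
        out.append(ov)
    return out
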