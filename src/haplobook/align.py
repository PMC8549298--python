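"""Minimizer seeding, colinear chaining, and edlib-backed base-level alignment.

This is the single alignment engine of the package: all-vs-all read overlap
detection, read-to-backbone mapping for polishing and SNP calling, and
contig-to-truth alignment in the evaluators all run through it.

Seeds are canonical-k-mer minimizers (smallest hashed k-mer per window of w
consecutive k-mers). Candidate placements are chained by longest increasing
subsequence on seed positions; the chained span is then aligned at base level
with edlib to obtain coordinates, an edit distance, and a CIGAR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import edlib
import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _encode(seq: str) -> np.ndarray:
    """2-bit-encode; non-ACGT bases become 255 (excluded from seeding)."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _mix64(x: np.ndarray) -> np.ndarray:
    # splitmix64 finalizer; decorrelates lexicographic k-mer order
    x = x.astype(np.uint64, copy=True)
    x ^= x >> np.uint64(30)
    x *= np.uint64(0xBF58476D1CE4E5B9)
    x ^= x >> np.uint64(27)
    x *= np.uint64(0x94D049BB133111EB)
    x ^= x >> np.uint64(31)
    return x


def minimizers(seq: str, k: int, w: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (hash, position, strand) arrays of window minimizers.

    The k-mer at each position is compared with its reverse complement; the
    smaller 2k-bit code is hashed, and ``strand`` records whether the forward
    (0) or reverse (1) form was canonical. Windows containing ambiguous bases
    yield no seed.
    """
    n = len(seq) - k + 1
    if n < 1:
        e = np.empty(0, dtype=np.uint64)
        return e, np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint8)
    codes = _encode(seq)
    valid = codes != 255
    c = np.where(valid, codes, 0).astype(np.uint64)
    win = np.lib.stride_tricks.sliding_window_view(c, k)
    pw_f = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    pw_r = (np.uint64(4) ** np.arange(k, dtype=np.uint64))
    fwd = win @ pw_f
    rev = (np.uint64(3) - win) @ pw_r
    canon = np.minimum(fwd, rev)
    strand = (rev < fwd).astype(np.uint8)
    h = _mix64(canon)
    ok = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
    # ambiguous k-mers get the max hash so they never win a window
    h = np.where(ok, h, np.uint64(0xFFFFFFFFFFFFFFFF))
    if n < w:
        w = n
    hwin = np.lib.stride_tricks.sliding_window_view(h, w)
    arg = hwin.argmin(axis=1)
    pos = np.unique((np.arange(len(arg)) + arg).astype(np.int64))
    hh = h[pos]
    sel = hh != np.uint64(0xFFFFFFFFFFFFFFFF)
    return hh[sel], pos[sel], strand[pos][sel]


class MinimizerIndex:
    """Hash -> occurrence lists over a collection of named sequences."""

    def __init__(self, sequences: dict[str, str], k: int, w: int, max_hits: int = 200):
        self.k = k
        self.w = w
        self.max_hits = max_hits
        self.lengths = {name: len(s) for name, s in sequences.items()}
        table: dict[int, list[tuple[str, int, int]]] = {}
        for name, seq in sequences.items():
            hh, pp, ss = minimizers(seq, k, w)
            for h, p, s in zip(hh.tolist(), pp.tolist(), ss.tolist()):
                table.setdefault(h, []).append((name, p, s))
        # drop hyper-repetitive seeds
        self.table = {h: occ for h, occ in table.items() if len(occ) <= max_hits}

    def anchors(self, seq: str) -> dict[tuple[str, int], list[tuple[int, int]]]:
        """Match seq's minimizers against the index.

        Returns {(target_name, relative_orientation): [(qpos, tpos), ...]}
        where relative_orientation 0 means the query matches the target
        forward and 1 means it matches the reverse complement. For orientation
        1 the query position is flipped (qpos' = qlen - k - qpos) so that
        anchors of a true overlap are co-increasing in both coordinates.
        """
        hh, pp, ss = minimizers(seq, self.k, self.w)
        qlen = len(seq)
        out: dict[tuple[str, int], list[tuple[int, int]]] = {}
        for h, qp, qs in zip(hh.tolist(), pp.tolist(), ss.tolist()):
            occ = self.table.get(h)
            if not occ:
                continue
            for name, tp, ts in occ:
                rel = qs ^ ts
                if rel:
                    qp2 = qlen - self.k - qp
                else:
                    qp2 = qp
                out.setdefault((name, rel), []).append((qp2, tp))
        return out


def chain_anchors(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest co-increasing chain of (qpos, tpos) anchors.

    Anchors are sorted by qpos (then tpos) and the longest strictly increasing
    subsequence in tpos is extracted (patience sorting, O(n log n)).
    """
    if not pairs:
        return []
    pairs = sorted(set(pairs))
    tpos = [t for _, t in pairs]
    import bisect

    tails: list[int] = []  # tpos of smallest tail of LIS of each length
    tails_idx: list[int] = []
    prev = [-1] * len(pairs)
    for i, t in enumerate(tpos):
        j = bisect.bisect_left(tails, t)
        if j == len(tails):
            tails.append(t)
            tails_idx.append(i)
        else:
            tails[j] = t
            tails_idx[j] = i
        prev[i] = tails_idx[j - 1] if j > 0 else -1
    chain = []
    i = tails_idx[-1]
    while i >= 0:
        chain.append(pairs[i])
        i = prev[i]
    chain.reverse()
    return chain


@dataclass
class Alignment:
    """A base-level placement of a query on a reference."""

    q_start: int  # on the oriented query
    q_end: int
    r_start: int
    r_end: int
    strand: str  # '+' if query used forward, '-' if reverse-complemented
    cigar: str  # extended CIGAR (=, X, I, D); I consumes query, D reference
    edit_distance: int

    @property
    def block_len(self) -> int:
        return max(self.q_end - self.q_start, self.r_end - self.r_start)

    @property
    def identity(self) -> float:
        b = self.block_len
        return 1.0 - self.edit_distance / b if b else 0.0


_CIGAR_OPS = frozenset("=XID")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = []
    num = 0
    for ch in cigar:
        if ch.isdigit():
            num = num * 10 + ord(ch) - 48
        else:
            if ch not in _CIGAR_OPS:
                raise ValueError(f"bad CIGAR op {ch!r}")
            ops.append((num, ch))
            num = 0
    return ops


def map_to_reference(
    query: str,
    reference: str,
    index: Optional[MinimizerIndex] = None,
    k: int = 15,
    w: int = 5,
    min_anchors: int = 3,
    max_divergence: float = 0.35,
) -> Optional[Alignment]:
    """Place a query on a reference and align it at base level.

    The minimizer chain fixes the approximate diagonal; the query (clipped to
    the part that can lie on the reference) is then aligned to the implied
    reference window with edlib in infix mode. Returns None if no adequate
    seeding or if the alignment diverges beyond ``max_divergence``.
    """
    if index is None:
        index = MinimizerIndex({"ref": reference}, k=k, w=w)
        ref_name = "ref"
    else:
        ref_name = next(iter(index.lengths))
    anch = index.anchors(query)
    best_chain, best_rel = [], 0
    for (name, rel), pairs in anch.items():
        if name != ref_name:
            continue
        ch = chain_anchors(pairs)
        if len(ch) > len(best_chain):
            best_chain, best_rel = ch, rel
    if len(best_chain) < min_anchors:
        return None
    strand = "-" if best_rel else "+"
    oriented = revcomp(query) if best_rel else query
    qlen, rlen = len(query), len(reference)
    offs = sorted(t - q for q, t in best_chain)
    d = offs[len(offs) // 2]
    # part of the query that can sit on the reference, with slack for indels
    margin = max(60, int(0.25 * qlen))
    q_lo = max(0, -d - margin)
    q_hi = min(qlen, rlen - d + margin)
    if q_hi - q_lo < index.k:
        return None
    r_lo = max(0, q_lo + d - margin)
    r_hi = min(rlen, q_hi + d + margin)
    sub = oriented[q_lo:q_hi]
    res = edlib.align(sub, reference[r_lo:r_hi], mode="HW", task="path")
    if res["editDistance"] < 0:
        return None
    loc = res["locations"][0]
    aln = Alignment(
        q_start=q_lo,
        q_end=q_hi,
        r_start=r_lo + loc[0],
        r_end=r_lo + loc[1] + 1,
        strand=strand,
        cigar=res["cigar"],
        edit_distance=res["editDistance"],
    )
    if aln.edit_distance > max_divergence * aln.block_len:
        return None
    return aln


def bases_at(
    aln: Alignment, oriented_query: str, positions: list[int]
) -> dict[int, tuple[str, int]]:
    """Query base (and its oriented-query offset) at each reference position.

    One CIGAR walk. Positions falling in a deletion or outside the aligned
    span are absent from the result.
    """
    want = sorted(p for p in positions if aln.r_start <= p < aln.r_end)
    if not want:
        return {}
    out: dict[int, tuple[str, int]] = {}
    qi = aln.q_start
    ri = aln.r_start
    wi = 0
    for n, op in parse_cigar(aln.cigar):
        if op in "=X":
            while wi < len(want) and want[wi] < ri + n:
                qp = qi + (want[wi] - ri)
                out[want[wi]] = (oriented_query[qp], qp)
                wi += 1
            qi += n
            ri += n
        elif op == "I":
            qi += n
        else:  # D
            while wi < len(want) and want[wi] < ri + n:
                wi += 1  # deleted in the query
            ri += n
        if wi >= len(want):
            break
    return out
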