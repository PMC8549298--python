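"""Pileup consensus: mapping reads onto a backbone and majority-voting columns.

One window-free pileup over the whole backbone replaces windowed consensus
polishers: every read is placed by the minimizer chain aligner, its CIGAR is
expanded into (query base, backbone column) pairs, and each column is replaced
by its majority symbol (a base, or a deletion); inserted strings supported by
a majority of the covering reads are spliced in between columns.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .align import Alignment, MinimizerIndex, map_to_reference, revcomp, _encode
from .io import Read

__all__ = ["MappedRead", "map_reads", "Pileup", "build_pileup", "consensus", "polish"]

_CIG_RE = re.compile(r"(\d+)([=XID])")


@dataclass
class MappedRead:
    read: Read
    aln: Alignment

    @property
    def oriented_seq(self) -> str:
        s = self.read.sequence
        return revcomp(s) if self.aln.strand == "-" else s


def _mapping_knobs(platform: str) -> tuple[int, int, float]:
    """(k, w, max divergence) for read-to-backbone placement."""
    if platform == "hifi":
        return 15, 10, 0.20
    return 15, 5, 0.40


def map_reads(
    reads: Sequence[Read],
    reference: str,
    platform: str = "hifi",
    index: Optional[MinimizerIndex] = None,
) -> list[MappedRead]:
    """Place each read on the backbone; reads with no adequate placement are skipped."""
    k, w, maxdiv = _mapping_knobs(platform)
    if index is None:
        index = MinimizerIndex({"ref": reference}, k=k, w=w)
    out = []
    for read in reads:
        aln = map_to_reference(read.sequence, reference, index=index, max_divergence=maxdiv)
        if aln is not None:
            out.append(MappedRead(read, aln))
    return out


@dataclass
class Pileup:
    counts: np.ndarray  # 5 x L; rows A,C,G,T,deletion
    insertions: dict[int, Counter]  # column -> Counter of strings inserted before it

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def _cigar_arrays(cigar: str) -> tuple[np.ndarray, np.ndarray]:
    nums, ops = [], []
    for m in _CIG_RE.finditer(cigar):
        nums.append(int(m.group(1)))
        ops.append(m.group(2))
    return np.asarray(nums, dtype=np.int64), np.asarray(ops)


def build_pileup(ref_len: int, mapped: Sequence[MappedRead]) -> Pileup:
    counts = np.zeros((5, ref_len), dtype=np.int32)
    insertions: dict[int, Counter] = {}
    for mr in mapped:
        seq = mr.oriented_seq
        enc = _encode(seq)
        nums, ops = _cigar_arrays(mr.aln.cigar)
        qadv = np.where((ops == "=") | (ops == "X") | (ops == "I"), nums, 0)
        radv = np.where((ops == "=") | (ops == "X") | (ops == "D"), nums, 0)
        qpos = mr.aln.q_start + np.concatenate(([0], np.cumsum(qadv)[:-1]))
        rpos = mr.aln.r_start + np.concatenate(([0], np.cumsum(radv)[:-1]))
        is_m = (ops == "=") | (ops == "X")
        if is_m.any():
            n = nums[is_m]
            qs = qpos[is_m]
            rs = rpos[is_m]
            total = int(n.sum())
            within = np.arange(total) - np.repeat(np.cumsum(n) - n, n)
            qcols = np.repeat(qs, n) + within
            rcols = np.repeat(rs, n) + within
            codes = enc[qcols]
            good = codes != 255
            np.add.at(counts, (codes[good], rcols[good]), 1)
        is_d = ops == "D"
        if is_d.any():
            n = nums[is_d]
            rs = rpos[is_d]
            total = int(n.sum())
            within = np.arange(total) - np.repeat(np.cumsum(n) - n, n)
            rcols = np.repeat(rs, n) + within
            np.add.at(counts[4], rcols, 1)
        for i in np.nonzero(ops == "I")[0]:
            col = int(rpos[i])
            if col >= ref_len:
                continue
            ins = seq[int(qpos[i]) : int(qpos[i]) + int(nums[i])]
            insertions.setdefault(col, Counter())[ins] += 1
    return Pileup(counts, insertions)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def consensus(reference: str, pileup: Pileup) -> tuple[str, np.ndarray]:
    """Majority-vote sequence and its per-position read coverage.

    Columns nobody covers keep the backbone base (coverage 0). A deletion
    symbol must strictly outvote every base to remove a column. An insertion
    is spliced in iff one inserted string is supported by more than half of
    the reads covering the column.
    """
    counts = pileup.counts
    cov = pileup.coverage
    L = counts.shape[1]
    if L == 0:
        return reference, np.zeros(0, dtype=np.int64)
    best = counts[:4].argmax(axis=0)
    best_n = counts[:4].max(axis=0)
    del_wins = counts[4] > best_n
    ref_arr = np.frombuffer(reference.encode("ascii"), dtype=np.uint8)
    out_chars = np.where(cov > 0, _BASES[best], ref_arr)
    keep = (cov == 0) | ~del_wins
    # splice majority insertions between kept columns
    splice: list[tuple[int, str, int]] = []
    for col, ctr in pileup.insertions.items():
        ins, n = min(ctr.items(), key=lambda kv: (-kv[1], kv[0]))
        c = cov[col] if col < L else 0
        if c > 0 and 2 * n > c:
            splice.append((col, ins, int(c)))
    splice.sort()
    pieces: list[str] = []
    covs: list[np.ndarray] = []
    prev = 0
    kept_chars = out_chars  # indexed by original column
    for col, ins, c in splice:
        kmask = keep[prev:col]
        pieces.append(kept_chars[prev:col][kmask].tobytes().decode("ascii"))
        covs.append(cov[prev:col][kmask])
        pieces.append(ins)
        covs.append(np.full(len(ins), c, dtype=np.int64))
        prev = col
    kmask = keep[prev:]
    pieces.append(kept_chars[prev:][kmask].tobytes().decode("ascii"))
    covs.append(cov[prev:][kmask])
    seq = "".join(pieces)
    coverage = np.concatenate(covs).astype(np.int64) if covs else np.zeros(0, np.int64)
    return seq, coverage


def polish(
    reference: str,
    reads: Sequence[Read],
    platform: str = "hifi",
    rounds: int = 2,
) -> tuple[str, np.ndarray, list[MappedRead]]:
    """Iterated map-and-vote polishing.

    Returns the polished sequence, its coverage profile, and the final-round
    read placements (on the pre-final-vote backbone). If no read maps, the
    input is returned unchanged with zero coverage.
    """
    seq = reference
    coverage = np.zeros(len(reference), dtype=np.int64)
    mapped: list[MappedRead] = []
    for _ in range(max(1, rounds)):
        mapped = map_reads(reads, seq, platform=platform)
        if not mapped:
            return seq, coverage, []
        pl = build_pileup(len(seq), mapped)
        seq, coverage = consensus(seq, pl)
    return seq, coverage, mapped
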