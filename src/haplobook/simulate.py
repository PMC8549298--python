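"""Synthetic diploid genomes and platform-like long reads with ground truth.

The generator emulates the pseudo-diploid setting used to benchmark
haplotype-aware assemblers: one random haplotype, a second derived from it by
Bernoulli-per-base SNPs and sparse short indels, and reads sampled from both
haplotypes with lognormal lengths and i.i.d. per-base substitution /
insertion / deletion errors. Every read records its haplotype of origin and
true coordinates, so every pipeline stage can be scored against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .align import revcomp
from .io import Read

__all__ = ["DiploidTruth", "ReadTruth", "simulate_diploid", "simulate_reads"]

_ALPHA = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class ReadTruth:
    haplotype: int  # 1 or 2
    start: int  # on the haplotype of origin, 0-based half-open
    end: int
    strand: str


@dataclass
class DiploidTruth:
    hap1: str
    hap2: str
    # (position on hap1, position on hap2, hap1 allele, hap2 allele)
    het_sites: list[tuple[int, int, str, str]] = field(default_factory=list)
    # (position on hap1, 'ins'|'del', sequence inserted into / deleted from hap2)
    indels: list[tuple[int, str, str]] = field(default_factory=list)
    read_truth: dict[str, ReadTruth] = field(default_factory=dict)


def _random_dna(rng: np.random.Generator, n: int) -> np.ndarray:
    return _ALPHA[rng.integers(0, 4, size=n)]


def simulate_diploid(
    hap_len: int,
    snp_rate: float = 0.01,
    indel_rate: float = 0.0005,
    seed: int = 0,
) -> DiploidTruth:
    """Two haplotypes differing by SNPs and 1-10 bp indels.

    SNP positions are Bernoulli(snp_rate) per base, alleles uniform over the
    three alternatives; indel positions Bernoulli(indel_rate), half insertions
    half deletions, lengths uniform on 1..10. Fully deterministic given seed.
    """
    if not (0 <= snp_rate <= 0.1 and 0 <= indel_rate <= 0.1):
        raise ValueError("variant rates must lie in [0, 0.1]")
    rng = np.random.default_rng(seed)
    h1 = _random_dna(rng, hap_len)
    sub_mask = rng.random(hap_len) < snp_rate
    sub_pos = np.nonzero(sub_mask)[0]
    # alternative allele: shift by 1..3 in base space, never identical
    shifts = rng.integers(1, 4, size=len(sub_pos))
    code = np.searchsorted(_ALPHA, h1[sub_pos])  # ACGT are sorted bytes
    alt = _ALPHA[(code + shifts) % 4]
    ind_mask = (rng.random(hap_len) < indel_rate) & ~sub_mask
    ind_pos = np.nonzero(ind_mask)[0]
    is_ins = rng.random(len(ind_pos)) < 0.5
    ind_len = rng.integers(1, 11, size=len(ind_pos))
    ins_seqs = [
        _random_dna(rng, int(n)).tobytes().decode() if i else ""
        for i, n in zip(is_ins, ind_len)
    ]

    hap1 = h1.tobytes().decode()
    h2 = h1.copy()
    h2[sub_pos] = alt

    indels: list[tuple[int, str, str]] = []
    deleted = np.zeros(hap_len, dtype=bool)
    pieces: list[str] = []
    cursor = 0
    shift_at: dict[int, int] = {}
    shift = 0
    for p, ins_flag, ln, ins_seq in zip(ind_pos.tolist(), is_ins.tolist(),
                                        ind_len.tolist(), ins_seqs):
        if p < cursor:
            continue  # swallowed by a previous deletion
        pieces.append(h2[cursor:p].tobytes().decode())
        if ins_flag:
            pieces.append(h2[p : p + 1].tobytes().decode())
            pieces.append(ins_seq)
            indels.append((p, "ins", ins_seq))
            shift += len(ins_seq)
            cursor = p + 1
        else:
            ln = int(min(ln, hap_len - p))
            deleted[p : p + ln] = True
            indels.append((p, "del", hap1[p : p + ln]))
            shift -= ln
            cursor = p + ln
        shift_at[cursor] = shift
    pieces.append(h2[cursor:].tobytes().decode())
    hap2 = "".join(pieces)

    # map surviving SNP positions onto hap2 coordinates
    het_sites: list[tuple[int, int, str, str]] = []
    bounds = sorted(shift_at)
    import bisect

    for p, a in zip(sub_pos.tolist(), alt.tobytes().decode()):
        if deleted[p]:
            continue
        i = bisect.bisect_right(bounds, p) - 1
        s = shift_at[bounds[i]] if i >= 0 else 0
        het_sites.append((p, p + s, hap1[p], a))
    return DiploidTruth(hap1, hap2, het_sites, indels)


def _lognormal_lengths(rng, n, mean, sd, lo, hi):
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    ln = rng.lognormal(mu, np.sqrt(sigma2), size=n)
    return np.clip(ln, lo, hi).astype(np.int64)


def _apply_errors(rng, seq: str, err_sub: float, err_ins: float, err_del: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = len(arr)
    u = rng.random((3, n))
    sub = u[0] < err_sub
    if sub.any():
        idx = np.nonzero(sub)[0]
        code = np.searchsorted(_ALPHA, arr[idx])
        arr[idx] = _ALPHA[(code + rng.integers(1, 4, size=len(idx))) % 4]
    dele = u[1] < err_del
    ins = u[2] < err_ins  # one random base inserted after the position
    reps = (~dele).astype(np.int64) + ins.astype(np.int64)
    src = np.repeat(np.arange(n), reps)
    if len(src) == 0:
        return ""
    is_first = np.concatenate(([True], src[1:] != src[:-1]))
    take_orig = is_first & ~dele[src]
    out = np.where(take_orig, arr[src], _random_dna(rng, len(src)))
    return out.astype(np.uint8).tobytes().decode()


def simulate_reads(
    truth: DiploidTruth,
    coverage_per_hap: float = 20.0,
    mean_len: int = 10000,
    len_sd: int = 2000,
    err_sub: float = 0.0,
    err_ins: float = 0.0,
    err_del: float = 0.0,
    seed: int = 0,
    min_len: int = 500,
) -> list[Read]:
    """Sample reads from both haplotypes until each reaches the target coverage.

    Lengths are lognormal(mean, sd) clamped to [min_len, haplotype length];
    starts uniform; strands random; errors i.i.d. per base at the given rates.
    Ground-truth origins are recorded in ``truth.read_truth``. Deterministic
    given seed.
    """
    rng = np.random.default_rng(seed)
    reads: list[Read] = []
    for hap_no, hap in ((1, truth.hap1), (2, truth.hap2)):
        hlen = len(hap)
        target = coverage_per_hap * hlen
        total = 0
        i = 0
        while total < target:
            L = int(_lognormal_lengths(rng, 1, mean_len, len_sd, min_len, hlen)[0])
            start = int(rng.integers(0, hlen - L + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            frag = hap[start : start + L]
            if strand == "-":
                frag = revcomp(frag)
            if err_sub or err_ins or err_del:
                frag = _apply_errors(rng, frag, err_sub, err_ins, err_del)
            rid = f"r{hap_no}_{i:05d}"
            reads.append(Read(rid, frag))
            truth.read_truth[rid] = ReadTruth(hap_no, start, start + L, strand)
            total += L
            i += 1
    return reads
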