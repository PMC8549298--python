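"""Heterozygous-SNP discovery and read phasing by weighted minimum error correction.

A cluster's reads are mapped onto its polished ad hoc reference; columns with
a balanced second allele become candidate heterozygous SNPs; each read's
alleles at those sites form a row of the allele matrix; and an exact
column-sweep dynamic program partitions the rows into the two local
haplotypes, minimizing the summed weight of entries that must be flipped for
each side to be consistent with a single allele per column (the wMEC
objective). Runtime is linear in the number of sites and exponential only in
the per-column read coverage, which is capped by read selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .align import bases_at
from .consensus import MappedRead, build_pileup
from .io import AssemblyParams

__all__ = [
    "SNPSite",
    "AlleleMatrix",
    "Phasing",
    "call_snps",
    "build_allele_matrix",
    "solve_wmec",
    "assign_unphased",
]

MISSING = -1
_BASE_ORDER = "ACGT"


@dataclass
class SNPSite:
    position: int  # on the ad hoc reference, 0-based
    ref_allele: str
    alt_allele: str
    depth: int
    ref_count: int
    alt_count: int

    @property
    def af(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0


@dataclass
class AlleleMatrix:
    """Reads x het-site matrix over {0 (ref), 1 (alt), missing} with weights."""

    sites: list[SNPSite]
    read_ids: list[str]
    entries: np.ndarray  # (n_reads, n_sites) int8; MISSING where uncovered
    weights: np.ndarray  # (n_reads, n_sites) float; 0 where missing

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass
class Phasing:
    assignment: dict[str, str]  # read id -> 'H1' | 'H2' | 'both' | 'unassigned'
    mec_cost: float = 0.0

    def group(self, label: str) -> list[str]:
        return sorted(r for r, l in self.assignment.items() if l == label)


def call_snps(
    mapped: Sequence[MappedRead],
    reference: str,
    params: AssemblyParams,
) -> list[SNPSite]:
    """Candidate heterozygous substitution sites from the read pileup.

    A column is a site iff depth >= snp_min_depth, the reference-agreeing and
    the top alternative base each have count >= snp_min_allele_count, and the
    alternative fraction lies in [snp_af_low, snp_af_high]. Indels are never
    markers.
    """
    if not mapped:
        return []
    pl = build_pileup(len(reference), mapped)
    counts = pl.counts[:4]
    depth = pl.coverage  # includes deletion calls
    ref_codes = np.frombuffer(reference.encode("ascii"), dtype=np.uint8)
    code_of = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(_BASE_ORDER):
        code_of[ord(b)] = i
    rc = code_of[ref_codes]
    L = len(reference)
    cols = np.arange(L)
    valid = rc != 255
    ref_count = np.zeros(L, dtype=np.int64)
    ref_count[valid] = counts[rc[valid], cols[valid]]
    masked = counts.copy()
    masked[rc[valid], cols[valid]] = -1
    alt_code = masked.argmax(axis=0)
    alt_count = masked.max(axis=0)
    af = np.divide(alt_count, depth, out=np.zeros(L), where=depth > 0)
    is_site = (
        valid
        & (depth >= params.snp_min_depth)
        & (ref_count >= params.snp_min_allele_count)
        & (alt_count >= params.snp_min_allele_count)
        & (af >= params.snp_af_low)
        & (af <= params.snp_af_high)
    )
    sites = [
        SNPSite(
            position=int(p),
            ref_allele=reference[p],
            alt_allele=_BASE_ORDER[alt_code[p]],
            depth=int(depth[p]),
            ref_count=int(ref_count[p]),
            alt_count=int(alt_count[p]),
        )
        for p in np.nonzero(is_site)[0]
    ]
    return sites


def build_allele_matrix(
    mapped: Sequence[MappedRead],
    sites: Sequence[SNPSite],
) -> AlleleMatrix:
    """One row per mapped read; 0/1 where the read shows ref/alt, else missing.

    A third allele or a deletion at a site leaves the entry missing. Weights
    are the read's base quality at the site when present, else a constant 10.
    """
    sites = list(sites)
    positions = [s.position for s in sites]
    read_ids = [mr.read.id for mr in mapped]
    n, m = len(read_ids), len(sites)
    entries = np.full((n, m), MISSING, dtype=np.int8)
    weights = np.zeros((n, m), dtype=np.float64)
    site_idx = {p: j for j, p in enumerate(positions)}
    for i, mr in enumerate(mapped):
        got = bases_at(mr.aln, mr.oriented_seq, positions)
        if not got:
            continue
        qual = mr.read.quality
        if qual is not None and mr.aln.strand == "-":
            qual = qual[::-1]
        for pos, (base, qp) in got.items():
            j = site_idx[pos]
            s = sites[j]
            if base == s.ref_allele:
                entries[i, j] = 0
            elif base == s.alt_allele:
                entries[i, j] = 1
            else:
                continue
            weights[i, j] = float(qual[qp]) if qual is not None else 10.0
    return AlleleMatrix(sites, read_ids, entries, weights)


def _read_spans(entries: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First and last non-missing column per row (-1,-1 for empty rows)."""
    n, m = entries.shape
    has = entries != MISSING
    first = np.full(n, -1, dtype=np.int64)
    last = np.full(n, -1, dtype=np.int64)
    any_rows = has.any(axis=1)
    first[any_rows] = has[any_rows].argmax(axis=1)
    last[any_rows] = m - 1 - has[any_rows, ::-1].argmax(axis=1)
    return first, last


def _select_reads(first, last, order_key, cap: int) -> np.ndarray:
    """Greedy read selection keeping per-column coverage <= cap.

    Reads are offered longest interval first (ties by id); a read is accepted
    iff no column of its interval is already at the cap.
    """
    m = int(last.max()) + 1 if len(last) and last.max() >= 0 else 0
    load = np.zeros(m, dtype=np.int64)
    chosen = np.zeros(len(first), dtype=bool)
    for i in order_key:
        f, l = first[i], last[i]
        if f < 0:
            continue
        if (load[f : l + 1] < cap).all():
            load[f : l + 1] += 1
            chosen[i] = True
    return chosen


class _ColumnSweep:
    """The wMEC forward/backward dynamic program over column bipartition masks.

    Per-column cost arrays over all 2^coverage bipartitions are built by
    subset-sum doubling; transitions between columns with different active
    sets marginalize departing reads by pairwise min-folds and replicate in
    entering reads, all as contiguous numpy reshapes. Memory is kept flat by
    checkpointing the cumulative cost array every few columns and re-deriving
    per-column argmins segment by segment during the backtrace.
    """

    CHECKPOINT_EVERY = 8

    def __init__(self, entries, weights, active_cols):
        self.entries = entries
        self.weights = weights
        self.active = active_cols
        self.m = len(active_cols)

    def _col_cost(self, j: int) -> np.ndarray:
        act = self.active[j]
        nb = len(act)
        e = self.entries[act, j]
        w = self.weights[act, j].astype(np.float32)
        w1 = np.where(e == 1, w, 0.0).astype(np.float32)
        w0 = np.where(e == 0, w, 0.0).astype(np.float32)
        in1 = np.zeros(1 << nb, dtype=np.float32)
        in0 = np.zeros(1 << nb, dtype=np.float32)
        for i in range(nb):
            half = 1 << i
            in1[half : 2 * half] = in1[:half] + w1[i]
            in0[half : 2 * half] = in0[:half] + w0[i]
        cost_in = np.minimum(in1, in0)  # side of the set bits
        cost_out = np.minimum(w1.sum() - in1, w0.sum() - in0)
        return cost_in + cost_out

    @staticmethod
    def _fold_min(vals, drop_bits_desc, idx=None):
        """Marginalize bits out of a 2^n array by pairwise min (ties keep bit 0)."""
        for b in drop_bits_desc:
            block = 1 << b
            v = vals.reshape(-1, 2, block)
            take_r = v[:, 1, :] < v[:, 0, :]
            vals = np.where(take_r, v[:, 1, :], v[:, 0, :]).reshape(-1)
            if idx is not None:
                i = idx.reshape(-1, 2, block)
                idx = np.where(take_r, i[:, 1, :], i[:, 0, :]).reshape(-1)
        return vals, idx

    @staticmethod
    def _expand(vals, insert_bits_asc):
        """Replicate a 2^n array in new bit positions (entering reads are free)."""
        for b in insert_bits_asc:
            block = 1 << b
            v = vals.reshape(-1, block)
            vals = np.repeat(v, 2, axis=0).reshape(-1)
        return vals

    def _transition_bits(self, j: int) -> tuple[list[int], list[int]]:
        """(bits of column j-1 to fold out, bits of column j to insert)."""
        prev, cur = self.active[j - 1], self.active[j]
        cur_set = set(cur.tolist())
        prev_set = set(prev.tolist())
        drop = [k for k, r in enumerate(prev.tolist()) if r not in cur_set]
        ins = [k for k, r in enumerate(cur.tolist()) if r not in prev_set]
        return sorted(drop, reverse=True), sorted(ins)

    def _advance(self, cum: np.ndarray, j: int, with_arg: bool):
        """cum at column j-1 -> (cum at j, per-shared-mask argmin or None)."""
        drop, ins = self._transition_bits(j)
        arg = None
        if not drop and not ins:
            best = cum
        else:
            idx = np.arange(len(cum), dtype=np.int32) if with_arg else None
            best, arg = self._fold_min(cum, drop, idx)
            if with_arg and not drop:
                arg = idx
            best = self._expand(best, ins)
        return self._col_cost(j) + best, arg

    def run(self) -> tuple[np.ndarray, float]:
        """Forward sweep + checkpointed backtrace; returns (side per read, cost)."""
        m = self.m
        K = self.CHECKPOINT_EVERY
        checkpoints: dict[int, np.ndarray] = {}
        cum = self._col_cost(0)
        checkpoints[0] = cum
        for j in range(1, m):
            cum, _ = self._advance(cum, j, with_arg=False)
            if j % K == 0:
                checkpoints[j] = cum
        mask = int(np.argmin(cum))
        cost = float(cum[mask])

        n = self.entries.shape[0]
        side = np.full(n, -1, dtype=np.int64)

        def note(j: int, mask: int) -> None:
            for k, r in enumerate(self.active[j].tolist()):
                if side[r] == -1:
                    side[r] = (mask >> k) & 1

        j = m - 1
        note(j, mask)
        while j > 0:
            start = (j - 1) // K * K  # checkpointed column <= j-1
            for key in [k for k in checkpoints if k > start]:
                del checkpoints[key]
            args: dict[int, Optional[np.ndarray]] = {}
            cum_s = checkpoints[start]
            for jj in range(start + 1, j + 1):
                cum_s, arg = self._advance(cum_s, jj, with_arg=True)
                args[jj] = arg
            for jj in range(j, start, -1):
                drop, ins = self._transition_bits(jj)
                arg = args[jj]
                if arg is None:
                    prev_mask = mask  # identical active sets
                else:
                    # remove inserted bits to index the shared-mask arg table
                    shared_mask = mask
                    for b in sorted(ins, reverse=True):
                        shared_mask = ((shared_mask >> (b + 1)) << b) | (
                            shared_mask & ((1 << b) - 1)
                        )
                    prev_mask = int(arg[shared_mask])
                mask = prev_mask
                note(jj - 1, mask)
            j = start
        return side, cost


def solve_wmec(matrix: AlleleMatrix, params: AssemblyParams) -> Phasing:
    """Exact wMEC bipartition by a column-sweep dynamic program.

    Each read is active over the column interval between its first and last
    covered site. Per column, all bipartitions of the active reads are scored:
    the cost of a side is the cheaper of assigning it allele 0 or allele 1
    (summed weights of disagreeing entries). Transitions require consecutive
    columns to agree on shared reads. Costs and transitions are evaluated for
    all 2^coverage masks at once with numpy, and a backtrace recovers a
    minimum-cost assignment. Coverage above ``max_phasing_coverage`` is capped
    by interval-greedy read selection; excluded reads are assigned afterwards
    to their best-fitting side (their flips are not part of the MEC cost).

    Labels are canonical: H1 is the group containing the lexicographically
    smallest assigned read id.
    """
    n, m = matrix.entries.shape
    if m == 0 or n == 0:
        return Phasing({rid: "unassigned" for rid in matrix.read_ids}, 0.0)
    first, last = _read_spans(matrix.entries)
    span = last - first
    order = sorted(range(n), key=lambda i: (-span[i], matrix.read_ids[i]))
    chosen = _select_reads(first, last, order, params.max_phasing_coverage)
    active_cols: list[np.ndarray] = []
    for j in range(m):
        act = np.nonzero(chosen & (first <= j) & (last >= j))[0]
        active_cols.append(act)

    entries, weights = matrix.entries, matrix.weights
    dp = _ColumnSweep(entries, weights, active_cols)
    side, cost = dp.run()

    # consensus alleles per side, to place reads excluded by the coverage cap
    assignment: dict[str, str] = {}
    def side_consensus(bit: int) -> np.ndarray:
        rows = np.nonzero((side == bit) & chosen)[0]
        cons = np.full(m, MISSING, dtype=np.int8)
        for j in range(m):
            e = matrix.entries[rows, j]
            w = matrix.weights[rows, j]
            w1 = w[e == 1].sum()
            w0 = w[e == 0].sum()
            if w1 + w0 > 0:
                cons[j] = 1 if w1 > w0 else 0
        return cons

    cons = [side_consensus(0), side_consensus(1)]
    for i, rid in enumerate(matrix.read_ids):
        if first[i] < 0:
            assignment[rid] = "unassigned"
            continue
        if chosen[i] and side[i] >= 0:
            assignment[rid] = "H1" if side[i] == 0 else "H2"
            continue
        # read dropped by coverage cap: weighted best fit against side consensus
        e = matrix.entries[i]
        w = matrix.weights[i]
        scores = []
        for b in (0, 1):
            mismatch = (e != MISSING) & (cons[b] != MISSING) & (e != cons[b])
            scores.append(w[mismatch].sum())
        assignment[rid] = "H1" if scores[0] <= scores[1] else "H2"

    phasing = Phasing(assignment, cost)
    _canonicalize(phasing)
    return phasing


def _canonicalize(phasing: Phasing) -> None:
    assigned = sorted(r for r, l in phasing.assignment.items() if l in ("H1", "H2"))
    if not assigned:
        return
    if phasing.assignment[assigned[0]] == "H2":
        for r, l in phasing.assignment.items():
            if l == "H1":
                phasing.assignment[r] = "H2"
            elif l == "H2":
                phasing.assignment[r] = "H1"


def assign_unphased(cluster_read_ids: Sequence[str], phasing: Phasing) -> Phasing:
    """Give reads that carry no phasing signal the label 'both'.

    Reads absent from the matrix or with all-missing rows join both haplotype
    groups; if nothing at all was phased (no sites), every read is 'both' and
    a single unphased super read will result.
    """
    out = dict(phasing.assignment)
    any_phased = any(l in ("H1", "H2") for l in out.values())
    for rid in cluster_read_ids:
        label = out.get(rid, "unassigned")
        if label == "unassigned" or not any_phased:
            out[rid] = "both"
    return Phasing(out, phasing.mec_cost)
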