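"""Reference-based assembly scoring: completeness, phasing fidelity, contiguity.

Contigs are aligned to both truth haplotypes with the package's own chain
aligner; each contig is assigned the haplotype it matches best. Reported:

* haplotype coverage — % of truth bases (both haplotypes pooled) covered by
  aligned contigs on their assigned haplotype;
* switch error rate — over adjacent pairs of heterozygous sites covered by a
  contig, the fraction where the contig's alleles jump from one haplotype to
  the other;
* N50 (contig lengths vs assembly size), NG50 (vs diploid genome size) and
  NGA50 (alignment blocks split at misassembly breakpoints, vs diploid size);
* duplication ratio — aligned contig bases / distinct truth bases covered;
* QV — phred-scaled per-base error rate of the aligned blocks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import edlib
import numpy as np

from .align import Alignment, MinimizerIndex, bases_at, chain_anchors, revcomp
from .assembly import Contig
from .simulate import DiploidTruth

__all__ = ["EvalReport", "evaluate_assembly", "n50", "ng_metric", "align_contig_blocks"]


def n50(lengths: Sequence[int]) -> int:
    """Smallest length L such that pieces of length >= L cover half the total."""
    total = sum(lengths)
    return ng_metric(lengths, total) or 0


def ng_metric(lengths: Sequence[int], genome_size: int) -> Optional[int]:
    """N50-style statistic against an external size; None if half is never reached."""
    if genome_size <= 0:
        return None
    acc = 0
    for L in sorted(lengths, reverse=True):
        acc += L
        if 2 * acc >= genome_size:
            return L
    return None


@dataclass
class EvalReport:
    haplotype_coverage: Optional[float]  # percent
    switch_error_rate: Optional[float]  # percent
    n50: int
    ng50: Optional[int]
    nga50: Optional[int]
    duplication_ratio: Optional[float]
    qv_identity: Optional[float]
    n_contigs: int = 0
    total_bases: int = 0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def to_json(self, path) -> None:
        with open(path, "wt") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    def to_tsv(self, path) -> None:
        d = self.to_dict()
        with open(path, "wt") as fh:
            fh.write("\t".join(d.keys()) + "\n")
            fh.write("\t".join("NA" if v is None else str(v) for v in d.values()) + "\n")


def align_contig_blocks(
    sequence: str,
    reference: str,
    index: MinimizerIndex,
    breakpoint_jump: int = 1000,
) -> list[Alignment]:
    """Chain the contig onto the reference and split at discontinuities.

    Anchor chains whose diagonal jumps by more than ``breakpoint_jump`` are
    split into separate alignment blocks (misassembly breakpoints); each block
    is aligned at base level. Alignments are on the contig's forward or
    reverse-complement strand as chained.
    """
    anch = index.anchors(sequence)
    ref_name = next(iter(index.lengths))
    best_chain, best_rel = [], 0
    for (name, rel), pairs in sorted(anch.items()):
        if name != ref_name:
            continue
        ch = chain_anchors(pairs)
        if len(ch) > len(best_chain):
            best_chain, best_rel = ch, rel
    if len(best_chain) < 3:
        return []
    oriented = revcomp(sequence) if best_rel else sequence
    strand = "-" if best_rel else "+"
    # split the chain where the diagonal jumps
    blocks: list[list[tuple[int, int]]] = [[best_chain[0]]]
    for (q0, t0), (q1, t1) in zip(best_chain, best_chain[1:]):
        if abs((t1 - q1) - (t0 - q0)) > breakpoint_jump:
            blocks.append([])
        blocks[-1].append((q1, t1))
    out: list[Alignment] = []
    rlen = len(reference)
    for blk in blocks:
        if len(blk) < 3:
            continue
        qs = blk[0][0]
        qe = blk[-1][0] + index.k
        d = sorted(t - q for q, t in blk)[len(blk) // 2]
        margin = max(100, int(0.1 * (qe - qs)))
        # extend the block to the contig portion lying on the reference
        q_lo = max(0, -d - margin, qs - 5 * margin)
        q_hi = min(len(sequence), rlen - d + margin, qe + 5 * margin)
        r_lo = max(0, q_lo + d - margin)
        r_hi = min(rlen, q_hi + d + margin)
        if q_hi - q_lo < index.k:
            continue
        res = edlib.align(oriented[q_lo:q_hi], reference[r_lo:r_hi], mode="HW", task="path")
        if res["editDistance"] < 0:
            continue
        loc = res["locations"][0]
        out.append(
            Alignment(
                q_start=q_lo, q_end=q_hi,
                r_start=r_lo + loc[0], r_end=r_lo + loc[1] + 1,
                strand=strand, cigar=res["cigar"],
                edit_distance=res["editDistance"],
            )
        )
    return out


def evaluate_assembly(contigs: Sequence[Contig], truth: DiploidTruth) -> EvalReport:
    haps = {1: truth.hap1, 2: truth.hap2}
    genome_size = len(truth.hap1) + len(truth.hap2)
    lengths = [c.length for c in contigs]
    if not contigs:
        return EvalReport(0.0, None, 0, None, None, None, None, 0, 0)
    indexes = {h: MinimizerIndex({f"hap{h}": s}, k=15, w=10) for h, s in haps.items()}
    covered = {h: np.zeros(len(s), dtype=bool) for h, s in haps.items()}
    het_by_hap = {
        1: [(p1, a1, a2) for p1, _, a1, a2 in truth.het_sites],
        2: [(p2, a2, a1) for _, p2, a1, a2 in truth.het_sites],
    }
    aligned_contig_bases = 0
    total_edits = 0
    block_lengths: list[int] = []
    switches = 0
    pairs = 0
    for contig in contigs:
        per_hap = {}
        for h in (1, 2):
            blocks = align_contig_blocks(contig.sequence, haps[h], indexes[h])
            matched = sum(b.block_len - b.edit_distance for b in blocks)
            per_hap[h] = (matched, blocks)
        best_h = max((1, 2), key=lambda h: per_hap[h][0])
        matched, blocks = per_hap[best_h]
        if not blocks:
            continue
        oriented = (
            revcomp(contig.sequence) if blocks[0].strand == "-" else contig.sequence
        )
        site_calls: list[tuple[int, int]] = []  # (ref position, haplotype of allele)
        own_alleles = het_by_hap[best_h]
        positions = [p for p, _, _ in own_alleles]
        allele_of = {p: (a_own, a_other) for p, a_own, a_other in own_alleles}
        for b in blocks:
            covered[best_h][b.r_start : b.r_end] = True
            aligned_contig_bases += b.q_end - b.q_start
            total_edits += b.edit_distance
            block_lengths.append(b.q_end - b.q_start)
            got = bases_at(b, oriented, positions)
            for p, (base, _) in got.items():
                a_own, a_other = allele_of[p]
                if base == a_own:
                    site_calls.append((p, best_h))
                elif base == a_other:
                    site_calls.append((p, 3 - best_h))
        site_calls.sort()
        for (_, h0), (_, h1) in zip(site_calls, site_calls[1:]):
            pairs += 1
            if h0 != h1:
                switches += 1
    covered_bases = int(sum(c.sum() for c in covered.values()))
    hc = 100.0 * covered_bases / genome_size
    switch_rate = 100.0 * switches / pairs if pairs else None
    dup = aligned_contig_bases / covered_bases if covered_bases else None
    if aligned_contig_bases and total_edits:
        qv = -10.0 * np.log10(total_edits / aligned_contig_bases)
    elif aligned_contig_bases:
        qv = float("inf")
    else:
        qv = None
    return EvalReport(
        haplotype_coverage=hc,
        switch_error_rate=switch_rate,
        n50=n50(lengths),
        ng50=ng_metric(lengths, genome_size),
        nga50=ng_metric(block_lengths, genome_size) if block_lengths else None,
        duplication_ratio=dup,
        qv_identity=float(qv) if qv is not None else None,
        n_contigs=len(contigs),
        total_bases=sum(lengths),
    )
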