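"""Readers and writers for the formats the pipeline touches, plus run parameters.

All coordinates throughout the package are 0-based, half-open, on the forward
strand of the sequence they index (PAF convention). Reverse-strand overlaps
store target coordinates on the target's forward strand with strand flag '-'.
"""

from __future__ import annotations

import gzip
import io as _io
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

__all__ = [
    "Read",
    "AssemblyParams",
    "read_sequences",
    "write_fasta",
    "read_paf",
    "write_paf",
    "write_gfa",
    "load_params",
]


@dataclass
class Read:
    """A long read: unique id, uppercase DNA sequence, optional phred qualities."""

    id: str
    sequence: str
    quality: Optional[list[int]] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


# per-platform minimum overlap identity: HiFi reads are near-perfect, CLR/ONT
# carry 5-15% errors so pairwise identity of a true overlap drops accordingly
_PLATFORM_IDENTITY = {"hifi": 0.95, "clr": 0.75, "ont": 0.75}


@dataclass
class AssemblyParams:
    """Tunable parameters of the assembly pipeline.

    ``min_identity`` defaults per platform (0.95 hifi, 0.75 clr/ont) unless set
    explicitly. ``correct_raw_reads`` defaults to on for the noisy platforms
    (clr/ont) and off for hifi.
    """

    platform: str = "hifi"
    min_ovlp_len: int = 1000
    min_identity: Optional[float] = None
    snp_filter_k: int = 0
    max_phasing_coverage: int = 20
    tip_max_nodes: int = 2
    min_contig_len: int = 1000
    correct_raw_reads: Optional[bool] = None
    snp_edge_filter: bool = False
    polish_final: bool = True
    polish_rounds: int = 2
    rng_seed: int = 1
    # super-read graph uses stricter thresholds than the read graph
    # (identity None: 0.98 hifi; 0.95 clr/ont, where even majority-voted super
    # reads keep ~1-2% residual error at their thinly covered ends and
    # cross-haplotype joins are instead rejected by the SNP edge filter)
    sr_min_ovlp_len: int = 3000
    sr_min_identity: Optional[float] = None
    # super-read end trim: minimum pileup coverage kept. None: 2 for hifi; 5
    # for noisy platforms — with ~10% per-base error, 2 voters can tie, 4 can
    # tie 2-2, and 5 is the smallest depth where an erroneous majority needs
    # three independent errors
    sr_trim_min_cov: Optional[int] = None
    # pileup SNP caller thresholds
    snp_min_depth: int = 10
    snp_min_allele_count: int = 3
    snp_af_low: float = 0.2
    snp_af_high: float = 0.8
    # allele-frequency band for genotyping super-read joins: tighter than the
    # phasing band so isolated sequencing errors cannot reach het status,
    # while a true cross-haplotype join (both groups represented) stays inside
    join_af_low: float = 0.3
    join_af_high: float = 0.7
    threads: int = 1

    def __post_init__(self) -> None:
        if self.platform not in _PLATFORM_IDENTITY:
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.min_identity is None:
            self.min_identity = _PLATFORM_IDENTITY[self.platform]
        if not 0 < self.min_identity <= 1:
            raise ValueError(f"min_identity must be in (0, 1], got {self.min_identity}")
        if self.min_ovlp_len < 1:
            raise ValueError("min_ovlp_len must be >= 1")
        if self.snp_filter_k < 0:
            raise ValueError("snp_filter_k must be >= 0")
        if self.correct_raw_reads is None:
            self.correct_raw_reads = self.platform in ("clr", "ont")
        if self.sr_trim_min_cov is None:
            self.sr_trim_min_cov = 5 if self.platform in ("clr", "ont") else 2
        if self.sr_min_identity is None:
            self.sr_min_identity = 0.95 if self.platform in ("clr", "ont") else 0.98


def _open_text(path) -> _io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sniff_format(path) -> str:
    name = Path(path).name
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    return "fasta"


def read_sequences(path, fmt: str = "auto") -> list[Read]:
    """Parse a FASTA or FASTQ file (optionally gzipped) into a list of Reads.

    Record order is preserved, lowercase bases are uppercased, FASTQ qualities
    are retained. Duplicate ids raise.
    """
    if fmt == "auto":
        fmt = _sniff_format(path)
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {fmt!r}")
    reads: list[Read] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for i, rec in enumerate(SeqIO.parse(fh, fmt)):
            if rec.id in seen:
                raise ValueError(f"duplicate read id {rec.id!r} (record {i})")
            seen.add(rec.id)
            qual = rec.letter_annotations.get("phred_quality")
            reads.append(Read(rec.id, str(rec.seq), list(qual) if qual else None))
    return reads


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 80) -> None:
    """Write (header, sequence) pairs as FASTA."""
    with open(path, "wt") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_paf(path) -> list:
    """Read PAF overlaps (12 mandatory columns; extra columns ignored)."""
    from .overlap import Overlap

    overlaps = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(f"PAF line {lineno}: expected >= 12 columns, got {len(cols)}")
            (qid, qlen, qs, qe, strand, tid, tlen, ts, te, nmatch, blen, _mapq) = cols[:12]
            qlen, qs, qe = int(qlen), int(qs), int(qe)
            tlen, ts, te = int(tlen), int(ts), int(te)
            nmatch, blen = int(nmatch), int(blen)
            if not (0 <= qs < qe <= qlen) or not (0 <= ts < te <= tlen):
                raise ValueError(f"PAF line {lineno}: coordinates out of range")
            if strand not in "+-":
                raise ValueError(f"PAF line {lineno}: bad strand {strand!r}")
            overlaps.append(
                Overlap(
                    query_id=qid, target_id=tid,
                    query_len=qlen, target_len=tlen,
                    query_start=qs, query_end=qe,
                    target_start=ts, target_end=te,
                    strand=strand, n_matches=nmatch, block_len=blen,
                )
            )
    return overlaps


def write_paf(overlaps: Sequence, path) -> None:
    with open(path, "wt") as fh:
        for ov in overlaps:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        ov.query_id, ov.query_len, ov.query_start, ov.query_end,
                        ov.strand,
                        ov.target_id, ov.target_len, ov.target_start, ov.target_end,
                        ov.n_matches, ov.block_len, 255,
                    )
                )
                + "\n"
            )


def write_gfa(graph, sequences: dict[str, str], path) -> None:
    """Dump an overlap graph as GFA 1.0 (S and L lines)."""
    with open(path, "wt") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for node in graph.nodes:
            seq = sequences.get(node, "*")
            fh.write(f"S\t{node}\t{seq}\n")
        for u, v, data in graph.edges(data=True):
            ov = data.get("overlap")
            olen = ov.block_len if ov is not None else 0
            fh.write(f"L\t{u}\t+\t{v}\t+\t{olen}M\n")


_BOOL_FIELDS = {"correct_raw_reads", "snp_edge_filter", "polish_final"}


def _coerce(name: str, value: str):
    if name == "platform":
        return value
    if name in _BOOL_FIELDS:
        low = value.strip().lower()
        if low in ("1", "true", "yes", "on"):
            return True
        if low in ("0", "false", "no", "off"):
            return False
        raise ValueError(f"cannot parse boolean {name}={value!r}")
    if name in ("min_identity", "sr_min_identity", "snp_af_low", "snp_af_high"):
        return float(value)
    return int(value)


def load_params(config_path=None, **overrides) -> AssemblyParams:
    """Build AssemblyParams from an optional flat key=value file plus overrides.

    Overrides (CLI flags) take precedence over file values. Unknown keys are
    rejected.
    """
    valid = {f.name for f in fields(AssemblyParams)}
    values: dict = {}
    if config_path is not None:
        with _open_text(config_path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"config line {lineno}: expected key=value")
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in valid:
                    raise ValueError(f"config line {lineno}: unknown key {key!r}")
                values[key] = _coerce(key, value)
    for key, value in overrides.items():
        if value is None:
            continue
        if key not in valid:
            raise ValueError(f"unknown parameter {key!r}")
        values[key] = value
    return AssemblyParams(**values)


def save_manifest(manifest: dict, path) -> None:
    with open(path, "wt") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
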