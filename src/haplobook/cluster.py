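"""Seed-centred read clustering: the divide stage.

Reads are processed in order of decreasing length; each iteration takes the
longest unprocessed read as seed, collects every unprocessed read that has a
retained overlap with it into one cluster, and removes them all from further
consideration. Longer seeds attract more overlaps, so this greedy order keeps
the number of clusters small and the local assemblies long.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io import Read
from .overlap import Overlap

__all__ = ["ReadCluster", "build_clusters", "write_clusters_tsv"]


@dataclass
class ReadCluster:
    cluster_id: int
    seed_id: str
    member_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.member_ids.add(self.seed_id)

    @property
    def size(self) -> int:
        return len(self.member_ids)


def build_clusters(reads: Sequence[Read], overlaps: Iterable[Overlap]) -> list[ReadCluster]:
    """Greedy seed-centred partition of the read set.

    ``overlaps`` must already be filtered. Length ties are broken by read id
    so the partition is deterministic. Every read ends up in exactly one
    cluster; reads with no overlaps become singleton clusters.
    """
    neigh: dict[str, set[str]] = {r.id: set() for r in reads}
    for ov in overlaps:
        if ov.query_id in neigh and ov.target_id in neigh:
            neigh[ov.query_id].add(ov.target_id)
            neigh[ov.target_id].add(ov.query_id)
    order = sorted(reads, key=lambda r: (-r.length, r.id))
    processed: set[str] = set()
    clusters: list[ReadCluster] = []
    for read in order:
        if read.id in processed:
            continue
        members = {read.id} | {m for m in neigh[read.id] if m not in processed}
        processed |= members
        clusters.append(ReadCluster(len(clusters), read.id, members))
    return clusters


def write_clusters_tsv(clusters: Iterable[ReadCluster], path) -> None:
    with open(path, "wt") as fh:
        fh.write("cluster_id\tseed_id\tmember_id\n")
        for cl in clusters:
            for m in sorted(cl.member_ids):
                fh.write(f"{cl.cluster_id}\t{cl.seed_id}\t{m}\n")
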