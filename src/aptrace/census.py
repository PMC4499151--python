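"""Per-pool prevalence tables and sequence status classification.

The census of a pool is the exact multiset count of unique random-region
sequences ("prevalence").  Across a whole selection dataset, sequences fall
into three classes: *bystanders* seen exactly once in the entire dataset
(unselected background), *unclustered* true aptamers (multiple copies but no
near neighbour), and *clustered* true aptamers (members of a mutant family).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Optional, Sequence

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .cluster import Cluster

STATUSES = ("bystander", "unclustered", "clustered")


@dataclass
class PoolCensus:
    """Counts of unique sequences observed in one pool."""

    pool_id: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def region_length(self) -> Optional[int]:
        for seq in self.counts:
            return len(seq)
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(rows, columns=["sequence", "count"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path, pool_id: Optional[str] = None) -> "PoolCensus":
        df = pd.read_csv(path, sep="\t", dtype={"sequence": str, "count": int})
        pid = pool_id if pool_id is not None else Path(path).stem
        return cls(pool_id=pid, counts=dict(zip(df["sequence"], df["count"])))


def build_census(regions: Iterable[str], pool_id: str) -> PoolCensus:
    """Exact multiset count of the region stream; order-independent.

    All regions must share one length; a mixed-length stream raises ValueError
    naming the first offending sequence.
    """
    counts: Counter[str] = Counter()
    length: Optional[int] = None
    for seq in regions:
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise ValueError(
                f"pool {pool_id!r}: sequence {seq!r} has length {len(seq)}, expected {length}"
            )
        counts[seq] += 1
    return PoolCensus(pool_id=pool_id, counts=dict(sorted(counts.items())))


def combine_censuses(censuses: Sequence[PoolCensus]) -> pd.DataFrame:
    """Wide prevalence table: one row per sequence, one column per pool."""
    lengths = {c.region_length for c in censuses if c.region_length is not None}
    if len(lengths) > 1:
        raise ValueError(f"censuses mix region lengths: {sorted(lengths)}")
    series = {c.pool_id: pd.Series(c.counts, dtype="int64") for c in censuses}
    wide = pd.DataFrame(series).fillna(0).astype("int64")
    wide.index.name = "sequence"
    return wide.sort_index()


@dataclass(frozen=True)
class SequenceStatus:
    sequence: str
    status: str
    cluster_id: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.status == "clustered") != (self.cluster_id is not None):
            raise ValueError("cluster_id must be present iff status is 'clustered'")


def _cluster_membership(clusters: Sequence["Cluster"]) -> dict[str, tuple[str, int]]:
    membership: dict[str, tuple[str, int]] = {}
    for cl in clusters:
        size = len(cl.members)
        for m in cl.members:
            membership[m.sequence] = (cl.cluster_id, size)
    return membership


def classify_sequences(
    censuses: Sequence[PoolCensus],
    clusters: Optional[Sequence["Cluster"]] = None,
) -> list[SequenceStatus]:
    """Classify every unique sequence across the dataset.

    A sequence with a single copy in a single pool is a bystander; anything
    with more copies (or present in several pools) is a true aptamer.  With a
    clustering result, true aptamers assigned to a cluster of size >= 2 are
    'clustered', the rest 'unclustered'.  Lone-cluster members count as
    unclustered (a family of one is no family).
    """
    totals: Counter[str] = Counter()
    for c in censuses:
        totals.update(c.counts)
    membership = _cluster_membership(clusters) if clusters is not None else {}
    statuses = []
    for seq in sorted(totals):
        if totals[seq] == 1:
            statuses.append(SequenceStatus(seq, "bystander"))
            continue
        cid_size = membership.get(seq)
        if cid_size is not None and cid_size[1] >= 2:
            statuses.append(SequenceStatus(seq, "clustered", cid_size[0]))
        else:
            statuses.append(SequenceStatus(seq, "unclustered"))
    return statuses


def statuses_to_frame(statuses: Sequence[SequenceStatus]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"sequence": s.sequence, "status": s.status, "cluster_id": s.cluster_id or ""}
         for s in statuses]
    )


def round_composition(
    statuses: Sequence[SequenceStatus],
    censuses_by_round: Mapping[int, PoolCensus],
    clusters: Optional[Sequence["Cluster"]] = None,
) -> pd.DataFrame:
    """Per-round composition fractions and cluster convergence statistics.

    Fractions are over *unique* sequences present in each round (bystanders
    are single-read by definition, so read-weighted fractions would carry no
    information).  Cluster statistics cover clusters of size >= 2 with at
    least one member present in the round; ``mean_cluster_size`` is the mean
    number of members of such clusters observed in that round.
    """
    status_of = {s.sequence: s.status for s in statuses}
    real_clusters = [cl for cl in (clusters or []) if len(cl.members) >= 2]
    rows = []
    for rnd in sorted(censuses_by_round):
        present = set(censuses_by_round[rnd].counts)
        n = len(present)
        tallies = Counter(status_of.get(seq, "bystander") for seq in present)
        row: dict[str, object] = {"round": rnd, "n_unique": n}
        for st in STATUSES:
            row[f"frac_{st}"] = tallies[st] / n if n else 0.0
        if clusters is not None:
            sizes = []
            for cl in real_clusters:
                k = sum(1 for m in cl.members if m.sequence in present)
                if k:
                    sizes.append(k)
            row["n_clusters"] = len(sizes)
            row["mean_cluster_size"] = sum(sizes) / len(sizes) if sizes else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
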