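"""Edit-distance clustering of related sequences around founder sequences.

Selection pools contain families of sequences that arose by polymerase
misincorporation from a single abundant "founder".  Family members sit within
a small edit distance (substitutions, insertions, deletions) of the founder,
so clustering is greedy and abundance-ordered: the most abundant unassigned
sequence seeds a cluster and absorbs every unassigned sequence within
``max_dist`` edits of it.  A k-mer-profile prefilter cheaply discards distant
candidate pairs without ever excluding a true neighbour: one edit changes at
most k overlapping k-mers, so a pair at edit distance <= d differs by at most
2*k*d in L1 distance between k-mer count vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, Union

import edlib
import numpy as np
import pandas as pd

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def edit_distance(a: str, b: str, k: int = -1) -> int:
    """Unit-cost Levenshtein distance between two sequences.

    ``k >= 0`` bounds the computation; distances above ``k`` return -1.
    """
    return edlib.align(a, b, task="distance", k=k)["editDistance"]


def kmer_profile(seq: str, k: int = 4) -> np.ndarray:
    """Count vector over all 4**k DNA k-mers (lexicographic order)."""
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k={k}")
    codes = np.array([_BASE_CODE[c] for c in seq], dtype=np.int64)
    kmers = np.zeros(len(seq) - k + 1, dtype=np.int64)
    for i in range(k):
        kmers = kmers * 4 + codes[i:len(codes) - k + 1 + i]
    return np.bincount(kmers, minlength=4 ** k).astype(np.int32)


def kmer_distance(a: str, b: str, k: int = 4) -> float:
    """Euclidean distance between the k-mer count profiles of two sequences."""
    return float(np.linalg.norm(kmer_profile(a, k) - kmer_profile(b, k)))


@dataclass(frozen=True)
class ClusterMember:
    sequence: str
    edit_distance: int


@dataclass
class Cluster:
    """A founder sequence and its near variants (edit distance <= max_dist).

    The founder is the member with the highest total copy number; abundance
    ties break to the lexicographically smallest sequence.
    """

    cluster_id: str
    founder: str
    members: list[ClusterMember]

    def __len__(self) -> int:
        return len(self.members)

    @property
    def sequences(self) -> list[str]:
        return [m.sequence for m in self.members]


CensusLike = Union[pd.DataFrame, pd.Series, Mapping[str, int]]


def _totals(census: CensusLike) -> pd.Series:
    if isinstance(census, pd.DataFrame):
        return census.sum(axis=1)
    if isinstance(census, pd.Series):
        return census
    return pd.Series(census, dtype="int64")


def cluster_pool(
    census: CensusLike,
    max_dist: int = 3,
    k: int = 4,
    prefilter: bool = True,
) -> list[Cluster]:
    """Greedy founder-first clustering of a combined census.

    ``census`` maps sequence -> count (a Series/dict) or is a wide
    sequence-by-pool count table whose row sums give total abundance.
    Sequences are processed in descending total count (ties lexicographic);
    each seed collects all unassigned sequences within edit distance
    ``max_dist`` of it.  Candidates are prefiltered on base-composition and
    k-mer-profile L1 distance (admission threshold 2*k*max_dist, which can
    never exclude a true neighbour), then confirmed by exact edit distance.
    Deterministic for a given census.
    """
    totals = _totals(census)
    if totals.empty:
        raise ValueError("cannot cluster an empty census")
    order = sorted(totals.index, key=lambda s: (-int(totals[s]), s))
    seqs = list(order)
    n = len(seqs)
    lengths = np.array([len(s) for s in seqs], dtype=np.int32)
    prof1 = np.zeros((n, 4), dtype=np.int32)
    profk = None
    if prefilter:
        for i, s in enumerate(seqs):
            for c in s:
                prof1[i, _BASE_CODE[c]] += 1
        profk = np.vstack([kmer_profile(s, k) for s in seqs])
    unassigned = np.ones(n, dtype=bool)
    clusters: list[Cluster] = []
    for i in range(n):
        if not unassigned[i]:
            continue
        unassigned[i] = False
        cand = np.flatnonzero(unassigned)
        if cand.size and prefilter:
            cand = cand[np.abs(lengths[cand] - lengths[i]) <= max_dist]
            if cand.size:
                d1 = np.abs(prof1[cand] - prof1[i]).sum(axis=1)
                cand = cand[d1 <= 2 * max_dist]
            if cand.size:
                dk = np.abs(profk[cand] - profk[i]).sum(axis=1)
                cand = cand[dk <= 2 * k * max_dist]
        members = [ClusterMember(seqs[i], 0)]
        for j in cand:
            d = edit_distance(seqs[j], seqs[i], k=max_dist)
            if 0 <= d <= max_dist:
                members.append(ClusterMember(seqs[j], d))
                unassigned[j] = False
        clusters.append(Cluster(
            cluster_id=f"C{len(clusters) + 1:04d}",
            founder=seqs[i],
            members=members,
        ))
    return clusters


def clusters_to_frame(clusters: Sequence[Cluster], census: CensusLike = None) -> pd.DataFrame:
    """Long-format cluster table, optionally annotated with per-pool counts."""
    wide = census if isinstance(census, pd.DataFrame) else None
    totals = _totals(census) if census is not None else None
    rows = []
    for cl in clusters:
        for m in sorted(cl.members, key=lambda m: (m.edit_distance, m.sequence)):
            row: dict[str, object] = {
                "cluster_id": cl.cluster_id,
                "sequence": m.sequence,
                "is_founder": int(m.sequence == cl.founder),
                "edit_distance": m.edit_distance,
            }
            if totals is not None:
                row["total_count"] = int(totals.get(m.sequence, 0))
            if wide is not None:
                for pool in wide.columns:
                    row[f"count_{pool}"] = int(wide.at[m.sequence, pool]) \
                        if m.sequence in wide.index else 0
            rows.append(row)
    return pd.DataFrame(rows)


def write_clusters(clusters: Sequence[Cluster], path: str | Path,
                   census: CensusLike = None) -> None:
    clusters_to_frame(clusters, census).to_csv(path, sep="\t", index=False)
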