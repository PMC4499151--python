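"""Within-cluster mutational landscapes.

Polymerase errors during inter-round amplification seed each abundant founder
with a cloud of point-mutation derivatives.  Selection then reshapes that
cloud: variants whose mutation improves binding out-replicate their siblings,
while mutations at functionally critical ("cornerstone") positions are purged.
Comparing each position's observed derivative copies with the cluster-average
expectation therefore reads out, from sequencing data alone, which positions
tolerate, favour, or forbid substitution.

The cluster substitution rate is

    sigma = (total copies of all derivative sequences) / (founder copies * L)

with L the random-region length.  Under a uniform-error null, every position
expects ``founder_copies * sigma`` derivative copies; positions observed
``high_fold`` above (default 3) or ``low_fold`` below (default 1/3) that
expectation are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import Cluster

_BASES = ("A", "C", "G", "T")


def _single_substitution(founder: str, variant: str) -> Optional[tuple[int, str]]:
    """(1-based position, alternative base) if variant is a single substitution."""
    if len(variant) != len(founder):
        return None
    diff = [i for i, (a, b) in enumerate(zip(founder, variant)) if a != b]
    if len(diff) != 1:
        return None
    return diff[0] + 1, variant[diff[0]]


def substitution_rate(cluster: Cluster, counts: Mapping[str, int]) -> Optional[float]:
    """Cluster-average substitution rate sigma in the given pool.

    ``counts`` maps sequence -> copies in the pool.  Returns None when the
    founder is absent from the pool (rate undefined there).
    """
    founder_count = int(counts.get(cluster.founder, 0))
    if founder_count <= 0:
        return None
    derivative = sum(int(counts.get(m.sequence, 0))
                     for m in cluster.members if m.sequence != cluster.founder)
    return derivative / (founder_count * len(cluster.founder))


@dataclass
class LandscapeTable:
    """Per-position mutational profile of one cluster in one pool."""

    cluster_id: str
    founder: str
    founder_count: int
    sigma: float
    expected_per_position: float
    other_copies: int          # multi-substitution / indel derivatives
    total_derivative_copies: int
    per_position: pd.DataFrame

    @property
    def region_length(self) -> int:
        return len(self.founder)

    def write(self, path) -> None:
        self.per_position.to_csv(path, sep="\t", index=False)


def position_profile(
    cluster: Cluster,
    counts: Mapping[str, int],
    high_fold: float = 3.0,
    low_fold: float = 1.0 / 3.0,
    expected_rate: Optional[float] = None,
    alpha: float = 0.01,
) -> LandscapeTable:
    """Attribute single-substitution derivative copies to positions and flag them.

    Copies of each single-substitution variant are attributed to its position
    and alternative base; derivatives at edit distance 2-3 or with indels are
    tallied in an "other" class that contributes to sigma but not to any
    position.  ``expected_rate`` overrides the cluster's own sigma as the
    per-position expectation — useful when the member list is a curated
    subset that under-counts the true within-cluster rate.  Flags are
    ``high`` / ``low`` / ``normal`` by the fold thresholds; a one-sided
    Poisson tail probability (mean = expected copies) is reported alongside
    and marked significant at ``alpha``.
    """
    founder = cluster.founder
    L = len(founder)
    founder_count = int(counts.get(founder, 0))
    if founder_count <= 0:
        raise ValueError(
            f"founder of cluster {cluster.cluster_id!r} absent from pool; profile undefined")
    sigma = substitution_rate(cluster, counts)
    assert sigma is not None
    expected = founder_count * (expected_rate if expected_rate is not None else sigma)

    sub_copies = np.zeros((L, 4), dtype=np.int64)
    sub_variants = np.zeros((L, 4), dtype=np.int64)
    other_copies = 0
    total_derivative = 0
    for m in cluster.members:
        if m.sequence == founder:
            continue
        c = int(counts.get(m.sequence, 0))
        if c == 0:
            continue
        total_derivative += c
        hit = _single_substitution(founder, m.sequence)
        if hit is None:
            other_copies += c
            continue
        pos, alt = hit
        sub_copies[pos - 1, _BASES.index(alt)] += c
        sub_variants[pos - 1, _BASES.index(alt)] += 1

    rows = []
    for pos in range(1, L + 1):
        copies = int(sub_copies[pos - 1].sum())
        n_var = int((sub_variants[pos - 1] > 0).sum())
        if expected <= 0:
            flag, p_tail = "normal", np.nan
        elif copies >= high_fold * expected:
            flag = "high"
            p_tail = float(stats.poisson.sf(copies - 1, expected))
        elif copies <= low_fold * expected:
            flag = "low"
            p_tail = float(stats.poisson.cdf(copies, expected))
        else:
            flag, p_tail = "normal", np.nan
        rows.append({
            "position": pos,
            "founder_base": founder[pos - 1],
            **{f"copies_{b}": int(sub_copies[pos - 1, i]) for i, b in enumerate(_BASES)},
            "copies": copies,
            "n_distinct_variants": n_var,
            "expected": expected,
            "flag": flag,
            "poisson_p": p_tail,
            "significant": bool(p_tail < alpha) if np.isfinite(p_tail) else False,
        })
    return LandscapeTable(
        cluster_id=cluster.cluster_id,
        founder=founder,
        founder_count=founder_count,
        sigma=sigma,
        expected_per_position=float(expected),
        other_copies=other_copies,
        total_derivative_copies=total_derivative,
        per_position=pd.DataFrame(rows),
    )


def candidate_variants(
    table: LandscapeTable,
    cluster: Cluster,
    counts: Mapping[str, int],
) -> pd.DataFrame:
    """Rank single-substitution variants at high-flagged positions for testing.

    Variants are ordered by copy number; variants at positions where all
    three alternative bases occur are down-ranked, since uniformly mutable
    positions behave like neutral sites and their abundance is less likely to
    reflect improved binding.
    """
    high_pos = set(table.per_position.loc[table.per_position["flag"] == "high",
                                          "position"])
    n_var = dict(zip(table.per_position["position"],
                     table.per_position["n_distinct_variants"]))
    rows = []
    for m in cluster.members:
        if m.sequence == cluster.founder:
            continue
        hit = _single_substitution(cluster.founder, m.sequence)
        if hit is None:
            continue
        pos, alt = hit
        if pos not in high_pos:
            continue
        rows.append({
            "sequence": m.sequence,
            "position": pos,
            "substitution": f"{cluster.founder[pos - 1]}{pos}{alt}",
            "copies": int(counts.get(m.sequence, 0)),
            "downranked": n_var.get(pos, 0) >= 3,
        })
    df = pd.DataFrame(rows, columns=["sequence", "position", "substitution",
                                     "copies", "downranked"])
    if df.empty:
        return df
    df = df.sort_values(by=["downranked", "copies", "sequence"],
                        ascending=[True, False, True], kind="mergesort")
    return df.reset_index(drop=True)
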