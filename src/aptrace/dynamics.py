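"""Pool dynamics: enrichment rates, candidate ranking, amplification bias,
diversity accounting and convergence detection.

The enrichment rate of a sequence is its round-over-round prevalence ratio.
Because selection retains binders preferentially, the rate tracks binding
affinity more faithfully than prevalence alone, which mostly reflects the
starting template and early amplification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .census import PoolCensus
from .demux import gc_content


def enrichment_rate(
    count_prev: int,
    count_next: int,
    pseudocount: float = 0.5,
) -> Optional[float]:
    """Round-over-round prevalence ratio.

    Plain ratio ``count_next / count_prev`` when the sequence was already
    observed; for sequences newly appearing (``count_prev == 0``) the
    pseudocount regularises the rate to ``(count_next + p) / p``, which keeps
    ordering while avoiding infinities.  Both counts zero -> None (missing).
    """
    if count_prev < 0 or count_next < 0:
        raise ValueError("counts must be non-negative")
    if count_prev == 0 and count_next == 0:
        return None
    if count_prev == 0:
        if pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        return (count_next + pseudocount) / pseudocount
    return count_next / count_prev


def round_rate(rate: Optional[float]) -> Optional[float]:
    """One-decimal presentation rounding (round-half-to-even) used in tables."""
    return None if rate is None else round(rate, 1)


def enrichment_table(
    census_wide: pd.DataFrame,
    round_order: Sequence[str],
    pseudocount: float = 0.5,
    depth_normalize: bool = False,
) -> pd.DataFrame:
    """Per-sequence prevalence trajectory and transition rates.

    ``round_order`` lists the pool columns of ``census_wide`` in round order.
    With ``depth_normalize`` counts are rescaled to reads-per-million before
    ratios, for pools of unequal depth; the default is raw counts.
    Adds GC content of each sequence.
    """
    missing = [c for c in round_order if c not in census_wide.columns]
    if missing:
        raise KeyError(f"pools not in census table: {missing}")
    df = census_wide[list(round_order)].copy()
    df = df[df.sum(axis=1) > 0]
    values = df.to_numpy(dtype=float)
    if depth_normalize:
        depths = values.sum(axis=0)
        values = values / np.where(depths > 0, depths, 1.0) * 1e6
    out = df.copy()
    for i in range(len(round_order) - 1):
        a, b = round_order[i], round_order[i + 1]
        col = []
        for prev, nxt in zip(values[:, i], values[:, i + 1]):
            if prev == 0 and nxt == 0:
                col.append(np.nan)
            elif prev == 0:
                col.append((nxt + pseudocount) / pseudocount)
            else:
                col.append(nxt / prev)
        out[f"rate_{a}_to_{b}"] = col
    out["gc_content"] = [gc_content(s) for s in out.index]
    return out


def rank_candidates(
    records: pd.DataFrame,
    mode: str = "combined",
    prevalence_col: Optional[str] = None,
    rate_col: Optional[str] = None,
) -> pd.DataFrame:
    """Order candidates by prevalence, enrichment rate, or both combined.

    ``prevalence_col`` defaults to the last count column and ``rate_col`` to
    the last ``rate_*`` column of an :func:`enrichment_table` output.  The
    combined mode scores each sequence by the *worse* (max) of its two
    individual ranks, so a top candidate must rank high in both; ties break
    by prevalence, then sequence.
    """
    if records.empty:
        raise ValueError("no records to rank")
    rate_cols = [c for c in records.columns if c.startswith("rate_")]
    if rate_col is None:
        if not rate_cols:
            raise ValueError("no rate_* column found; pass rate_col")
        rate_col = rate_cols[-1]
    if prevalence_col is None:
        count_cols = [c for c in records.columns
                      if c not in rate_cols and c != "gc_content"]
        prevalence_col = count_cols[-1]
    df = records.copy()
    if mode == "prevalence":
        return df.sort_values(by=[prevalence_col, rate_col],
                              ascending=[False, False], kind="mergesort")
    if mode == "enrichment":
        return df.sort_values(by=[rate_col, prevalence_col],
                              ascending=[False, False], kind="mergesort")
    if mode == "combined":
        rank_p = df[prevalence_col].rank(ascending=False, method="min")
        rank_e = df[rate_col].rank(ascending=False, method="min", na_option="bottom")
        df["combined_rank"] = np.maximum(rank_p, rank_e)
        return df.sort_values(by=["combined_rank", prevalence_col],
                              ascending=[True, False], kind="mergesort")
    raise ValueError(f"unknown ranking mode {mode!r}")


def gc_binned_enrichment(
    gc_a: Sequence[float], rate_a: Sequence[float],
    gc_b: Sequence[float], rate_b: Sequence[float],
    bins: int | Sequence[float] = 10,
) -> pd.DataFrame:
    """Mean enrichment rate per GC-content bin for two amplification arms.

    ``bins`` is either a number of quantile bins over the pooled GC values
    (default: deciles) or explicit bin edges.  Bins with no members in an arm
    report NaN.
    """
    gc_a = np.asarray(gc_a, dtype=float)
    gc_b = np.asarray(gc_b, dtype=float)
    rate_a = np.asarray(rate_a, dtype=float)
    rate_b = np.asarray(rate_b, dtype=float)
    pooled = np.concatenate([gc_a, gc_b])
    if isinstance(bins, int):
        edges = np.unique(np.quantile(pooled, np.linspace(0, 1, bins + 1)))
    else:
        edges = np.asarray(bins, dtype=float)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        last = hi == edges[-1]
        in_a = (gc_a >= lo) & ((gc_a <= hi) if last else (gc_a < hi))
        in_b = (gc_b >= lo) & ((gc_b <= hi) if last else (gc_b < hi))
        rows.append({
            "gc_low": lo, "gc_high": hi,
            "n_a": int(in_a.sum()),
            "mean_rate_a": float(np.nanmean(rate_a[in_a])) if in_a.any() else np.nan,
            "n_b": int(in_b.sum()),
            "mean_rate_b": float(np.nanmean(rate_b[in_b])) if in_b.any() else np.nan,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DiversityDelta:
    """Gain/loss bookkeeping between an earlier and a later pool census."""

    n_prior: int
    n_lost: int
    n_new: int

    @property
    def net_change_fraction(self) -> float:
        if self.n_prior == 0:
            return 0.0
        return (self.n_new - self.n_lost) / self.n_prior

    @property
    def lost_fraction(self) -> float:
        return self.n_lost / self.n_prior if self.n_prior else 0.0


def diversity_accounting(
    census_prior: PoolCensus,
    census_later: PoolCensus,
    low_abundance_cutoff: int = 100,
) -> tuple[DiversityDelta, DiversityDelta]:
    """Set algebra on census keys between two pools.

    Returns ``(overall, low_abundance)``, the second restricted to prior
    sequences with count <= cutoff (new sequences have no prior count, so the
    restricted delta has ``n_new == 0``).
    """
    la = {c.region_length for c in (census_prior, census_later) if c.region_length}
    if len(la) > 1:
        raise ValueError(f"censuses mix region lengths: {sorted(la)}")
    prior = set(census_prior.counts)
    later = set(census_later.counts)
    overall = DiversityDelta(
        n_prior=len(prior),
        n_lost=len(prior - later),
        n_new=len(later - prior),
    )
    low = {s for s in prior if census_prior.counts[s] <= low_abundance_cutoff}
    restricted = DiversityDelta(
        n_prior=len(low),
        n_lost=len(low - later),
        n_new=0,
    )
    return overall, restricted


def convergence_report(stats: pd.DataFrame) -> tuple[pd.DataFrame, Optional[object]]:
    """Detect the convergence signature in per-round cluster statistics.

    ``stats`` needs columns ``round``, ``n_clusters``, ``mean_cluster_size``.
    Convergence is flagged at the first round where the number of clusters
    drops while their mean size keeps rising — the point where selection has
    turned competitive and weaker families start going extinct.  Returns the
    table with a ``converged`` flag column and the flagged round (or None).
    """
    if len(stats) < 2:
        raise ValueError("convergence detection needs at least 2 rounds")
    df = stats.sort_values("round").reset_index(drop=True).copy()
    flags = [False]
    for i in range(1, len(df)):
        flags.append(
            df.loc[i, "n_clusters"] < df.loc[i - 1, "n_clusters"]
            and df.loc[i, "mean_cluster_size"] > df.loc[i - 1, "mean_cluster_size"]
        )
    df["converged"] = flags
    flagged = df.loc[df["converged"], "round"]
    return df, (flagged.iloc[0] if not flagged.empty else None)
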