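"""End-to-end orchestration: reads in, annotated candidate shortlist out.

Stages run in a fixed order — demultiplex/extract, census, classification and
clustering, enrichment dynamics, specificity screening, mutational landscapes
— each checkpointed as a TSV artifact so any stage can be re-run or inspected
independently.  A rerun on identical inputs and config is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import census as census_mod
from . import cluster as cluster_mod
from . import dynamics as dynamics_mod
from . import landscape as landscape_mod
from . import specificity as specificity_mod
from .demux import PoolSpec, demux_and_extract, read_pool_sheet, read_sequences

log = logging.getLogger("aptrace.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class RunConfig:
    pool_sheet: str
    reads: list[str]                       # FASTQ/FASTA files (gzip ok)
    out_dir: str
    target_label: str
    control_label: Optional[str] = None
    adjusted_label: Optional[str] = None
    ortholog_label: Optional[str] = None
    max_barcode_mismatches: int = 0
    max_flank_mismatches: int = 2
    max_dist: int = 3
    kmer_k: int = 4
    pseudocount: float = 0.5
    fold: float = 10.0
    similarity: float = 3.0
    high_fold: float = 3.0
    low_fold: float = 1.0 / 3.0
    depth_normalize: str = "auto"
    n_landscape_clusters: int = 5
    shortlist_size: int = 20
    min_report_count: int = 5   # final-round prevalence needed to be ranked
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _validate(config: RunConfig) -> list[PoolSpec]:
    if not Path(config.pool_sheet).is_file():
        raise PipelineError(f"validate: pool sheet not found: {config.pool_sheet}")
    if not config.reads:
        raise PipelineError("validate: no read files given")
    for path in config.reads:
        if not Path(path).is_file():
            raise PipelineError(f"validate: read file not found: {path}")
    specs = read_pool_sheet(config.pool_sheet)
    if not specs:
        raise PipelineError(f"validate: empty pool sheet: {config.pool_sheet}")
    return specs


def _target_round_pools(specs: Sequence[PoolSpec], label: str) -> list[PoolSpec]:
    """Main-trajectory pools of the target, one per round, in round order."""
    chosen: dict[int, PoolSpec] = {}
    for s in sorted(specs, key=lambda s: (s.round_index, s.pool_id)):
        if s.target_label == label and s.round_index not in chosen:
            chosen[s.round_index] = s
    return [chosen[r] for r in sorted(chosen)]


def _latest_pool(specs: Sequence[PoolSpec], label: str) -> Optional[str]:
    cands = [s for s in specs if s.target_label == label]
    if not cands:
        return None
    return max(cands, key=lambda s: (s.round_index, s.pool_id)).pool_id


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Execute all stages; returns the candidate report (also written to disk)."""
    specs = _validate(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "run_config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2, sort_keys=True)

    # --- stage: demux + extract ------------------------------------------------
    try:
        def read_stream():
            for path in config.reads:
                yield from read_sequences(path)
        regions, tally = demux_and_extract(
            read_stream(), specs, config.max_barcode_mismatches,
            config.max_flank_mismatches)
    except Exception as exc:  # noqa: BLE001 - reported with stage context
        raise PipelineError(f"demux: {exc}") from exc
    tally.to_csv(out / "demux_tally.tsv", sep="\t", index=False)
    log.info("demux: %s", dict(zip(tally["reason"], tally["count"])))

    # --- stage: census ---------------------------------------------------------
    censuses = []
    census_dir = out / "census"
    census_dir.mkdir(exist_ok=True)
    for spec in specs:
        try:
            c = census_mod.build_census(regions[spec.pool_id], spec.pool_id)
        except ValueError as exc:
            raise PipelineError(f"census: pool {spec.pool_id}: {exc}") from exc
        c.write(census_dir / f"{spec.pool_id}.tsv")
        censuses.append(c)
    wide = census_mod.combine_censuses(censuses)
    wide.to_csv(out / "census_wide.tsv", sep="\t")

    # --- stage: clustering + classification ------------------------------------
    totals = wide.sum(axis=1)
    true_aptamers = wide[totals > 1]
    if true_aptamers.empty:
        raise PipelineError("cluster: no sequence with more than one copy")
    clusters = cluster_mod.cluster_pool(true_aptamers, max_dist=config.max_dist,
                                        k=config.kmer_k)
    cluster_mod.write_clusters(clusters, out / "clusters.tsv", true_aptamers)
    statuses = census_mod.classify_sequences(censuses, clusters)
    census_mod.statuses_to_frame(statuses).to_csv(
        out / "status.tsv", sep="\t", index=False)

    # --- stage: dynamics (target trajectory) ------------------------------------
    round_pools = _target_round_pools(specs, config.target_label)
    if len(round_pools) < 2:
        raise PipelineError(
            f"dynamics: need >= 2 rounds for target {config.target_label!r}")
    round_ids = [s.pool_id for s in round_pools]
    enrich = dynamics_mod.enrichment_table(wide, round_ids,
                                           pseudocount=config.pseudocount)
    enrich.to_csv(out / "enrichment.tsv", sep="\t", float_format="%.6g")

    by_round = {s.round_index: next(c for c in censuses if c.pool_id == s.pool_id)
                for s in round_pools}
    composition = census_mod.round_composition(statuses, by_round, clusters)
    composition.to_csv(out / "composition.tsv", sep="\t", index=False,
                       float_format="%.6g")
    if len(composition) >= 2:
        conv, flagged = dynamics_mod.convergence_report(composition)
        conv.to_csv(out / "convergence.tsv", sep="\t", index=False,
                    float_format="%.6g")

    # --- stage: specificity -----------------------------------------------------
    spec_table = None
    target_final = _latest_pool(specs, config.target_label)
    control_final = _latest_pool(specs, config.control_label) if config.control_label else None
    if control_final:
        spec_table = specificity_mod.specificity_table(
            wide, target_final, control_final,
            adjusted_pool=_latest_pool(specs, config.adjusted_label)
            if config.adjusted_label else None,
            ortholog_pool=_latest_pool(specs, config.ortholog_label)
            if config.ortholog_label else None,
            fold=config.fold, pseudocount=config.pseudocount,
            similarity=config.similarity, depth_normalize=config.depth_normalize)
        spec_table.to_csv(out / "specificity.tsv", sep="\t", float_format="%.6g")

    # --- stage: landscape --------------------------------------------------------
    final_counts = {s: int(wide.at[s, target_final]) for s in wide.index}
    landscape_dir = out / "landscape"
    landscape_dir.mkdir(exist_ok=True)
    top_variant: dict[str, str] = {}
    big = sorted([cl for cl in clusters if len(cl) >= 2],
                 key=lambda cl: (-final_counts.get(cl.founder, 0), cl.founder))
    for cl in big[:config.n_landscape_clusters]:
        if final_counts.get(cl.founder, 0) <= 0:
            continue
        table = landscape_mod.position_profile(
            cl, final_counts, high_fold=config.high_fold, low_fold=config.low_fold)
        table.write(landscape_dir / f"{cl.cluster_id}.tsv")
        cands = landscape_mod.candidate_variants(table, cl, final_counts)
        if not cands.empty:
            top_variant[cl.cluster_id] = cands.iloc[0]["substitution"]

    # --- stage: report -----------------------------------------------------------
    quantifiable = enrich[enrich[round_ids[-1]] >= config.min_report_count]
    if quantifiable.empty:
        raise PipelineError(
            f"report: no sequence reaches {config.min_report_count} copies in the final round")
    ranked = dynamics_mod.rank_candidates(quantifiable, mode="combined")
    report = ranked.copy()
    cluster_of = {m.sequence: cl.cluster_id for cl in clusters for m in cl.members}
    report["cluster_id"] = [cluster_of.get(s, "") for s in report.index]
    report["top_landscape_variant"] = [
        top_variant.get(cluster_of.get(s, ""), "") for s in report.index]
    if spec_table is not None:
        for col in ("pattern", "electrostatic_flag", "cross_species", "excluded"):
            report[col] = spec_table[col].reindex(report.index)
    else:
        report["excluded"] = False
    report.index.name = "sequence"
    report.to_csv(out / "report_full.tsv", sep="\t", float_format="%.6g")
    eligible = ~report["excluded"].astype(bool)
    if "pattern" in report.columns:
        eligible &= report["pattern"] == "target_specific"
    shortlist = report[eligible].head(config.shortlist_size)
    shortlist.to_csv(out / "report.tsv", sep="\t", float_format="%.6g")
    _write_text_report(shortlist, out / "report.txt", config)
    return shortlist


def _write_text_report(shortlist: pd.DataFrame, path: Path, config: RunConfig) -> None:
    lines = [
        f"Candidate shortlist (target: {config.target_label})",
        f"ranked by combined prevalence/enrichment rule; "
        f"{len(shortlist)} candidates after exclusions",
        "",
    ]
    rate_cols = [c for c in shortlist.columns if c.startswith("rate_")]
    last_rate = rate_cols[-1] if rate_cols else None
    for i, (seq, row) in enumerate(shortlist.iterrows(), start=1):
        bits = [f"{i:3d}. {seq}"]
        if last_rate is not None and pd.notna(row[last_rate]):
            bits.append(f"rate={row[last_rate]:.1f}")
        if "pattern" in row.index and isinstance(row["pattern"], str):
            bits.append(row["pattern"])
        if row.get("cross_species") is True:
            bits.append("cross-species")
        if row.get("cluster_id"):
            bits.append(f"cluster={row['cluster_id']}")
        if row.get("top_landscape_variant"):
            bits.append(f"variant={row['top_landscape_variant']}")
        lines.append("  ".join(bits))
    path.write_text("\n".join(lines) + "\n")
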