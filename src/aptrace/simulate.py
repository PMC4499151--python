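"""Generative SELEX simulator.

Produces multi-round, multi-pool selection data with known ground truth, for
validating the analysis pipeline end to end.  The model chains three steps
per round:

* **binding** — each molecule is retained independently with probability
  ``T / (T + Kd) + carrier_term`` (single-site Langmuir isotherm at target
  concentration ``T``, plus nonspecific carrier/background retention),
  capped at 1;
* **amplification** — a stochastic branching PCR: every molecule duplicates
  per cycle with an efficiency that is constant in emulsion mode and
  GC-dependent in open mode (``e = e_base - gc_slope * (GC - 0.5)``,
  clamped), and every newly synthesised base mutates with probability
  ``mu``, founding new derivative species;
* **sequencing** — multinomial read sampling from a pool, emitted as
  ``barcode + flank5 + region + flank3`` FASTQ records with a read-level
  ground-truth table.

Species classes emulate the populations a real selection contains: genuine
binders of graded affinity, nonbinders, carrier (Fc) binders, electrostatic
("charge") binders that light up against a positively charged protein, and
cross-reactive binders recognising both a target and its species ortholog.
Target concentration declines 25% per round, mirroring a typical increasing-
stringency schedule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import product
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .demux import PoolSpec, gc_content, write_pool_sheet

_BASES = "ACGT"
_ALTS = {b: [a for a in _BASES if a != b] for b in _BASES}

#: constant flanks of the N40 library design used as simulator defaults
DEFAULT_FLANK5 = "TCTCGATCTCAGCGAGTCGTCG"
DEFAULT_FLANK3 = "CCCATCCCTCTTCCTCTCTCCC"


@dataclass
class Species:
    """Ground-truth description of one founding library sequence."""

    sequence: str
    affinity_class: str                  # high | medium | low | nonbinder
    kd: float                            # nM, against the primary target
    carrier_affinity: float = 0.0        # additive retention from carrier binding
    charge_binder: bool = False
    cross_kd: Optional[float] = None     # nM against the ortholog, if cross-reactive
    planted_variant_of: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("kd must be > 0")


@dataclass
class SimConfig:
    """Campaign parameters.  Defaults emulate an N40 selection at reduced scale."""

    seed: int
    region_length: int = 40
    n_species: int = 600
    # Binders are rare specials in a random library: few in number and drawn
    # from the low end of the abundance spectrum, so background mass dominates
    # early pools the way it does in a real selection.
    log10_abundance_range: tuple[float, float] = (1.0, 4.0)
    binder_log10_abundance_range: tuple[float, float] = (1.0, 2.0)
    class_fractions: dict = field(default_factory=lambda: {
        "high": 0.02, "medium": 0.04, "low": 0.06, "nonbinder": 0.88})
    kd_ranges: dict = field(default_factory=lambda: {
        "high": (2.0, 20.0), "medium": (20.0, 200.0),
        "low": (200.0, 2000.0), "nonbinder": (1e4, 1e6)})
    carrier_binder_fraction: float = 0.03
    carrier_retention: float = 0.10
    charge_binder_fraction: float = 0.01
    charge_target_retention: float = 0.03   # weak electrostatic binding to protein targets
    charge_adjusted_retention: float = 0.60  # retention against the pH-adjusted control
    cross_reactive_fraction: float = 0.20    # fraction of high-affinity species
    cross_kd_range: tuple[float, float] = (1.5, 5.0)   # planted cross probes bind strongly
    ortholog_null_kd: float = 1e5
    background_retention: float = 0.02
    n_rounds: int = 5
    t0: float = 10.0                         # nM target at round 1
    t_decay: float = 0.75                    # 25% less target each round
    pcr_mode: str = "emulsion"
    pcr_cycles: int = 25
    e_base: float = 0.30
    mu: float = 1e-4                         # per newly synthesised base per cycle
    gc_slope: Optional[float] = None         # None -> calibrated (see calibrate_gc_slope)
    open_template_bias_sd: float = 0.05      # per-template efficiency spread, open mode only
    pool_size: int = 500000                  # molecules carried into each binding step
    reads_per_pool: int = 20000
    branch_round: Optional[int] = None       # ePCR/oPCR arm comparison from this round
    parallel_targets: bool = False           # final round split across 4 pools
    planted_variant: bool = False
    planted_variant_copies: int = 3
    planted_variant_kd_factor: float = 0.3
    target_label: str = "target"
    ortholog_label: str = "ortholog"
    control_label: str = "control"
    adjusted_label: str = "control_pH"

    def __post_init__(self) -> None:
        for name in ("carrier_retention", "charge_target_retention",
                     "charge_adjusted_retention", "background_retention",
                     "e_base", "mu", "t_decay"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def resolved_gc_slope(self) -> float:
        if self.gc_slope is not None:
            return self.gc_slope
        return calibrate_gc_slope(self.e_base, self.pcr_cycles)

    def target_concentration(self, round_index: int) -> float:
        return self.t0 * self.t_decay ** (round_index - 1)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("log10_abundance_range",):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def calibrate_gc_slope(e_base: float, cycles: int, fold: float = 3.0,
                       gc_low: float = 0.2) -> float:
    """Open-mode GC slope giving a sequence at ``gc_low`` GC a ``fold``-times
    larger expected amplification factor than the emulsion arm after ``cycles``
    cycles: solves ``((1 + e_base + slope*(0.5 - gc_low)) / (1 + e_base))**cycles = fold``.
    """
    return (1.0 + e_base) * (fold ** (1.0 / cycles) - 1.0) / (0.5 - gc_low)


def retention_probability(T: float, kd: float, carrier: float = 0.0) -> float:
    """Langmuir retention ``T/(T+Kd)`` plus additive carrier term, capped at 1."""
    return min(T / (T + kd) + carrier, 1.0)


def simulate_binding(
    composition: Mapping[str, int],
    T: float,
    kd: Mapping[str, float] | float,
    carrier: Mapping[str, float] | float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, int]:
    """Binomially thin a pool through one binding step.

    ``kd`` and ``carrier`` may be scalars or per-sequence mappings.  Each
    molecule of sequence ``s`` is retained independently with probability
    ``T/(T + kd[s]) + carrier[s]`` (capped at 1), so the retained count of a
    species is Binomial(count, p) with mean count * p.
    """
    if rng is None:
        raise ValueError("an explicit rng is required for reproducibility")
    retained: dict[str, int] = {}
    for seq in sorted(composition):
        k = kd[seq] if isinstance(kd, Mapping) else kd
        c = carrier[seq] if isinstance(carrier, Mapping) else carrier
        p = retention_probability(T, k, c)
        kept = int(rng.binomial(composition[seq], p))
        if kept:
            retained[seq] = kept
    return retained


def _binomial_thin(composition: Mapping[str, int], retention: Mapping[str, float],
                   rng: np.random.Generator) -> dict[str, int]:
    out: dict[str, int] = {}
    for seq in sorted(composition):
        kept = int(rng.binomial(composition[seq], retention[seq]))
        if kept:
            out[seq] = kept
    return out


def simulate_pcr(
    composition: Mapping[str, int],
    mode: str = "emulsion",
    cycles: int = 25,
    mu: float = 1e-4,
    e_base: float = 0.30,
    gc_slope: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
    origin: Optional[dict[str, str]] = None,
    collect_positions: bool = False,
    min_efficiency: float = 0.02,
    template_bias_sd: float = 0.0,
):
    """Stochastic branching-process PCR with per-base mutation.

    Each cycle, every molecule duplicates with probability equal to its
    efficiency; each newly synthesised molecule carries at least one
    substitution with probability ``1 - (1 - mu)**L``.  Mutant molecules are
    assigned ``1 + Binomial(L-1, mu)`` substituted positions (the exact
    conditional law up to O((L*mu)^2)), at uniform positions and uniform
    alternative bases.  New sequences amplify in subsequent cycles.

    In open (bulk) mode, efficiency is GC-dependent and each template
    additionally draws a fixed per-reaction offset ``Normal(0,
    template_bias_sd)``, modelling sequence-specific bulk-PCR biases beyond
    GC (secondary structure, reannealing competition) that compartmentalised
    emulsion PCR suppresses.

    ``origin``, if given, is updated so each new derivative maps to the root
    founding sequence of its parent.  With ``collect_positions`` the per-
    position count of mutation events is returned alongside the composition.
    """
    if rng is None:
        raise ValueError("an explicit rng is required for reproducibility")
    if mode not in ("emulsion", "open"):
        raise ValueError(f"unknown PCR mode {mode!r}")
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    seqs = sorted(composition)
    counts = [int(composition[s]) for s in seqs]
    index = {s: i for i, s in enumerate(seqs)}
    L = len(seqs[0]) if seqs else 0
    if mode == "open" and gc_slope is None:
        gc_slope = calibrate_gc_slope(e_base, cycles)

    def efficiency(seq: str) -> float:
        if mode == "emulsion":
            return e_base
        bias = rng.normal(0.0, template_bias_sd) if template_bias_sd > 0 else 0.0
        return float(np.clip(e_base - gc_slope * (gc_content(seq) - 0.5) + bias,
                             min_efficiency, 0.999))

    effs = [efficiency(s) for s in seqs]
    p_mut = 1.0 - (1.0 - mu) ** L if L else 0.0
    events = np.zeros(L, dtype=np.int64)
    for _ in range(cycles):
        carr = np.asarray(counts, dtype=np.int64)
        new = rng.binomial(carr, np.asarray(effs, dtype=float))
        nmut = rng.binomial(new, p_mut) if p_mut > 0 else np.zeros_like(new)
        clean = new - nmut
        for i in np.flatnonzero(clean):
            counts[i] += int(clean[i])
        total_mut = int(nmut.sum())
        if total_mut == 0:
            continue
        parent_idx = np.repeat(np.arange(len(nmut)), nmut)
        n_extra = rng.binomial(L - 1, mu, size=total_mut)
        for pi, extra in zip(parent_idx, n_extra):
            s = seqs[pi]
            positions = rng.choice(L, size=1 + int(extra), replace=False)
            b = list(s)
            for pos in positions:
                b[pos] = _ALTS[b[pos]][rng.integers(3)]
                events[pos] += 1
            ms = "".join(b)
            j = index.get(ms)
            if j is None:
                index[ms] = len(seqs)
                seqs.append(ms)
                counts.append(1)
                effs.append(efficiency(ms))
                if origin is not None and ms not in origin:
                    origin[ms] = origin.get(s, s)
            else:
                counts[j] += 1
    out = {s: c for s, c in zip(seqs, counts) if c > 0}
    return (out, events) if collect_positions else out


def downsample_composition(composition: Mapping[str, int], n: int,
                           rng: np.random.Generator) -> dict[str, int]:
    """Draw an aliquot of ``n`` molecules without replacement (hypergeometric)."""
    seqs = sorted(composition)
    counts = np.array([composition[s] for s in seqs], dtype=np.int64)
    total = int(counts.sum())
    if total <= n:
        return dict(composition)
    drawn = rng.multivariate_hypergeometric(counts, n)
    return {s: int(c) for s, c in zip(seqs, drawn) if c > 0}


def sample_census(composition: Mapping[str, int], n_reads: int,
                  rng: np.random.Generator) -> dict[str, int]:
    """Multinomial read sampling from a pool, returned as sequence counts."""
    if n_reads == 0 or not composition:
        return {}
    seqs = sorted(composition)
    counts = np.array([composition[s] for s in seqs], dtype=np.float64)
    p = counts / counts.sum()
    drawn = rng.multinomial(n_reads, p)
    return {s: int(c) for s, c in zip(seqs, drawn) if c > 0}


def simulate_sequencing(
    composition: Mapping[str, int],
    n_reads: int,
    spec: PoolSpec,
    rng: np.random.Generator,
    fastq_path: str | Path,
    origin: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Sample reads from a pool and write them as FASTQ.

    Reads are ``barcode + flank5 + region + flank3`` with uniform top quality
    (no sequencing error by default).  Returns the read-level ground truth
    (read_id, region sequence, founding species, pool).
    """
    if not composition and n_reads > 0:
        raise ValueError("cannot sequence an empty composition")
    drawn = sample_census(composition, n_reads, rng)
    truth_rows = []
    fastq_path = Path(fastq_path)
    import gzip as _gzip
    import io as _io

    def opener(path, mode):
        if not fastq_path.name.endswith(".gz"):
            return open(path, mode)
        # mtime=0 keeps rerun output byte-identical
        return _io.TextIOWrapper(_gzip.GzipFile(path, "wb", mtime=0))

    with opener(fastq_path, "wt") as fh:
        i = 0
        for seq in sorted(drawn):
            for _ in range(drawn[seq]):
                read_id = f"{spec.pool_id}_{i:07d}"
                full = spec.barcode + spec.flank5 + seq + spec.flank3
                fh.write(f"@{read_id}\n{full}\n+\n{'I' * len(full)}\n")
                truth_rows.append({
                    "read_id": read_id,
                    "region": seq,
                    "species": (origin or {}).get(seq, seq),
                    "pool": spec.pool_id,
                })
                i += 1
    return pd.DataFrame(truth_rows,
                        columns=["read_id", "region", "species", "pool"])


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _make_species(config: SimConfig, rng: np.random.Generator
                  ) -> tuple[list[Species], dict[str, int]]:
    """Draw the founding species set and their initial copy numbers."""
    n = config.n_species
    seqs: list[str] = []
    seen = set()
    while len(seqs) < n:
        s = _random_sequence(rng, config.region_length)
        if s not in seen:
            seen.add(s)
            seqs.append(s)
    classes: list[str] = []
    for cls, frac in config.class_fractions.items():
        classes.extend([cls] * int(round(frac * n)))
    while len(classes) < n:
        classes.append("nonbinder")
    classes = classes[:n]
    perm = rng.permutation(n)
    classes = [classes[i] for i in perm]

    species: list[Species] = []
    for s, cls in zip(seqs, classes):
        lo, hi = config.kd_ranges[cls]
        kd = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        species.append(Species(sequence=s, affinity_class=cls, kd=kd))
    high = [sp for sp in species if sp.affinity_class == "high"]
    n_cross = max(1, int(round(config.cross_reactive_fraction * len(high)))) if high else 0
    cross_set = set(id(sp) for sp in high[:n_cross])
    for sp in species:
        if id(sp) in cross_set:
            continue  # planted probes stay free of passenger traits
        if rng.random() < config.carrier_binder_fraction:
            sp.carrier_affinity = config.carrier_retention
        elif rng.random() < config.charge_binder_fraction:
            # disjoint from carrier binders: the pH-shift phenomenon is defined
            # for sequences that do NOT bind the control under normal buffer
            sp.charge_binder = True
    for sp in high[:n_cross]:
        # planted cross-reactive probes: strong, comparable affinity for both
        # orthologs, so the planted phenomenon is observable by design
        sp.kd = float(rng.uniform(*config.cross_kd_range))
        sp.cross_kd = sp.kd * float(rng.uniform(0.7, 1.5))

    copies = {}
    for sp in species:
        rng_range = (config.log10_abundance_range if sp.affinity_class == "nonbinder"
                     else config.binder_log10_abundance_range)
        copies[sp.sequence] = max(1, int(round(10 ** rng.uniform(*rng_range))))
    for sp in species:
        if sp.cross_kd is not None:
            # spike planted probes at the top of the binder abundance band so
            # they cannot be lost to founder-stage drift
            copies[sp.sequence] = max(copies[sp.sequence],
                                      int(round(10 ** config.binder_log10_abundance_range[1])))
        elif sp.charge_binder:
            # electrostatic passengers are unremarkable background members:
            # ordinary sequences that only light up in the pH-shifted buffer
            copies[sp.sequence] = max(1, int(round(10 ** rng.uniform(1.0, 3.0))))

    if config.planted_variant and high:
        founder = max(high, key=lambda sp: copies[sp.sequence])
        pos = int(rng.integers(config.region_length))
        alt = _ALTS[founder.sequence[pos]][int(rng.integers(3))]
        vseq = founder.sequence[:pos] + alt + founder.sequence[pos + 1:]
        variant = Species(
            sequence=vseq, affinity_class="high",
            kd=founder.kd * config.planted_variant_kd_factor,
            planted_variant_of=founder.sequence,
        )
        species.append(variant)
        copies[vseq] = config.planted_variant_copies
    return species, copies


@dataclass
class CampaignResult:
    """Everything a simulated campaign produced, with full ground truth."""

    config: SimConfig
    species: dict[str, Species]
    origin: dict[str, str]                  # any sequence -> founding species sequence
    pools: dict[str, dict[str, int]]        # pool_id -> bound-fraction composition
    pool_info: dict[str, dict]              # pool_id -> {round, target_label, arm}
    initial_composition: dict[str, int]

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for seq in sorted(self.species):
            sp = self.species[seq]
            rows.append({
                "sequence": seq,
                "affinity_class": sp.affinity_class,
                "kd": sp.kd,
                "cross_kd": sp.cross_kd if sp.cross_kd is not None else np.nan,
                "carrier_affinity": sp.carrier_affinity,
                "charge_binder": sp.charge_binder,
                "planted_variant_of": sp.planted_variant_of or "",
                "initial_copies": self.initial_composition.get(seq, 0),
            })
        return pd.DataFrame(rows)


def _retention_map(seqs: Sequence[str], kind: str, T: float, config: SimConfig,
                   species: Mapping[str, Species], origin: Mapping[str, str]
                   ) -> dict[str, float]:
    out = {}
    for s in seqs:
        sp = species[origin.get(s, s)]
        p = config.background_retention + sp.carrier_affinity
        if kind in ("target", "ortholog"):
            kd = sp.kd if kind == "target" else (
                sp.cross_kd if sp.cross_kd is not None else config.ortholog_null_kd)
            p += T / (T + kd)
            if sp.charge_binder:
                p += config.charge_target_retention
        elif kind == "control_ph":
            if sp.charge_binder:
                p += config.charge_adjusted_retention
        elif kind != "control":
            raise ValueError(f"unknown pool kind {kind!r}")
        out[s] = min(p, 1.0)
    return out


def simulate_campaign(config: SimConfig) -> CampaignResult:
    """Run a full multi-round selection campaign.

    Rounds chain bind -> amplify -> aliquot.  Each round's *bound* fraction is
    recorded as a pool (that is what gets sequenced in practice).  Optional
    features: a ``branch_round`` amplifies that round's bound fraction by both
    emulsion and open PCR and carries each arm through one further selection
    round; ``parallel_targets`` splits the final round's library across
    target, ortholog, control and pH-adjusted control pools.
    """
    rng = np.random.default_rng(config.seed)
    species_list, initial = _make_species(config, rng)
    species = {sp.sequence: sp for sp in species_list}
    origin = {s: s for s in species}
    pools: dict[str, dict[str, int]] = {}
    pool_info: dict[str, dict] = {}
    current = dict(initial)

    def record(pool_id: str, comp: dict[str, int], rnd: int, label: str, arm: str):
        pools[pool_id] = comp
        pool_info[pool_id] = {"round": rnd, "target_label": label, "arm": arm}

    for r in range(1, config.n_rounds + 1):
        T = config.target_concentration(r)
        last = r == config.n_rounds
        if last and config.parallel_targets:
            kinds = [("target", config.target_label),
                     ("ortholog", config.ortholog_label),
                     ("control", config.control_label),
                     ("control_ph", config.adjusted_label)]
        else:
            kinds = [("target", config.target_label)]
        bound_main = None
        for kind, label in kinds:
            ret = _retention_map(sorted(current), kind, T, config, species, origin)
            bound = _binomial_thin(current, ret, rng)
            record(f"R{r}_{label}", bound, r, label, "main")
            if kind == "target":
                bound_main = bound
        if config.branch_round == r:
            # Arm comparison: amplify this round's bound fraction by both PCR
            # modes and record each amplified library directly, so the two arm
            # pools differ only in the amplification step.
            for mode, arm in (("emulsion", "epcr"), ("open", "opcr")):
                amp = simulate_pcr(
                    bound_main, mode=mode, cycles=config.pcr_cycles, mu=config.mu,
                    e_base=config.e_base, gc_slope=config.resolved_gc_slope,
                    rng=rng, origin=origin,
                    template_bias_sd=config.open_template_bias_sd)
                aliquot = downsample_composition(amp, config.pool_size, rng)
                record(f"R{r + 1}_{config.target_label}_{arm}", aliquot, r + 1,
                       config.target_label, arm)
        if not last:
            amp = simulate_pcr(
                bound_main, mode=config.pcr_mode, cycles=config.pcr_cycles,
                mu=config.mu, e_base=config.e_base,
                gc_slope=config.resolved_gc_slope, rng=rng, origin=origin,
                template_bias_sd=config.open_template_bias_sd)
            current = downsample_composition(amp, config.pool_size, rng)
    return CampaignResult(
        config=config, species=species, origin=origin,
        pools=pools, pool_info=pool_info, initial_composition=initial)


def _generate_barcodes(n: int, length: int = 6, min_dist: int = 3) -> list[str]:
    """Deterministic barcode set with pairwise Hamming distance >= min_dist."""
    chosen: list[str] = []
    for cand in product(_BASES, repeat=length):
        code = "".join(cand)
        if all(sum(a != b for a, b in zip(code, prev)) >= min_dist for prev in chosen):
            chosen.append(code)
            if len(chosen) == n:
                return chosen
    raise ValueError(f"cannot generate {n} barcodes of length {length}")


def make_pool_specs(result: CampaignResult,
                    flank5: str = DEFAULT_FLANK5,
                    flank3: str = DEFAULT_FLANK3) -> list[PoolSpec]:
    pool_ids = sorted(result.pools)
    barcodes = _generate_barcodes(len(pool_ids))
    specs = []
    for pid, bc in zip(pool_ids, barcodes):
        info = result.pool_info[pid]
        specs.append(PoolSpec(
            pool_id=pid, round_index=info["round"], target_label=info["target_label"],
            barcode=bc, flank5=flank5, flank3=flank3,
            region_length=result.config.region_length))
    return specs


def write_campaign(result: CampaignResult, outdir: str | Path,
                   reads_per_pool: Optional[int] = None,
                   gzip_output: bool = True) -> list[PoolSpec]:
    """Write a campaign to disk: FASTQ per pool, pool sheet, ground truth, config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_reads = reads_per_pool if reads_per_pool is not None else result.config.reads_per_pool
    specs = make_pool_specs(result)
    write_pool_sheet(specs, outdir / "pools.tsv")
    rng = np.random.default_rng([result.config.seed, 7919])
    truth_frames = []
    for spec in specs:
        suffix = ".fastq.gz" if gzip_output else ".fastq"
        truth_frames.append(simulate_sequencing(
            result.pools[spec.pool_id], n_reads, spec, rng,
            outdir / f"{spec.pool_id}{suffix}", origin=result.origin))
    pd.concat(truth_frames, ignore_index=True).to_csv(
        outdir / "reads_truth.tsv", sep="\t", index=False)
    result.truth_frame().to_csv(outdir / "species.tsv", sep="\t", index=False)
    cfg = asdict(result.config)
    cfg["gc_slope_resolved"] = result.config.resolved_gc_slope
    with open(outdir / "config.json", "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True, default=str)
    return specs
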