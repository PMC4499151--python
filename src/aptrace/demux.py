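"""Read handling for multiplexed selection-pool sequencing runs.

A sequencing run covers many pools (selection rounds, parallel targets,
amplification arms).  Each pool is identified by a short barcode at a fixed
offset in the read, and the variable region of the library sits between two
constant flanking sequences.  This module assigns reads to pools and extracts
the variable region, tallying every rejection with a reason code.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd
from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_DNA = frozenset("ACGT")

#: rejection reason codes used by :func:`extract_region`
REASONS = ("flank5_not_found", "flank3_not_found", "bad_region_length", "ambiguous_base")


class ConfigurationError(ValueError):
    """Raised when a pool sheet is internally inconsistent (e.g. ambiguous barcodes)."""


def normalize_sequence(seq: str) -> str:
    """Uppercase and map RNA to the DNA alphabet (U -> T)."""
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass(frozen=True)
class PoolSpec:
    """Description of one sequenced pool.

    Parameters
    ----------
    pool_id :
        Unique short identifier, e.g. ``"R3_hIL10RA"``.
    round_index :
        Selection round the pool was sampled from (0 = naive library).
    target_label :
        The protein the pool was incubated with (``"hIL10RA"``, ``"hIgG"``, ...).
    barcode, flank5, flank3 :
        Pool barcode and the constant flanks surrounding the random region.
    region_length :
        Length of the random region (40 or 20 for the libraries analysed here).
    barcode_offset :
        Read offset at which the barcode is expected (default 0).
    reverse_orientation :
        If true, reads are reverse-complemented before flank search.
    """

    pool_id: str
    round_index: int
    target_label: str
    barcode: str
    flank5: str
    flank3: str
    region_length: int
    barcode_offset: int = 0
    reverse_orientation: bool = False

    def __post_init__(self) -> None:
        for name in ("barcode", "flank5", "flank3"):
            value = normalize_sequence(getattr(self, name))
            object.__setattr__(self, name, value)
            if not set(value) <= _DNA or not value:
                raise ConfigurationError(
                    f"pool {self.pool_id!r}: {name} must be non-empty ACGT, got {value!r}"
                )
        if self.region_length <= 0:
            raise ConfigurationError(f"pool {self.pool_id!r}: region_length must be > 0")
        if self.round_index < 0:
            raise ConfigurationError(f"pool {self.pool_id!r}: round_index must be >= 0")


@dataclass
class Read:
    sequence: str
    quality: Optional[str] = None
    source_file: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty read sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError("quality string length does not match sequence length")


def _open_maybe_gzip(path: Path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_sequences(path: str | Path) -> Iterator[Read]:
    """Stream reads from a FASTQ or FASTA file, gzip-transparent.

    Format is chosen by extension (``.fastq``/``.fq`` -> FASTQ, else FASTA),
    ignoring a trailing ``.gz``.
    """
    path = Path(path)
    stem = path.name[:-3] if path.name.endswith(".gz") else path.name
    fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    with _open_maybe_gzip(path) as handle:
        for rec in SeqIO.parse(handle, fmt):
            qual = None
            if fmt == "fastq":
                qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield Read(sequence=str(rec.seq), quality=qual, source_file=str(path))


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def check_barcode_set(pools: list[PoolSpec], max_barcode_mismatches: int) -> None:
    """Validate that barcodes are mutually distinguishable at the allowed tolerance.

    Requires pairwise distance > 2 * max_barcode_mismatches (compared over the
    shorter barcode's length when lengths differ, which also rejects prefix
    collisions).  Raises :class:`ConfigurationError` before any read is touched.
    """
    ids = [p.pool_id for p in pools]
    if len(set(ids)) != len(ids):
        raise ConfigurationError("pool_ids are not unique")
    for i, a in enumerate(pools):
        for b in pools[i + 1:]:
            if a.barcode_offset != b.barcode_offset:
                continue
            n = min(len(a.barcode), len(b.barcode))
            d = hamming(a.barcode[:n], b.barcode[:n])
            if d <= 2 * max_barcode_mismatches:
                raise ConfigurationError(
                    f"barcodes of pools {a.pool_id!r} and {b.pool_id!r} are ambiguous "
                    f"at {max_barcode_mismatches} allowed mismatch(es)"
                )


def demultiplex(
    reads: Iterable[Read],
    pools: list[PoolSpec],
    max_barcode_mismatches: int = 0,
) -> tuple[dict[str, list[Read]], list[Read]]:
    """Assign each read to the pool whose barcode best matches within tolerance.

    Returns ``(assigned, unassigned)`` where ``assigned`` maps pool_id to the
    reads carrying its barcode.  A read with no barcode within
    ``max_barcode_mismatches``, or tied between two barcodes, goes to
    ``unassigned``.  Every input read lands in exactly one bucket.
    """
    check_barcode_set(pools, max_barcode_mismatches)
    assigned: dict[str, list[Read]] = {p.pool_id: [] for p in pools}
    unassigned: list[Read] = []
    for read in reads:
        seq = normalize_sequence(read.sequence)
        best_d, best_pool, tie = None, None, False
        for p in pools:
            window = seq[p.barcode_offset:p.barcode_offset + len(p.barcode)]
            if len(window) < len(p.barcode):
                continue
            d = hamming(window, p.barcode)
            if best_d is None or d < best_d:
                best_d, best_pool, tie = d, p, False
            elif d == best_d:
                tie = True
        if best_d is not None and best_d <= max_barcode_mismatches and not tie:
            assigned[best_pool.pool_id].append(read)
        else:
            unassigned.append(read)
    return assigned, unassigned


def approx_find(haystack: str, needle: str, max_mismatches: int, start: int = 0) -> Optional[int]:
    """Leftmost position >= start where needle matches with <= max_mismatches substitutions."""
    if max_mismatches == 0:
        pos = haystack.find(needle, start)
        return None if pos < 0 else pos
    n = len(needle)
    for pos in range(start, len(haystack) - n + 1):
        mm = 0
        for a, b in zip(haystack[pos:pos + n], needle):
            if a != b:
                mm += 1
                if mm > max_mismatches:
                    break
        if mm <= max_mismatches:
            return pos
    return None


def extract_region(
    read: Read, spec: PoolSpec, max_flank_mismatches: int = 2
) -> tuple[Optional[str], Optional[str]]:
    """Extract the random region between the constant flanks.

    Returns ``(region, None)`` on success or ``(None, reason)`` where reason is
    one of :data:`REASONS`.  The enclosed region must have exactly
    ``spec.region_length`` bases and contain only ACGT.
    """
    seq = normalize_sequence(read.sequence)
    if spec.reverse_orientation:
        seq = reverse_complement(seq)
    start5 = approx_find(seq, spec.flank5, max_flank_mismatches, start=spec.barcode_offset)
    if start5 is None:
        return None, "flank5_not_found"
    region_start = start5 + len(spec.flank5)
    start3 = approx_find(seq, spec.flank3, max_flank_mismatches, start=region_start)
    if start3 is None:
        return None, "flank3_not_found"
    region = seq[region_start:start3]
    if len(region) != spec.region_length:
        return None, "bad_region_length"
    if not set(region) <= _DNA:
        return None, "ambiguous_base"
    return region, None


def demux_and_extract(
    reads: Iterable[Read],
    pools: list[PoolSpec],
    max_barcode_mismatches: int = 0,
    max_flank_mismatches: int = 2,
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Full read intake: demultiplex, then extract regions per pool.

    Returns the per-pool region lists and a tally table with one row per
    outcome (``assigned``, ``unassigned`` and each rejection reason).
    """
    by_pool, unassigned = demultiplex(reads, pools, max_barcode_mismatches)
    specs = {p.pool_id: p for p in pools}
    regions: dict[str, list[str]] = {p.pool_id: [] for p in pools}
    tally: Counter[str] = Counter()
    tally["unassigned"] = len(unassigned)
    for pool_id, pool_reads in by_pool.items():
        spec = specs[pool_id]
        for read in pool_reads:
            region, reason = extract_region(read, spec, max_flank_mismatches)
            if region is None:
                tally[reason] += 1
            else:
                regions[pool_id].append(region)
                tally["assigned"] += 1
    rows = [{"reason": k, "count": tally[k]}
            for k in ("assigned", "unassigned", *REASONS)]
    return regions, pd.DataFrame(rows)


_SHEET_COLUMNS = {
    "pool_id": "pool_id", "round": "round_index", "round_index": "round_index",
    "target": "target_label", "target_label": "target_label",
    "barcode": "barcode", "flank5": "flank5", "flank3": "flank3",
    "region_length": "region_length", "barcode_offset": "barcode_offset",
    "orientation": "orientation",
}


def read_pool_sheet(path: str | Path) -> list[PoolSpec]:
    """Load pool specifications from a tab-delimited sheet.

    Required columns: pool_id, round, target, barcode, flank5, flank3,
    region_length.  Optional: barcode_offset, orientation ("fwd"/"rev").
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = df.rename(columns={c: _SHEET_COLUMNS[c] for c in df.columns if c in _SHEET_COLUMNS})
    specs = []
    for _, row in df.iterrows():
        specs.append(PoolSpec(
            pool_id=str(row["pool_id"]),
            round_index=int(row["round_index"]),
            target_label=str(row["target_label"]),
            barcode=str(row["barcode"]),
            flank5=str(row["flank5"]),
            flank3=str(row["flank3"]),
            region_length=int(row["region_length"]),
            barcode_offset=int(row.get("barcode_offset", 0) or 0),
            reverse_orientation=str(row.get("orientation", "fwd")).lower().startswith("rev"),
        ))
    check_barcode_set(specs, 0)
    return specs


def write_pool_sheet(specs: list[PoolSpec], path: str | Path) -> None:
    rows = [{
        "pool_id": s.pool_id, "round": s.round_index, "target": s.target_label,
        "barcode": s.barcode, "flank5": s.flank5, "flank3": s.flank3,
        "region_length": s.region_length, "barcode_offset": s.barcode_offset,
        "orientation": "rev" if s.reverse_orientation else "fwd",
    } for s in specs]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
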