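"""Cross-pool specificity screening.

Running aliquots of one library against the target, a control carrier protein
(e.g. the Fc fusion partner), a pH-adjusted control, and a species ortholog
in parallel exposes binding patterns that a single selection cannot: carrier
binders and electrostatically driven binders enrich in control pools, while
genuinely cross-reactive candidates enrich comparably against both orthologs.

The workhorse rule is the ten-fold prevalence ratio: a sequence at least
ten-fold more prevalent in the target pool than in the control pool is
target-specific; ten-fold the other way is control-preferential; anything in
between is shared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

PATTERNS = ("target_specific", "shared", "control_preferential")


def classify_pattern(
    count_target: float,
    count_control: float,
    fold: float = 10.0,
    pseudocount: float = 0.5,
) -> str:
    """Ten-fold-rule classification of a target/control prevalence pair."""
    if count_target < 0 or count_control < 0:
        raise ValueError("counts must be non-negative")
    if fold <= 1:
        raise ValueError("fold must be > 1")
    ratio = (count_target + pseudocount) / (count_control + pseudocount)
    if ratio >= fold:
        return "target_specific"
    if ratio <= 1.0 / fold:
        return "control_preferential"
    return "shared"


def electrostatic_filter(
    count_control_normal: float,
    count_control_adjusted: float,
    fold: float = 10.0,
    pseudocount: float = 0.5,
) -> bool:
    """Flag sequences whose control binding is unmasked by a pH shift.

    When the buffer pH is adjusted so the control protein carries net positive
    charge, sequences binding through electrostatics rather than shape light
    up in the adjusted pool.  Flagged sequences are excluded from candidate
    lists.
    """
    if count_control_normal < 0 or count_control_adjusted < 0:
        raise ValueError("counts must be non-negative")
    ratio = (count_control_adjusted + pseudocount) / (count_control_normal + pseudocount)
    return ratio >= fold


def cross_species_call(
    count_target_a: float,
    count_target_b: float,
    count_control: float,
    fold: float = 10.0,
    pseudocount: float = 0.5,
    similarity: float = 3.0,
) -> tuple[bool, str, str]:
    """Call a sequence cross-reactive between two orthologous targets.

    Cross-species requires target-specific classification against the control
    for *both* targets, and the two target prevalences within a
    ``similarity``-fold band of each other.  Returns
    ``(cross_species, pattern_a, pattern_b)``.
    """
    pattern_a = classify_pattern(count_target_a, count_control, fold, pseudocount)
    pattern_b = classify_pattern(count_target_b, count_control, fold, pseudocount)
    ratio = (count_target_a + pseudocount) / (count_target_b + pseudocount)
    similar = 1.0 / similarity <= ratio <= similarity
    call = pattern_a == "target_specific" and pattern_b == "target_specific" and similar
    return call, pattern_a, pattern_b


def _depth_scaled(census_wide: pd.DataFrame, pools: Sequence[str],
                  mode: str = "auto") -> pd.DataFrame:
    """Rescale pool columns to a common depth when depths differ > 2x.

    ``mode``: "auto" (rescale only on >2x depth imbalance), "always", "never".
    Counts are scaled to the geometric-mean depth so pseudocounts keep a
    count-like magnitude.
    """
    sub = census_wide[list(pools)].astype(float)
    depths = sub.sum(axis=0)
    if mode == "never" or (depths <= 0).any():
        return sub
    imbalance = depths.max() / max(depths.min(), 1.0)
    if mode == "always" or (mode == "auto" and imbalance > 2.0):
        ref = float(np.exp(np.log(depths).mean()))
        return sub * (ref / depths)
    return sub


@dataclass
class SpecificityCall:
    sequence: str
    prevalence_by_pool: dict[str, float]
    pattern: str
    electrostatic_flag: bool = False
    cross_species: bool = False
    excluded: bool = False


def specificity_table(
    census_wide: pd.DataFrame,
    target_pool: str,
    control_pool: str,
    adjusted_pool: Optional[str] = None,
    ortholog_pool: Optional[str] = None,
    extra_control_pools: Sequence[str] = (),
    fold: float = 10.0,
    pseudocount: float = 0.5,
    similarity: float = 3.0,
    depth_normalize: str = "auto",
) -> pd.DataFrame:
    """Classify every sequence of a combined census across parallel pools.

    A sequence is ``excluded`` if it is control-preferential against *any*
    configured control pool or carries the electrostatic flag.  Pool counts
    are depth-rescaled before ratios when pool depths differ more than 2x
    (``depth_normalize="auto"``; also "always"/"never").
    """
    pools = [target_pool, control_pool]
    if adjusted_pool:
        pools.append(adjusted_pool)
    if ortholog_pool:
        pools.append(ortholog_pool)
    pools.extend(extra_control_pools)
    missing = [p for p in pools if p not in census_wide.columns]
    if missing:
        raise KeyError(f"pools not in census table: {missing}")
    scaled = _depth_scaled(census_wide, pools, depth_normalize)
    rows = []
    for seq in scaled.index:
        t = scaled.at[seq, target_pool]
        c = scaled.at[seq, control_pool]
        pattern = classify_pattern(t, c, fold, pseudocount)
        flagged = False
        if adjusted_pool:
            flagged = electrostatic_filter(
                c, scaled.at[seq, adjusted_pool], fold, pseudocount)
        control_pref = pattern == "control_preferential"
        for extra in extra_control_pools:
            if classify_pattern(t, scaled.at[seq, extra], fold,
                                pseudocount) == "control_preferential":
                control_pref = True
        cross = False
        pattern_b = ""
        if ortholog_pool:
            cross, _, pattern_b = cross_species_call(
                t, scaled.at[seq, ortholog_pool], c, fold, pseudocount, similarity)
        row = {
            "sequence": seq,
            **{f"count_{p}": float(scaled.at[seq, p]) for p in pools},
            "pattern": pattern,
            "electrostatic_flag": flagged,
            "cross_species": cross,
            "excluded": flagged or control_pref,
        }
        if ortholog_pool:
            row["ortholog_pattern"] = pattern_b
        rows.append(row)
    return pd.DataFrame(rows).set_index("sequence")
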