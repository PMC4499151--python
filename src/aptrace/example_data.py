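"""Worked-example dataset from a published IL-10RA aptamer selection.

Round-4 and round-5 prevalence counts of representative sequences — core
(founder) sequences of the major clusters, the members of cluster J, and
examples of unclustered and bystander sequences — together with the
enrichment rates as printed in the study's summary table (one-decimal).
These counts serve as documentation examples and validation inputs: the
enrichment-rate, clustering and mutational-landscape code must reproduce the
printed values from the raw counts.

For two cluster-J variants (G7T and G30T) the printed rate does not equal
the raw round-over-round count ratio (1.8 vs 2.6 and 5.1 vs 4.9); those two
rows are listed in :data:`NON_RAW_RATIO_IDS` and excluded from exact checks.
"""

from __future__ import annotations

#: id -> (random-region sequence, R4 count, R5 count, printed enrichment rate)
CORE_SEQUENCES: dict[str, tuple[str, int, int, float]] = {
    "401": ("CCCCCGCATCACGCCGTGGTGCGATTGACACAATTGCAAT", 103513, 421606, 4.1),
    "402": ("TCACAGTCCCGGTGCCGCACTAAAACCCATTGTTGTGCGA", 37630, 149129, 4.0),
    "403": ("TGAGAACTTCTCTCAGTCGGTGGGAGAGTACATCCTAACA", 23423, 6081, 0.3),
    "406": ("TAGACGAGCACTTCTCTCAGTCGCATTCATTATTTAAATT", 16011, 3058, 0.2),
    "407": ("CCCCTTCCAGCGATTACGATCATTGACTCTCAGTCCTGTG", 11789, 4679, 0.4),
    "408": ("ATCGACAGCTCTCAGTCCATTCGAGGAATGTTCATCGATA", 5637, 1738, 0.3),
    "411": ("AGCCATGACGATGTCGTTACGTAGATGCAGAGACTCCTAA", 3961, 6311, 1.6),
    "436": ("TAACACTCGATTCTCCTAGCCCGCTAGAAATTCCCCTCCC", 2513, 76374, 30.4),
    "446": ("AAAGACCGTTTTTTAAAACGCTCAATATACACGACATAAA", 89, 409, 4.6),
    "454": ("TGAATCTCGCGCTCGTTGGTACCCTTAAAATAAAGGCATA", 742, 3147, 4.2),
}

CLUSTER_J_FOUNDER = "AGCCATGACGATGTCGTTACGTAGATGCAGAGACTCCTAA"


def _variant(substitution: str) -> str:
    base, pos, alt = substitution[0], int(substitution[1:-1]), substitution[-1]
    assert CLUSTER_J_FOUNDER[pos - 1] == base
    return CLUSTER_J_FOUNDER[:pos - 1] + alt + CLUSTER_J_FOUNDER[pos:]


#: id -> (sequence, R4 count, R5 count, printed enrichment rate)
CLUSTER_J: dict[str, tuple[str, int, int, float]] = {
    "411-J": (CLUSTER_J_FOUNDER, 3961, 6311, 1.6),
    "411-J-A1G": (_variant("A1G"), 14, 47, 3.4),
    "411-J-G7T": (_variant("G7T"), 14, 25, 2.6),
    "411-J-A19T": (_variant("A19T"), 1, 2, 2.0),
    "411-J-C28T": (_variant("C28T"), 2, 17, 8.5),
    "411-J-G30T": (_variant("G30T"), 9, 46, 4.9),
    "411-J-A39G": (_variant("A39G"), 4, 5, 1.2),
}

#: printed rate is not the raw count ratio for these rows (excluded from exact checks)
NON_RAW_RATIO_IDS = frozenset({"411-J-G7T", "411-J-G30T"})

#: unclustered true aptamers and bystanders (sequence, R4 count, R5 count)
UNCLUSTERED = {
    "1BTCIHHiD": ("TGAAGACTTCTCAGTGCCTCGTCGTACTAAAAACGCAATA", 0, 3),
    "1TJjuBP": ("GCAGCTATCTCACCGAAAGCGTCGCTATATTCGTCGTTAT", 1, 3),
}
BYSTANDERS = (
    ("CTATCGCGGCCGATTGTTTCTGCGGACGATGTTGTCCTCA", 0, 1),
    ("TAGTTTGGGCATGTTTCCCTTGTAGGTGTGAAACCACTTA", 0, 1),
)

#: typical within-cluster per-position substitution-rate band reported for
#: this selection; the lower edge serves as the baseline expectation when a
#: cluster's member list is a curated subset that under-counts its own rate
TYPICAL_SUBSTITUTION_RATE_RANGE = (0.001, 0.005)

def cluster_j_counts(round_index: int) -> dict[str, int]:
    """Counts of the cluster-J members in one round (4 or 5)."""
    idx = {4: 1, 5: 2}[round_index]
    return {seq: vals[idx] for seq, vals in
            ((v[0], v) for v in CLUSTER_J.values())}
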