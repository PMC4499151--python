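"""Within-cluster substitution rates, position profiles and variant ranking."""

import numpy as np
import pytest

from aptrace import example_data
from aptrace.cluster import Cluster, ClusterMember, cluster_pool
from aptrace.landscape import candidate_variants, position_profile, substitution_rate

L = 40
FOUNDER = "ACGT" * 10


def make_cluster(founder, variants):
    members = [ClusterMember(founder, 0)]
    members += [ClusterMember(v, 1 if len(v) == len(founder) else 2) for v in variants]
    return Cluster(cluster_id="C0001", founder=founder, members=members)


def sub(founder, pos, alt):
    return founder[:pos - 1] + alt + founder[pos:]


def cluster_j():
    counts = example_data.cluster_j_counts(5)
    clusters = cluster_pool(counts)
    assert len(clusters) == 1
    return clusters[0], counts


class TestSubstitutionRate:
    def test_printed_formula_on_round_numbers(self):
        # 400 derivative copies over a 10000-copy founder and 40 positions
        variants = [sub(FOUNDER, p, "A" if FOUNDER[p - 1] != "A" else "C")
                    for p in range(1, 5)]
        cluster = make_cluster(FOUNDER, variants)
        counts = {FOUNDER: 10000, **{v: 100 for v in variants}}
        assert substitution_rate(cluster, counts) == pytest.approx(0.001)

    def test_no_derivatives_gives_zero(self):
        cluster = make_cluster(FOUNDER, [])
        assert substitution_rate(cluster, {FOUNDER: 10}) == 0.0

    def test_worked_example_cluster_j_round5(self):
        cluster, counts = cluster_j()
        # 47+25+2+17+46+5 = 142 derivative copies over founder 6311 and L 40
        assert substitution_rate(cluster, counts) == pytest.approx(142 / 252440)

    def test_founder_absent_is_undefined(self):
        cluster = make_cluster(FOUNDER, [])
        assert substitution_rate(cluster, {FOUNDER: 0}) is None

    def test_invariant_under_uniform_scaling(self):
        cluster, counts = cluster_j()
        scaled = {s: 7 * c for s, c in counts.items()}
        assert substitution_rate(cluster, scaled) == pytest.approx(
            substitution_rate(cluster, counts))


class TestPositionProfile:
    def test_uniform_variant_counts_flag_nothing(self):
        variants, counts = [], {FOUNDER: 1000}
        for pos in range(1, L + 1):
            for alt in "ACGT":
                if alt != FOUNDER[pos - 1]:
                    v = sub(FOUNDER, pos, alt)
                    variants.append(v)
                    counts[v] = 5
        table = position_profile(make_cluster(FOUNDER, variants), counts)
        assert (table.per_position["flag"] == "normal").all()
        assert (table.per_position["n_distinct_variants"] == 3).all()

    def test_copy_conservation_including_other_class(self):
        v1 = sub(FOUNDER, 3, "T")
        v2 = sub(sub(FOUNDER, 5, "G"), 9, "G")        # distance 2 -> other
        v3 = FOUNDER[:10] + FOUNDER[11:]              # deletion -> other
        cluster = make_cluster(FOUNDER, [v1, v2, v3])
        counts = {FOUNDER: 500, v1: 7, v2: 3, v3: 2}
        table = position_profile(cluster, counts)
        attributed = int(table.per_position["copies"].sum())
        assert attributed == 7
        assert table.other_copies == 5
        assert attributed + table.other_copies == table.total_derivative_copies

    def test_flags_are_monotone_in_observed_copies(self):
        v = sub(FOUNDER, 1, "G")
        other = sub(FOUNDER, 20, "A")  # second position keeps sigma > 0
        order = {"low": 0, "normal": 1, "high": 2}
        flags = []
        for c in (0, 2, 10, 60, 400):
            counts = {FOUNDER: 1000, v: c, other: 30}
            table = position_profile(make_cluster(FOUNDER, [v, other]), counts)
            flags.append(table.per_position.set_index("position").at[1, "flag"])
        levels = [order[f] for f in flags]
        assert levels == sorted(levels)
        assert flags[0] == "low" and flags[-1] == "high"

    def test_worked_example_position_flags(self):
        """Position 1 (A1G, 47 copies) is flagged high and position 19 (A19T,
        2 copies) low, against the selection's typical per-position rate."""
        cluster, counts = cluster_j()
        baseline = example_data.TYPICAL_SUBSTITUTION_RATE_RANGE[0]
        table = position_profile(cluster, counts, expected_rate=baseline)
        flags = table.per_position.set_index("position")["flag"]
        assert flags[1] == "high"
        assert flags[19] == "low"
        assert flags[30] == "high"   # G30T, 46 copies
        assert flags[28] == "normal"  # C28T sits at the typical rate

    def test_founder_absent_raises(self):
        with pytest.raises(ValueError):
            position_profile(make_cluster(FOUNDER, []), {FOUNDER: 0})


class TestCandidateVariants:
    def test_worked_example_a1g_ranked_first(self):
        cluster, counts = cluster_j()
        table = position_profile(
            cluster, counts,
            expected_rate=example_data.TYPICAL_SUBSTITUTION_RATE_RANGE[0])
        ranked = candidate_variants(table, cluster, counts)
        assert ranked.iloc[0]["substitution"] == "A1G"

    def test_no_high_positions_gives_empty_list(self):
        v = sub(FOUNDER, 2, "G")
        cluster = make_cluster(FOUNDER, [v])
        counts = {FOUNDER: 100, v: 1}
        table = position_profile(cluster, counts, expected_rate=0.01)
        assert candidate_variants(table, cluster, counts).empty

    def test_fully_mutable_positions_are_downranked(self):
        v_single = sub(FOUNDER, 1, "G")
        v_multi = [sub(FOUNDER, 5, alt) for alt in "CGT"]
        cluster = make_cluster(FOUNDER, [v_single] + v_multi)
        counts = {FOUNDER: 1000, v_single: 40,
                  v_multi[0]: 20, v_multi[1]: 15, v_multi[2]: 14}
        table = position_profile(cluster, counts, expected_rate=2e-4)
        ranked = candidate_variants(table, cluster, counts)
        assert ranked.iloc[0]["sequence"] == v_single
        assert not ranked.iloc[0]["downranked"]
        assert ranked[ranked["position"] == 5]["downranked"].all()


class TestPlantedVariantRecovery:
    def test_planted_high_fitness_variant_ranks_top3(self):
        """A variant planted with improved affinity ends up flagged high and
        within the top-3 proposed candidates in >= 90% of replicates."""
        from aptrace.census import PoolCensus, combine_censuses
        from aptrace.simulate import SimConfig, sample_census, simulate_campaign

        hits = 0
        seeds = range(1, 21)
        for seed in seeds:
            config = SimConfig(seed=seed, n_rounds=3, planted_variant=True)
            result = simulate_campaign(config)
            founder = next(sp.planted_variant_of
                           for sp in result.species.values() if sp.planted_variant_of)
            variant = next(s for s, sp in result.species.items()
                           if sp.planted_variant_of)
            rng = np.random.default_rng(seed + 500)
            census = sample_census(result.pools["R3_target"], 100000, rng)
            wide = combine_censuses([PoolCensus("R3", census)])
            wide = wide[wide["R3"] >= 2]
            clusters = cluster_pool(wide)
            cl = next((c for c in clusters if founder in c.sequences), None)
            if cl is None or cl.founder != founder:
                continue
            counts = {s: int(census.get(s, 0)) for s in cl.sequences}
            table = position_profile(cl, counts)
            ranked = candidate_variants(table, cl, counts)
            if variant in ranked.head(3)["sequence"].tolist():
                hits += 1
        assert hits >= 0.9 * len(seeds)
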