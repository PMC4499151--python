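"""Generative model checks: binding, PCR, sequencing, campaign properties."""

import numpy as np
import pytest
from scipy import stats

from aptrace.demux import PoolSpec, gc_content
from aptrace.simulate import (
    SimConfig,
    calibrate_gc_slope,
    downsample_composition,
    retention_probability,
    sample_census,
    simulate_binding,
    simulate_campaign,
    simulate_pcr,
    simulate_sequencing,
)


class TestBinding:
    def test_langmuir_midpoint(self):
        assert retention_probability(T=5.0, kd=5.0) == pytest.approx(0.5)

    def test_huge_kd_without_carrier_retains_nothing(self):
        assert retention_probability(T=5.0, kd=1e12) == pytest.approx(0.0, abs=1e-9)

    def test_carrier_term_is_additive_and_capped(self):
        assert retention_probability(5.0, 5.0, carrier=0.2) == pytest.approx(0.7)
        assert retention_probability(5.0, 1e-9, carrier=0.5) == 1.0

    def test_retained_counts_match_binomial_expectation(self):
        rng = np.random.default_rng(0)
        n_species, n_mol = 200, 100000
        seqs = {"".join("ACGT"[b] for b in rng.integers(0, 4, size=40))
                for _ in range(n_species)}
        comp = {s: n_mol // n_species for s in seqs}
        kd = {s: float(10 ** (i % 5)) for i, s in enumerate(sorted(seqs))}
        retained = simulate_binding(comp, T=10.0, kd=kd, rng=rng)
        within = 0
        for s in sorted(comp):
            p = retention_probability(10.0, kd[s])
            mean = comp[s] * p
            sd = np.sqrt(comp[s] * p * (1 - p))
            if abs(retained.get(s, 0) - mean) <= 3 * max(sd, 1e-9):
                within += 1
        # ~1% of species are expected outside 3 sigma by chance
        assert within >= 0.97 * len(comp)

    def test_retained_never_exceeds_input(self):
        rng = np.random.default_rng(1)
        comp = {"ACGT" * 10: 500, "TTTT" * 10: 100}
        retained = simulate_binding(comp, T=100.0, kd=1.0, carrier=0.5, rng=rng)
        assert all(retained[s] <= comp[s] for s in retained)


class TestPcr:
    def test_zero_mutation_rate_creates_no_new_sequences(self):
        rng = np.random.default_rng(2)
        comp = {"ACGT" * 10: 1000, "TGCA" * 10: 1000}
        out = simulate_pcr(comp, mode="emulsion", cycles=10, mu=0.0,
                           e_base=0.5, rng=rng)
        assert set(out) == set(comp)
        # emulsion: one shared expected amplification factor
        factors = [out[s] / comp[s] for s in comp]
        assert all(abs(f - 1.5 ** 10) / 1.5 ** 10 < 0.15 for f in factors)

    def test_open_mode_favours_low_gc(self):
        rng = np.random.default_rng(3)
        mid_low = "A" * 10 + "ACGT" * 5 + "T" * 10   # GC 0.25
        mid_high = "G" * 10 + "ACGT" * 5 + "C" * 10  # GC 0.75
        comp = {mid_low: 5000, mid_high: 5000}
        out = simulate_pcr(comp, mode="open", cycles=10, mu=0.0, e_base=0.3,
                           rng=rng)
        assert out[mid_low] > out[mid_high]

    def test_low_gc_open_amplification_is_three_fold_of_emulsion(self):
        """Calibration: a 0.2-GC sequence amplifies ~3x more in the open arm
        than any sequence does in the emulsion arm."""
        seq = "A" * 16 + "GCGCGCGC" + "T" * 16  # 8 GC of 40 = 0.2
        assert gc_content(seq) == pytest.approx(0.2)
        cycles, e_base = 25, 0.30
        rng = np.random.default_rng(4)
        n0 = 20000
        open_out = simulate_pcr({seq: n0}, mode="open", cycles=cycles, mu=0.0,
                                e_base=e_base, rng=rng)
        emul_out = simulate_pcr({seq: n0}, mode="emulsion", cycles=cycles, mu=0.0,
                                e_base=e_base, rng=rng)
        ratio = open_out[seq] / emul_out[seq]
        assert ratio == pytest.approx(3.0, rel=0.1)

    def test_mutation_positions_follow_branching_expectation(self):
        """Mutation events land uniformly across positions (chi-square) and
        the event total matches the branching-process mean within 3 sigma."""
        rng = np.random.default_rng(5)
        founder = "ACGT" * 10
        n0, cycles, mu, e = 2000, 20, 1e-3, 0.05
        out, events = simulate_pcr({founder: n0}, mode="emulsion", cycles=cycles,
                                   mu=mu, e_base=e, rng=rng, collect_positions=True)
        total = int(events.sum())
        # expected events: sum over cycles of E[new molecules] * L * mu
        expected_new = sum(n0 * (1 + e) ** (t - 1) * e for t in range(1, cycles + 1))
        expected_events = expected_new * 40 * mu
        assert abs(total - expected_events) <= 3 * np.sqrt(expected_events)
        chi = stats.chisquare(events)
        assert chi.pvalue > 0.01
        assert len(out) > 1  # derivative species exist

    def test_derivatives_inherit_root_origin(self):
        rng = np.random.default_rng(6)
        founder = "ACGT" * 10
        origin = {founder: founder}
        out = simulate_pcr({founder: 5000}, cycles=10, mu=1e-3, e_base=0.3,
                           rng=rng, origin=origin)
        assert all(origin[s] == founder for s in out)

    def test_requires_rng_and_valid_mode(self):
        with pytest.raises(ValueError):
            simulate_pcr({"ACGT": 1}, rng=None)
        with pytest.raises(ValueError):
            simulate_pcr({"ACGT": 1}, mode="nested", rng=np.random.default_rng(0))


class TestSequencingAndSampling:
    def spec(self):
        return PoolSpec(pool_id="P", round_index=1, target_label="t",
                        barcode="ACACAC", flank5="TCTCGATCTCAGCGAGTCGTCG",
                        flank3="CCCATCCCTCTTCCTCTCTCCC", region_length=8)

    def test_zero_reads_writes_empty_fastq(self, tmp_path):
        truth = simulate_sequencing({"ACGTACGT": 5}, 0, self.spec(),
                                    np.random.default_rng(0), tmp_path / "x.fastq")
        assert truth.empty
        assert (tmp_path / "x.fastq").read_text() == ""

    def test_single_species_reads_are_identical(self, tmp_path):
        truth = simulate_sequencing({"ACGTACGT": 5}, 20, self.spec(),
                                    np.random.default_rng(0), tmp_path / "x.fastq")
        assert (truth["region"] == "ACGTACGT").all()
        lines = (tmp_path / "x.fastq").read_text().splitlines()
        assert len(lines) == 80
        assert all(l == lines[1] for l in lines[1::4])

    def test_sampled_counts_match_multinomial_expectation(self):
        rng = np.random.default_rng(7)
        comp = {"AAAA": 5000, "CCCC": 3000, "GGGG": 2000}
        n = 10000
        drawn = sample_census(comp, n, rng)
        for s, c in comp.items():
            p = c / 10000
            sd = np.sqrt(n * p * (1 - p))
            assert abs(drawn.get(s, 0) - n * p) <= 3 * sd

    def test_downsampling_is_exact_without_replacement(self):
        rng = np.random.default_rng(8)
        comp = {"AAAA": 60, "CCCC": 40}
        sub = downsample_composition(comp, 50, rng)
        assert sum(sub.values()) == 50
        assert all(sub[s] <= comp[s] for s in sub)


class TestCampaign:
    def test_seeded_rerun_is_identical(self):
        config = SimConfig(seed=123, n_rounds=2, n_species=150,
                           parallel_targets=True)
        a = simulate_campaign(config)
        b = simulate_campaign(config)
        assert a.pools == b.pools
        assert a.truth_frame().equals(b.truth_frame())

    def test_bound_pools_never_exceed_inputs(self):
        config = SimConfig(seed=5, n_rounds=2, n_species=150)
        result = simulate_campaign(config)
        total_initial = sum(result.initial_composition.values())
        assert sum(result.pools["R1_target"].values()) <= total_initial

    def test_high_affinity_species_enrich_faster_than_nonbinders(self):
        """Across replicates, mean round-over-round enrichment of planted
        high-affinity binders exceeds that of plain nonbinders."""
        wins = 0
        for seed in range(1, 6):
            config = SimConfig(seed=seed, n_rounds=3, n_species=200)
            result = simulate_campaign(config)
            c2, c3 = result.pools["R2_target"], result.pools["R3_target"]
            rates = {"high": [], "nonbinder": []}
            for seq, sp in result.species.items():
                if sp.affinity_class not in rates or sp.carrier_affinity > 0 \
                        or sp.charge_binder:
                    continue
                prev = c2.get(seq, 0)
                if prev >= 5:
                    rates[sp.affinity_class].append(c3.get(seq, 0) / prev)
            if rates["high"] and rates["nonbinder"]:
                wins += np.mean(rates["high"]) > np.mean(rates["nonbinder"])
        assert wins == 5

    def test_campaign_writes_are_deterministic(self, tmp_path):
        import hashlib
        from aptrace.simulate import write_campaign
        config = SimConfig(seed=77, n_rounds=2, n_species=100)
        digests = []
        for name in ("a", "b"):
            out = tmp_path / name
            write_campaign(simulate_campaign(config), out, reads_per_pool=1000)
            digest = {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                      for p in out.iterdir()}
            digests.append(digest)
        assert digests[0] == digests[1]

    def test_gc_slope_calibration_closed_form(self):
        e, c = 0.3, 25
        slope = calibrate_gc_slope(e, c)
        lhs = ((1 + e + slope * 0.3) / (1 + e)) ** c
        assert lhs == pytest.approx(3.0)
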