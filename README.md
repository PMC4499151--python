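# aptrace

Analysis toolkit for high-throughput-sequencing-guided SELEX (HTS-SELEX):
from multiplexed FASTQ reads of selection-round pools to ranked,
specificity-annotated, mutationally profiled aptamer candidates — plus a
generative simulator of the whole selection process for validating every
stage against known ground truth.

## The problem

In vitro selection (SELEX) evolves an oligonucleotide library against a
protein target through repeated rounds of binding, partitioning and PCR
amplification. Deep sequencing of the intermediate pools turns candidate
discovery into a data-analysis problem, but raw prevalence is a poor guide:
PCR bias, carrier-protein binders and electrostatic passengers all inflate
sequences that never bind the intended target. `aptrace` implements the
screening strategy that addresses this:

* **Demultiplexing and region extraction** (`aptrace.demux`) — reads are
  assigned to pools by barcode and the random region is cut out between the
  constant flanks, with per-reason rejection tallies.
* **Pool census** (`aptrace.census`) — exact per-pool prevalence of every
  unique sequence; sequences are classified as *bystanders* (one copy in the
  whole dataset), *unclustered* true aptamers, or *clustered* true aptamers.
* **Clustering** (`aptrace.cluster`) — greedy, abundance-ordered grouping of
  mutant families: the most abundant unassigned sequence founds a cluster
  and absorbs every sequence within Levenshtein distance ≤ 3, with a k-mer
  profile prefilter (admission bound `L1 ≤ 2·k·d`) that can never exclude a
  true neighbour.
* **Enrichment dynamics** (`aptrace.dynamics`) — the round-over-round
  prevalence ratio (enrichment rate) per sequence, candidate ranking by
  prevalence, enrichment or the worse-of-both-ranks combination, GC-binned
  amplification-bias comparison between emulsion and open PCR arms,
  gained/lost diversity accounting, and detection of selection convergence
  (cluster count falls while mean cluster size keeps rising).
* **Specificity screening** (`aptrace.specificity`) — the ten-fold rule on
  prevalences across parallel pools (target vs control carrier protein)
  classifies sequences as target-specific, shared or control-preferential;
  a pH-adjusted control pool exposes electrostatic binders; comparable
  enrichment against a species ortholog calls cross-species candidates.
* **Mutational landscape** (`aptrace.landscape`) — within a cluster, the
  substitution rate σ = (derivative copies) / (founder copies × L) and a
  per-position profile flag positions mutated above (3×) or below (1/3×)
  expectation; abundant variants at high-flagged positions are proposed as
  affinity-improving candidates.
* **Simulator** (`aptrace.simulate`) — a generative SELEX model (Langmuir
  binding, branching-process PCR with per-base mutation and GC-dependent
  open-PCR bias, multinomial sequencing) that emits FASTQ plus ground truth,
  so the full pipeline can be validated end to end.
* **Pipeline** (`aptrace.pipeline`, CLI `aptrace`) — orchestrates all stages
  with TSV checkpoints and a final annotated candidate shortlist;
  deterministic given inputs and config.

## Worked example

The package ships the prevalence counts of representative sequences from a
published IL-10RA selection (`aptrace.example_data`): the core sequences of
the major clusters and the members of cluster J, at rounds 4 and 5.

```python
from aptrace import cluster_pool, enrichment_rate, position_profile, substitution_rate
from aptrace.dynamics import round_rate
from aptrace.example_data import TYPICAL_SUBSTITUTION_RATE_RANGE, cluster_j_counts

# enrichment rate of the top riser in the worked example (sequence 436)
print("rate 436:", round_rate(enrichment_rate(2513, 76374)))

# cluster the seven published cluster-J members by their round-5 counts
counts = cluster_j_counts(5)
(cluster,) = cluster_pool(counts)
print("founder:", cluster.founder[:12] + "...", "members:", len(cluster))
print("sigma:", f"{substitution_rate(cluster, counts):.2e}")

table = position_profile(cluster, counts,
                         expected_rate=TYPICAL_SUBSTITUTION_RATE_RANGE[0])
flagged = table.per_position.query("flag != 'normal' and copies > 0")
print(flagged[["position", "founder_base", "copies", "flag"]].to_string(index=False))
```

prints

```
rate 436: 30.4
founder: AGCCATGACGAT... members: 7
sigma: 5.63e-04
 position founder_base  copies flag
        1            A      47 high
        7            G      25 high
       19            A       2  low
       30            G      46 high
```

Sequence 436 rose 2 513 → 76 374 copies between rounds (rate 30.4), the
seven cluster-J sequences form a single mutant family around their most
abundant member, and positions 1 and 30 carry far more variant copies than
the per-position expectation — those variants (A1G, G30T) are the ones to
synthesise and test — while position 19 is barely mutable, marking a
"cornerstone" position that should not be altered during optimisation.

A full in-silico campaign, from FASTQ to shortlist:

```
aptrace simulate --config sim.yaml --out simdata/
aptrace run --config run.yaml
```

where `sim.yaml` sets simulator parameters (`seed` is required) and
`run.yaml` points the pipeline at `simdata/pools.tsv` and the FASTQ files.
Individual stages are available as `aptrace demux / census / cluster /
dynamics / diversity / converge / specificity / landscape`.

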