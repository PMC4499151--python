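# Methods

This note documents the models, rules and numerical choices behind
`aptrace`: what each stage computes, what the synthetic-data generator does
and does not emulate, and where genuinely open design decisions were made.

## Read intake

Reads are assigned to pools by matching each pool's barcode at a fixed read
offset (default 0); the best match within `max_barcode_mismatches`
(default 0) wins, ties and out-of-tolerance reads go to an `unassigned`
bucket. Before any read is touched the barcode set is validated: every pair
must differ by more than `2 × max_barcode_mismatches` (compared over the
shorter barcode when lengths differ), otherwise assignment would be
ambiguous by construction. All sequence input is normalised to the DNA
alphabet (U→T, uppercase), because the selection alternates RNA and cDNA
and every downstream comparison is alphabet-agnostic; pools sequenced in
reverse orientation declare it and are reverse-complemented before flank
search.

The random region is the subsequence between the leftmost approximate
occurrence of the 5′ constant flank (≤ `max_flank_mismatches`
substitutions, default 2) and the leftmost occurrence of the 3′ flank after
it. A read is rejected — and tallied under a reason code — if either flank
is missing, the enclosed region length differs from the library design
(40 nt or 20 nt here), or the region contains an ambiguous base. Paired-end
merging, quality trimming and adapter discovery are out of scope; the
input is assumed to be one consolidated read stream.

## Census and sequence status

A pool census is the exact multiset count of unique regions
("prevalence"), independent of read order. Across all pools of a dataset,
a sequence seen exactly once is a *bystander* (unselected background); any
sequence with more copies, or present in several pools, is a *true
aptamer*. With a clustering result, true aptamers in a family of ≥ 2
members are *clustered*; members of singleton clusters count as
unclustered, since a family of one is no evidence of a mutant cloud.
Round-composition fractions are computed over unique sequences, not reads:
bystanders are single-read by definition, so read-weighted fractions would
be uninformative.

## Clustering

Mutant families arise from polymerase errors during inter-round
amplification, so members sit within a small edit distance of the abundant
founding sequence. Clustering is greedy and founder-first: sequences are
processed in descending total copy number (ties lexicographic, for
determinism); each seed absorbs every unassigned sequence within unit-cost
Levenshtein distance ≤ 3 *of the founder* (not transitively — this matches
the founder-plus-variants structure the landscape analysis consumes, and
whether the distance rule should chain between members is genuinely
undecidable from the family definition alone). Edit distances are computed
with `edlib`.

Candidates are prefiltered before the exact distance call. One edit
operation changes at most k of a sequence's overlapping k-mers, so a pair
at edit distance ≤ d differs by at most `2·k·d` in L1 distance between
k-mer count vectors; with the defaults k = 4, d = 3 the admission
threshold is 24 and the filter provably never excludes a true member. A
4-dimensional base-composition check (bound `2·d`) and a length check run
first because they are nearly free. Tests assert filter-on/filter-off
equivalence against an independent all-pairs dynamic-programming oracle.

## Enrichment dynamics

The enrichment rate of a sequence between consecutive rounds is the plain
ratio of its raw counts; the worked-example table reproduces exactly under
this definition (rates are presented rounded to one decimal, Python
round-half-to-even). Two printed rows (G7T, G30T of cluster J) do not equal
their raw-count ratio under any rounding and are excluded from exact
checks. For sequences absent in the earlier round a pseudocount (default
0.5) regularises the rate to `(count + 0.5) / 0.5`, preserving order while
avoiding infinities; depth-normalised (reads-per-million) rates are
available by flag for pools of unequal depth. Both counts zero means the
rate is undefined and is reported missing.

Ranking modes: by final-round prevalence, by last-transition rate, or
*combined* — each sequence is scored by the worse (max) of its two
individual ranks, so a leader must do well on both; ties break by
prevalence. Because pseudocount rates of newly detected singletons would
otherwise dominate the rate ranking, the pipeline ranks only sequences
with at least `min_report_count` (default 5) copies in the final round —
the rate of a sequence with no quantifiable denominator is not evidence.

Diversity accounting between an earlier and a later pool is set algebra on
census keys (`n_prior`, `n_lost`, `n_new`, net change), with a second
variant restricted to prior sequences at or below a copy-number cutoff
(default 100) — the population most vulnerable to amplification dropout.
Convergence is flagged at the first round where the number of clusters
falls while mean cluster size keeps rising: the signature of selection
turning competitive.

## Specificity screening

The ten-fold rule compares pseudocounted prevalences between the target
pool and a control pool: ratio ≥ 10 → target-specific, ≤ 1/10 →
control-preferential, otherwise shared. The rule is antisymmetric under
pool swap and monotone in the target count (property-tested on the
exhaustive 0–1000 count grid). When pool depths differ by more than 2×,
counts are first rescaled to the geometric-mean depth so the pseudocount
keeps a count-like magnitude.

Electrostatic binders are exposed by a control pool incubated at a pH
where the control protein carries net positive charge: a sequence ≥ 10-fold
more prevalent in the adjusted pool than in the normal-pH control pool is
flagged and excluded. The quantitative threshold is a package choice (the
screening idea fixes the comparison, not the number); it deliberately
mirrors the ten-fold pattern rule.

A sequence is called cross-species when it classifies target-specific
against the control for *both* a target and its ortholog and its two
target-pool prevalences agree within a 3-fold band ("similar prevalence"
needs a number; 3 is the package default). Exclusion is composable: a
sequence flagged against any configured control is dropped from candidate
lists.

An important regime note: prevalence-share ratios between bound pools are
compressed by the ratio of pool mean retentions. When a library is already
dominated by binder mass, target-pool shares flatten and the ten-fold rule
loses its separation. The screen therefore belongs early in a selection,
while background mass still dominates both pools — the pipeline and the
simulator's validation campaigns run it on a round-2 split for this
reason.

## Mutational landscape

For a cluster in a pool, the substitution rate is

    σ = (total copies of all derivative members) / (founder copies × L)

with L the random-region length (40). Copies of each single-substitution
variant are attributed to its position and alternative base; members at
edit distance 2–3 or with indels join an "other" class that contributes to
σ but to no position (attributed + other = total derivative copies, a
tested conservation). Under a uniform-error null every position expects
`founder_copies × σ` derivative copies; a position is flagged *high* at
≥ 3× expectation and *low* at ≤ 1/3× (defaults). A one-sided Poisson tail
probability (mean = expected copies) is reported alongside at α = 0.01 as
a convenience statistic; the flags themselves are the fold rule.

`expected_rate` can override the cluster's own σ as the expectation. This
matters when the member list is a curated subset: the worked-example
cluster-J table lists only 6 representative variants, so its apparent σ
(5.6×10⁻⁴) under-counts the full cluster's rate. Profiling that subset
against the selection's typical per-position rate band (0.001–0.005;
`example_data.TYPICAL_SUBSTITUTION_RATE_RANGE`, lower edge used as the
baseline) recovers the expected picture: positions 1 and 30 high,
position 19 low. Note the two published phrasings of the typical rate
("0.001–0.005 at each position" vs "10–50 variants per 10 000 founder
copies") are not mutually consistent under the printed formula; the
formula as printed is implemented and the σ values the simulator produces
(~0.001–0.005) match the per-position phrasing.

Candidate variants for affinity testing are the single-substitution
variants at high-flagged positions, ranked by copy number; variants at
positions where all three alternative bases occur are down-ranked, since
uniformly mutable positions behave like neutral sites.

## The simulator

The generator produces multi-round, multi-pool campaigns with full ground
truth. Its purpose is validation: every phenomenon the analysis claims to
detect is planted with known labels.

**Binding.** Each molecule is retained independently with probability
`T/(T + Kd) + carrier + background`, capped at 1 — the single-site
Langmuir isotherm (consistent with Kd defined as the protein concentration
retaining half the RNA) plus additive nonspecific terms. Target
concentration starts at `t0 = 10` nM (an effective availability for the
scaled-down pools, not a literal bead loading) and declines 25% per round.
Background bead retention is 0.02.

**Species classes.** Sequences are random 40-mers. Binders are rare
specials, as in a real random library: 2% high-affinity (Kd 2–20 nM), 4%
medium (20–200), 6% low (200–2000), 88% nonbinders (10⁴–10⁶), with binder
initial copies drawn from the low end (10–100) of the log-uniform
abundance spectrum (10–10⁴ for background). This keeps background mass
dominant in early pools — the regime in which reference-pool screening is
informative (see above); with binder-heavy toy libraries the prevalence
ratios compress and no screen can work, which is a property of
compositional data, not of the code. Passenger classes: 3% carrier (Fc)
binders (additive retention 0.10 in every protein pool), 1% electrostatic
binders (weak +0.03 in protein pools, +0.60 in the pH-adjusted control
pool; disjoint from carrier binders, since the pH-shift phenomenon is
defined for sequences that do not bind the control under normal buffer).
Planted ground-truth probes are made observable by design: cross-reactive
probes (20% of the high class, ≥ 1) get strong, similar affinities for
both orthologs (Kd 1.5–5 nM, ortholog Kd within 0.7–1.5×) and top-of-band
initial copies; the optional planted high-fitness variant starts at 3
copies one substitution away from the most abundant high-affinity founder
with 0.3× its Kd.

**PCR.** A stochastic branching process: per cycle each molecule
duplicates with its efficiency; every newly synthesised molecule mutates
with probability `1 − (1 − μ)^L` (μ = 10⁻⁴ per base per cycle, Taq-like),
carrying `1 + Binomial(L−1, μ)` substitutions at uniform positions and
bases — the exact conditional law to O((Lμ)²). New sequences amplify in
subsequent cycles and inherit their root founder for ground-truth
bookkeeping. Emulsion mode amplifies uniformly (efficiency `e_base` = 0.30
over 25 cycles; the compartmentalisation that produces this uniformity is
not modelled, only its measured consequence). Open (bulk) mode is biased
two ways: a GC-dependent efficiency `e = e_base − slope·(GC − 0.5)`, with
the slope calibrated so a 0.2-GC sequence's expected amplification factor
is 3× the emulsion arm's after the configured cycles, and a per-template
efficiency offset `Normal(0, 0.05)` drawn once per reaction, representing
sequence-specific bulk-PCR biases beyond GC (structure, reannealing
competition) that compartmentalisation suppresses. The GC slope alone,
acting on the narrow GC spread of a random 40-mer library (sd ≈ 0.08),
cannot reproduce the large rare-sequence dropout that bulk PCR shows; the
template-bias term is what carries that phenomenon. Analyses that read
out the GC response in isolation disable it.

**Sequencing and scale.** Pools are downsampled between stages by
hypergeometric aliquoting (`pool_size` = 5×10⁵ molecules into each
binding step) and sequenced by multinomial read sampling
(`reads_per_pool` = 2×10⁴ by default; validation analyses use 10⁵). Reads
are emitted as `barcode + flank5 + region + flank3` with the N40 library's
constant flanks, uniform top quality and no sequencing error by default
(region-extraction exactness is tested separately); barcodes are a
deterministic length-6 set at pairwise Hamming distance ≥ 3. Campaign
writes are byte-stable (gzip mtime pinned) and fully reproducible from the
seed.

**What the simulator does not emulate.** Real library scale (~10¹⁴
molecules vs ~10⁶ here — binder frequencies are inflated accordingly),
secondary-structure-dependent binding, reverse-transcription bias, droplet
occupancy statistics, sequencing error, and chimeric PCR products. Passing
tests therefore show the analysis recovers planted truths under this
generative model, not that the model exhausts real data's failure modes.

## Validation problem sizes

The test suite and acceptance script run the simulator at reduced scale,
chosen to keep the full suite in minutes on one CPU while leaving the
measured properties far from their thresholds: 600 species, 2–3 rounds,
5×10⁵-molecule pools, 10⁵-read censuses; 12–30 replicates per property
(20 for the affinity–enrichment correlation, 20 for arm-loss comparisons,
30 for screening sensitivities, 20 for planted-variant recovery). Observed
values at these sizes: mean Spearman(−log Kd, enrichment rate) ≈ 0.85 over
screened candidates; charge-binder flag sensitivity ≈ 95–98% over members
with ≥ 10 reads in the adjusted pool (members extinct before the screen
cannot be flagged by any method); cross-species call sensitivity 100% with
no false calls among single-target high binders; open-arm low-abundance
loss exceeds the emulsion arm's in every replicate (≈ 15–20% vs ≈ 7%).

## Known limitations

* Founder-anchored membership means a variant at distance 4 from the
  founder but 1 from another member founds a new cluster; a transitive rule
  would merge them.
* The ten-fold rule degrades as selection converges (share compression);
  the pipeline applies it to the latest pools it is given and leaves
  choosing the screen round to the experiment design.
* The combined ranking is deliberately conservative (worse-of-both-ranks);
  a sequence with an extreme rate but modest prevalence, or vice versa,
  ranks behind consistent performers even when the extreme is genuine.
* σ uses the founder count as denominator; for clusters whose founder is
  itself depleted the rate is inflated. Rates are reported per pool, and
  profiling requires the founder present in that pool.
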