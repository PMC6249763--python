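# Methods

## Problem setting

A draft plant genome often exists only as unordered scaffolds. Given one or
more genetic linkage maps — markers with linkage-group (LG) assignments and
centimorgan (cM) positions, each marker tied to a scaffold coordinate — the
scaffolds can be assigned, ordered and oriented into pseudo-chromosomes.
`mapanchor` implements that integration for full-sib ("CP") outcross
populations of self-incompatible species such as pear, where markers
segregate as lm×ll or nn×np (testcross, 1:1) or hk×hk (intercross, 1:2:1),
plus the two downstream validation analyses used in such projects: a
bulked-segregant QTL scan against the new assembly and a protein-level
synteny comparison against a related genome.

## Marker quality control

The cascade mirrors standard GBS map-building practice:

- **Depth mask.** A call with read depth outside the inclusive range
  [`depth_min`=5, `depth_max`=1500] is treated as missing. Both bounds are
  taken as inclusive.
- **Alphabet mask.** Calls outside the marker's segregation-class alphabet
  (e.g. an `hk` call at an lm×ll marker) become missing; this is how
  "abnormal bases" are handled.
- **Missing / integrity.** A marker is removed when missing in more than
  `max_missing_individuals`=10 offspring **or** when its non-missing
  fraction is below `min_integrity`=0.95. The two published rules are read
  as independent OR-joined filters; for a population of 345 the missing-count
  rule is the stricter one. The integrity denominator counts offspring only.
- **Segregation distortion.** Pearson chi-square against the Mendelian
  ratio, df = classes − 1, no continuity correction (matching common
  mapping-software behaviour); removal at p < 0.05. On undistorted 1:1
  markers at n = 345 the realized type-I rate is ≈ 0.047 rather than 0.05
  because the binomial is discrete; the calibration test asserts the exact
  binomial 99% band.
- **Redundancy reduction.** When a scaffold carries more than
  `max_snps_per_scaffold`=5 qualified SNPs, five are kept "equally
  distributed": five targets evenly spaced over the occupied span (first to
  last marker position, inclusive endpoints — markers can only exist where
  SNPs were called, so the span is used rather than the scaffold length),
  each target taking its nearest not-yet-chosen marker with ties resolved
  toward the lower position.

The cascade is idempotent; re-running it on its own output changes nothing.

## Consensus anchoring

- **Assignment.** A scaffold goes to the LG with the largest
  Σ (map weight × marker count); an exact tie, or no mapped marker, leaves
  it unplaced (chromosome 0). Markers on a losing LG are excluded from
  positioning and orientation — the weighted-majority rule is this package's
  resolution of multi-LG conflicts, which published pipelines leave
  unspecified.
- **Consensus position.** Per map, a scaffold's position is the mean cM of
  its markers on the assigned LG normalized by that LG's span to [0,1] (0.5
  when the span is degenerate); the consensus is the weight-averaged
  position over maps containing the scaffold.
- **Ordering.** The objective is J(order) = Σₖ wₖ·ρₖ with ρₖ the Spearman
  correlation between map k's marker cM values and the marker order induced
  by the candidate scaffold ordering (scaffold rank, then within-scaffold
  bp; orientation is resolved separately and not fed back into J). Groups
  of ≤ 8 scaffolds are solved by full enumeration; larger groups start from
  the consensus-position sort and apply steepest-ascent over all pairwise
  swaps until no swap improves J. A deterministic local search was chosen
  over a genetic algorithm deliberately: results are reproducible
  bit-for-bit and the exact small-group branch preserves optimality
  guarantees where they can be checked. Ties break lexicographically by
  scaffold id.
- **Orientation.** The sign of Σₖ wₖ·ρₖ⁽ⁱⁿ⁾, where ρₖ⁽ⁱⁿ⁾ correlates
  within-scaffold bp with cM in map k. Scaffolds without two markers at
  distinct bp *and* distinct cM — including two-marker scaffolds whose
  markers share a cM value, a common outcome at GBS resolution — stay "?":
  anchored but strandless. Single-marker scaffolds are anchored, never
  oriented.
- **Concordance.** For auditing, the Spearman rho between each input map's
  marker order and the consensus order is reported per (map, LG).

## Pseudo-chromosome construction

Ordered scaffolds are concatenated with a spacer of `gap_len`=100 N bases;
"−" scaffolds are reverse-complemented, "?" scaffolds enter forward but
retain "?" in the AGP. The 100-bp default is the value recovered from the
published per-chromosome arithmetic (chromosome length − scaffold sum =
100 × (scaffold count − 1) on every chromosome); it is exposed as a
configuration knob. The builder works in length-only mode (no sequences)
for accounting work, always emits AGP v2.1 (gap rows: `scaffold`/`yes`/
`map`), and validates the tiling invariant — object length equals the sum of
component spans — on every write. Unplaced scaffolds stay separate records
rather than being concatenated into a "chr0" super-sequence, so no arbitrary
ordering is baked into the FASTA.

Statistics: N50 is the length of the piece at which the descending
cumulative sum reaches half the total, L50 the number of pieces needed;
marker density is unique markers per Mb of partition bases; the average
marker spacing of a map uses the LG-length / marker-count convention
(rather than markers − 1), the simpler of the two conventions that both
reproduce the published one-decimal values.

## Synthetic data model

The simulator is the test harness's ground truth, built to mirror the study
conditions rather than to be a general-purpose genetics simulator.

- **Genome.** `n_chrom` chromosomes of equal length tiled exactly by
  scaffolds at random breakpoints (minimum scaffold length 1 kb), i.i.d.
  uniform nucleotides, roughly half of the scaffolds assigned a true "−"
  orientation. The bp→cM relation is linear at `cm_per_mb` (default 4 cM/Mb,
  the genome-wide average implied by ≈1850 cM over ≈500 Mb; recovery tests
  use 25 cM/Mb so that 0.5-Mb test chromosomes still span ≥ 10 cM).
- **Cross.** Parental gametes follow a Markov process along each
  chromosome: the allele switches between adjacent markers with probability
  r = kosambi_r(Δcm) = tanh(Δcm/50)/2, independently per interval. This
  reproduces Kosambi two-point distances exactly but not Kosambi's
  interference structure over triples — adequate here because the consumers
  of these data (QC, anchoring) depend only on marginal and pairwise
  behaviour. Class mix defaults to 40/42/18% (lm×ll / nn×np / hk×hk),
  near the proportions observed in the GBS populations. Depths are negative
  binomial (mean 30, dispersion 0.3 — GBS-like overdispersion); calls are
  masked at `missing_rate` (default 5%); a genotyping-error rate is exposed
  and defaults to 0 since no empirical GBS error rate was available to
  emulate.
- **Map noise.** Estimated maps are modelled as the true map plus Gaussian
  cM jitter, non-overlapping adjacent swaps at `swap_rate`, random marker
  drops, and optional LG misassignment — the error modes that make multi-map
  consensus non-trivial in practice.
- **Bulks.** A dominant causal locus with phenotype-selected pools: a SNP at
  recombination fraction r from the locus has expected alt-allele frequency
  (1−r)/2 in the carrier pool and r/2 in the non-carrier pool, so
  E|Δ(SNP-index)| = (1−2r)/2, decaying to 0 for unlinked chromosomes
  (r = 0.5). Depths are Poisson around `mean_depth` with binomial alt
  counts.

All randomness flows through `numpy.random.default_rng` with explicit
integer seeds; identical seeds give byte-identical outputs across runs.

What the simulator does **not** emulate: read-level artefacts (mapping
bias, allele dropout at restriction sites), linkage-map construction errors
that correlate across populations, unequal chromosome sizes, segregation
distortion hot-spots, and real sequence composition. Passing recovery tests
therefore demonstrates the correctness of the integration algorithms under
the stated statistical model, not robustness to every artefact of real GBS
data.

## QTL-seq scan

SNP-index = alt depth / total depth per pool (the alt/total convention is
adopted; the alternative "non-reference-parent allele" reading differs only
by a sign that the absolute difference removes). Rows with zero total depth
in either pool are excluded. Windows are anchored at position 1, advance by
`step`=20 kb, truncate at the chromosome end; the window mean of per-SNP
|Δ(SNP-index)| is the scan statistic. The threshold is the (1 − 0.005)
quantile of non-missing window means genome-wide — a quantile over windowed
statistics, not per-SNP values, because candidate regions are defined as
intervals. Windows at or above threshold merge when overlapping or
book-ended; a below-threshold gap keeps subintervals distinct. With an AGP,
each interval is decomposed into the scaffold pieces it covers, in 1-based
inclusive scaffold coordinates with orientation-aware back-projection.

## Synteny

Best hits per query are ranked by higher bitscore, then lower e-value, then
lexicographic subject id; a pair is kept iff it is mutual and both
directions pass e ≤ 1e-7. Per chromosome pair the count of homolog pairs
and the absolute Spearman correlation of gene midpoints are reported —
absolute, because the relative orientation of two assemblies' chromosomes
is arbitrary; Spearman, consistent with the rank-based collinearity
measures used elsewhere in the package. Gene position is the midpoint of
the annotated span. Isoform pre-filtering is left to the caller (the hit
tables are inputs).

## Pipeline and determinism

`run_pipeline` executes simulate → qc → anchor → build → mapstats → qtlseq
→ synteny from one YAML config over documented defaults, derives per-stage
seeds from the global seed by fixed offsets, and writes a manifest with a
parameter hash and SHA-256 checksum per output so reruns are auditable.
The pipeline's synteny stage is a self-comparison (truth coordinates vs the
rebuilt assembly through marker projections), which must give diagonal
|rho| = 1 — an end-to-end consistency check of the builder.

## Numerical choices and edge cases

- Spearman correlations use average ranks for ties (scipy); degenerate
  (constant) vectors contribute 0 to the ordering objective and "?" to
  orientation.
- The ordering objective encodes (scaffold rank, within-scaffold bp) as
  rank·10¹² + bp before ranking; positions are far below 10¹², so the
  encoding is exact in double precision.
- Hill-climb acceptance requires an improvement > 1e-12 to avoid cycling on
  float noise; the steepest-ascent scan order is fixed, so results are
  deterministic.
- The redundancy selector compares distances with a 1e-12 guard so exact
  ties resolve toward the lower position.
- `threshold_top` uses the default linear-interpolation quantile; with all
  window means equal every window sits at threshold and merging yields one
  interval per chromosome.
- Problem sizes in the test suite and acceptance script are scaled-down
  study analogues (e.g. 3–17 chromosomes of 0.5–10 Mb, 15–17 scaffolds,
  1000 SNPs/chromosome at depth 20 for scan recovery), chosen as the
  smallest sizes at which the statistical claims under test are
  well-powered.

## Known limitations

- The hill-climb ordering is a local optimizer; on adversarial conflicting
  maps it can stall below the global optimum (the exact branch covers
  groups ≤ 8, where optimality is verified against enumeration).
- Equal-length chromosomes and a linear bp→cM relation are simplifications;
  recombination-rate heterogeneity along chromosomes is not modelled.
- The QTL scan reports no confidence band for |Δ(SNP-index)|; the
  top-fraction threshold is an order statistic, not a significance level.
- Gap sizes between scaffolds are fixed at the spacer length; no
  read-pair- or long-read-based gap estimation is attempted.
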