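# mapanchor

Tools for turning F1 outcross SNP genotypes and per-population genetic maps
into an anchored, chromosome-level genome assembly — and for checking the
result with a bulked-segregant QTL scan and a reciprocal-best-hit synteny
comparison.

The package re-implements the computational chain used to build the pear
*Pyrus bretschneideri* 'Dangshansuli' (DS) v1.1 pseudo-chromosomes from
genotyping-by-sequencing (GBS) maps of two full-sib ("CP") populations plus
a previously published map:

1. **Marker QC** — per-call depth masking (5–1500× inclusive), removal of
   markers missing in >10 individuals or with integrity <95%, a chi-square
   segregation-distortion test (1:1 for lm×ll / nn×np, 1:2:1 for hk×hk,
   P < 0.05), and redundancy reduction to five evenly distributed SNPs per
   scaffold.
2. **Consensus anchoring** — each scaffold is assigned to the linkage group
   with the largest weighted marker support (map weights 2/2/1), positioned
   by the weighted mean of its normalized cM positions, ordered to maximize
   the collinearity objective J = Σₖ wₖ·ρₖ (ρₖ = Spearman correlation between
   map k's cM positions and the induced marker order; exact enumeration for
   small groups, deterministic hill-climb otherwise), and oriented by the
   sign of its within-scaffold bp↔cM correlation when ≥2 markers at distinct
   positions support it.
3. **Pseudo-chromosome construction** — ordered scaffolds are concatenated
   with 100-N spacers ("−" scaffolds reverse-complemented) into FASTA + AGP
   v2.1, with N50/L50, marker-density and genome-fraction accounting.
4. **QTL-seq scan** — per-SNP SNP-index (alt/total depth per bulk),
   |Δ(SNP-index)| averaged in 1-Mb windows advanced by 20 kb, top-0.5%
   windows merged into candidate intervals and projected through the AGP
   onto scaffold pieces.
5. **Synteny** — reciprocal-best-hit ortholog pairing (e ≤ 1e-7) and
   per-chromosome-pair |Spearman| position correlations.

A fully deterministic simulator (`mapanchor.simulate`) emulates the study
design — a 17-LG outcross with the three CP marker classes, overdispersed
GBS depths and missingness, noisy per-population map estimates via the
Kosambi mapping function d = 25·ln((1+2r)/(1−2r)), scaffold fragmentation
of a known genome, and two phenotype-pooled bulks segregating at one causal
locus — so the whole chain is testable offline against known truth.

## Worked example

Run the synthetic end-to-end pipeline (5 chromosomes × 2 Mb, 40 scaffolds,
3 noisy maps with weights 2/2/1, two bulks):

```bash
mapanchor run --seed 42 --outdir demo
```

`demo/anchor_plan.tsv` lists each scaffold's chromosome, rank, orientation
and support:

```
scaffold  chrom  order_index  orientation  n_markers  consensus_pos
scf0001   1      0            -            11         0.027626
scf0002   1      1            -            9          0.117214
scf0003   1      2            +            24         0.375323
```

`demo/assembly_stats.tsv` gives the consensus-map partition accounting —
here 32 scaffolds (9,716,000 bp, 97.16% of the genome) are anchored with 197
unique markers (20.3 markers/Mb), 28 of them oriented:

```
partition  markers_unique  markers_per_mb  ...  total_bases  pct_of_genome
anchored   197             20.3            ...  9716000      97.16
oriented   192             20.3            ...  9455000      94.55
```

and `demo/qtl_intervals.tsv` shows the top-0.5% |Δ(SNP-index)| candidate
interval, which contains the simulated causal locus at chr5:1,000,000:

```
chrom  start   end      length   peak_mean_abs_delta
chr5   480001  1540000  1060000  0.438
```

Every stage is also exposed as its own subcommand (`simulate`, `qc`,
`anchor`, `build`, `mapstats`, `qtlseq`, `synteny`) over plain TSV/FASTA/AGP
files; see `mapanchor --help`.

## Layout

- `src/mapanchor/io_formats.py` — FASTA / AGP v2.1 / map, genotype,
  pool-depth and hit-table TSV readers and writers with strict validation
- `src/mapanchor/simulate.py` — truth layouts, crosses, map noise, bulks
- `src/mapanchor/marker_qc.py` — the filtering cascade
- `src/mapanchor/consensus_anchor.py` — assignment, ordering, orientation
- `src/mapanchor/pseudochrom.py` — builder + assembly/map statistics
- `src/mapanchor/qtlscan.py` — SNP-index windows and candidate intervals
- `src/mapanchor/synteny.py` — RBH pairing and chromosome correspondence
- `src/mapanchor/pipeline.py`, `cli.py` — orchestration and the CLI
- `docs/methods.md` — models, assumptions, parameter choices, limitations
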