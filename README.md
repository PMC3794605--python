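# methylsplice

Integrative analysis of tissue-specific DNA methylation and alternative
splicing from two-channel tiling-array data, with position-dependent 6mer
motif discovery.

## The problem

Intragenic DNA methylation differences between tissues (for example retina
vs brain) are associated with differential inclusion of exons, but the
sequence logic behind this coupling — which motifs, on which side of the
exon, promoting inclusion or exclusion — has to be recovered from two noisy
genome-wide assays at once.  `methylsplice` implements the full analysis
chain for researchers in regulatory epigenomics:

1. **T-DMR calling.** Two-channel methylation tiling arrays (input and
   methylation-enriched DNA, three replicates per tissue) are lowess- and
   quantile-normalized; per-probe relative methylation is
   M = log2(enriched/input).  Probes are tested between tissues and maximal
   runs of ≥ 3 neighboring significant probes (p < 0.005, consistent
   direction) become tissue-specific differentially methylated regions
   (T-DMRs).
2. **Genomic annotation.** Probes and T-DMRs are assigned one category
   (≤ 4 kb upstream of the TSS, 5′UTR, exon, intron, 3′UTR, intergenic) and a
   CpG-island context (island / shore ≤ 3 kb / shelf ≤ 4 kb / open sea);
   category enrichment uses the hypergeometric upper tail against the
   array's probe distribution.
3. **Conservation.** The fraction of nucleotides with a per-base
   conservation score above a cutoff, pooled over an interval set, with
   two-proportion comparisons between sets.
4. **Splicing index.** Exon inclusion is the normalized intensity
   NI = log2 exon intensity − log2 gene-level intensity; the splicing index
   SI = mean NI(tissue 1) − mean NI(tissue 2).  An exon is alternatively
   spliced (AS) when p < 0.01 and |SI| > log2 1.25.
5. **Integration.** T-DMRs link to exons through either the flanking-intron
   window or fixed 1 kb flanks; each link to an AS exon is classified
   **positive** (hypermethylation and greater inclusion in the same tissue)
   or **negative** (hypermethylation with exclusion).
6. **Motif discovery.** Within the 1 kb gene-sense flanks, every 6mer's
   count M over N overlapping windows is tested against its background
   frequency f (from the flanks of 10 000 random exons) with the binomial
   upper tail P(X ≥ M), X ~ Bin(N, f); Benjamini–Hochberg FDR 1% per group.
   Motif roles are compared between upstream and downstream positions
   (same role / one position only / opposing), CpG content and conservation
   of motifs are profiled, consensus motifs are built by hierarchical
   clustering, and motif-pair spacing is tested against a 100-fold shuffle
   null.

A first-class synthetic-data module generates genomes, gene models, CpG
islands, conservation tracks, probe arrays and exon-expression matrices
with planted T-DMRs, planted AS exons coupled under positive/negative
regulation, and planted motifs — plus a machine-readable truth set, so
every stage is testable end to end without any downloads.

## Worked example

```python
from methylsplice import SimConfig, simulate_dataset
from methylsplice import tdmr as td
from methylsplice.splicing import compute_ni, call_as_exons
from methylsplice.integration import exon_level_association, classify_links

ds = simulate_dataset(SimConfig(seed=1))          # ~2 Mb, ~51k probes
table = td.filter_background(td.normalize(ds.probe_table))
m = td.relative_methylation(table)
calls = td.call_tdmrs(m, table.probes, table.sample_tissue, table.tissues)
print(f"T-DMRs called: {len(calls)} (planted: {len(ds.truth.tdmrs)})")
t = calls[0]
print(f"first T-DMR: {t.chrom}:{t.start}-{t.end} {t.direction}-hyper, "
      f"{len(t.probe_ids)} probes, mean delta {t.mean_delta:+.3f}")
as_calls = call_as_exons(compute_ni(ds.expression), table.sample_tissue, table.tissues)
print(f"AS exons: {int(as_calls['is_AS'].sum())} of {len(as_calls)} tested")
links = exon_level_association(as_calls, calls, ds.bundle.genes_by_id(), mode="1kb")
reg = classify_links(links, calls, as_calls)
print("regulation labels:", reg["regulation"].value_counts().to_dict())
```

prints

```
T-DMRs called: 124 (planted: 100)
first T-DMR: chr1:9880-10490 tissueB-hyper, 15 probes, mean delta -0.309
AS exons: 58 of 553 tested
regulation labels: {'positive': 35, 'negative': 25}
```

All 100 planted T-DMRs are recovered (some split across two calls, hence
124); the mean delta of ±0.31 matches the planted difference of 0.3; 58 of
the 70 planted AS exons clear both splicing thresholds at this noise
level, and every T-DMR/AS link is labeled with its regulation direction.

The same flow is available from the shell:

```
methylsplice all --out run/           # simulate → … → motifs + report.md
methylsplice simulate --config cfg.yaml --seed 3 --out run/
```

Each stage writes stable filenames (`tdmrs.bed`, `as_calls.tsv`,
`regulation.tsv`, `motif_stats_<position>_<regulation>.tsv`, `report.md`,
…); a rerun with the same seed reproduces them byte for byte.

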