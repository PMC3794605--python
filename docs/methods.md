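# Methods

This note documents the models, statistical choices and numerical details
behind `methylsplice`, and what the synthetic benchmarks do and do not
demonstrate about real data.

## Coordinates and conventions

All coordinates are 0-based, half-open, BED-style, on disk and in memory.
Strand handling is explicit: "upstream"/"downstream" of an exon always
means gene-sense orientation, and motif sequence is read on the gene-sense
strand (minus-strand genes are reverse-complemented).  The two tissues are
ordered; signed quantities (probe delta, splicing index) are always
tissue 1 minus tissue 2, so a tissue swap flips their sign but never a
positive/negative regulation label.

## Array model and normalization

Each sample contributes two log2-scale channels per probe: input
(untreated DNA) and methylation-enriched DNA.  Relative methylation is
M = enriched − input, the log of the enrichment ratio.  Normalization is
the standard two-colour recipe:

1. **Control lowess.** Non-genomic control probes measure background: the
   lowess fit of their log-ratio against input intensity, interpolated at
   every probe's input, is subtracted from the enriched channel.  This
   removes intensity-dependent channel bias and anchors the ratio scale to
   the control background.  Fitting the ratio (not the raw enriched
   channel) is essential — subtracting a fit of enriched-vs-input would
   remove the identity component and invert the bias.  Lowess span 0.4;
   below 10 control probes the step is skipped with a warning.
2. **Quantile normalization** across samples, per channel, so sorted
   per-sample distributions are identical (ties resolved by stable ranks).

Background filtering drops genomic probes whose mean input falls below the
2.5th percentile of control-probe input; controls themselves never enter
testing.

## Probe statistic and T-DMR calling

With three replicates per tissue a raw per-probe Welch t-test has ~4
degrees of freedom.  At the p < 0.005 cutoff the critical value is
t ≈ 5.6 while a probe carrying a Δ = 0.3 difference at M-noise sd 0.1 has
noncentrality only ≈ 3.7 — roughly 24% power per probe, which makes a
≥ 3-consecutive-probe rule essentially unattainable however strong the
regional signal.  Dense tiling provides the remedy: neighboring probes
share signal, so the caller

- smooths M per sample with a 3-probe running mean along each chromosome
  (window truncated at chromosome edges and at inter-probe gaps > 300 bp),
  and
- moderates the variance: the per-probe squared standard error is shrunk
  toward the array-wide median with 20 pseudo-degrees of freedom
  (empirical-Bayes, limma-style), and the statistic is referred to a t
  distribution with the augmented df.

Under the standard benchmark conditions this yields interval sensitivity
≈ 100% and call-level FDR of a few percent; the plain per-probe test
(`smooth_window=1, prior_df=0`) remains available and is used to verify
the run/merge semantics in isolation.  "Neighboring" means adjacent in
array order on the same chromosome with a genomic gap ≤ 300 bp; runs must
be direction-consistent (all probe deltas one sign), maximal, and contain
at least three probes.  The region spans first-probe start to last-probe
end; its direction names the hypermethylated tissue.

A permutation FDR estimate is provided: all balanced relabelings of the
samples are enumerated (sampled with a seed when more than `n_perm`),
excluding the observed labeling and its mirror — including them would pin
the estimate at ≥ 2/n_perm even for arbitrarily strong signal, destroying
the sd → 0 limit.

## Genomic categories and CpG context

An interval receives exactly one category by precedence
5′UTR > 3′UTR > exon > intron > upstream > intergenic (upstream = 4 kb
strand-aware from the gene's outermost TSS); overlaps across genes resolve
by the same precedence, then lexicographic gene id, making assignment
independent of annotation order.  Category enrichment of T-DMR probes is
the hypergeometric upper tail against the array's probe composition.
CpG context distances are edge gaps to the nearest island: overlap =
island, ≤ 3 kb shore, ≤ 4 kb shelf, else open sea; an interval merely
touching an island (gap 0, no overlap) is classed island.  Gene-set
enrichment is hypergeometric with Bonferroni correction at 0.05.

## Conservation

Scores live in [0, 1] per base; unscored bases are excluded from
denominators (never counted as 0), and an interval set with no scored base
is flagged undefined rather than reported as 0.  The statistic is the
pooled fraction of bases with score **strictly greater** than the cutoff,
so it is invariant to interval fragmentation.  Group comparisons use a
two-proportion z-test (pooled variance, no continuity correction) on the
pooled base counts.

## Splicing index

NI = exon log2 intensity − gene-level log2 intensity, with the gene level
summarized as the mean of its exons' log2 intensities per sample (a
median or meta-probe summarization would also be defensible; the mean
keeps the within-gene NIs summing to zero, which the tests exploit).
Single-exon genes have NI ≡ 0 by construction and are excluded from AS
calling.  SI = mean NI(tissue 1) − mean NI(tissue 2); an exon is AS when
the Welch t-test on NI across replicates gives p < 0.01 **and**
|SI| > log2 1.25, both strict.  The exon-level test is left unmoderated:
the AS thresholds were designed for this scale of statistic, and the
acceptance benchmarks for splicing are run at low noise where 4-df power
is not limiting.

## Integration and regulation labels

Links between T-DMRs and exons support two windows: the exon plus its two
directly flanking introns, or the exon plus fixed 1 kb flanks.  A T-DMR
touching the exon interval is `within_exon` even when it straddles the
boundary (exon contact dominates); otherwise the label is
upstream/downstream in gene-sense orientation.  A T-DMR linked to several
AS exons contributes one assignment per exon.  Regulation is **positive**
iff the hypermethylated tissue equals the tissue of higher inclusion.
Coverage statistics merge T-DMRs before measuring, and pool bases across
exon neighborhoods (fractions are therefore weighted by length, matching
the two-proportion comparison applied to them).

## Motif discovery

Foreground groups are T-DMR subsequences clipped to the 1 kb flank window,
stratified by (position × regulation), gene-sense strand, no
reverse-complement pooling (upstream vs downstream is strand-meaningful).
Counts use overlapping windows; a length-L sequence yields L − 5 windows,
and ΣM over the 4096 k-mers equals N exactly.  The background is built
from the same-side 1 kb flanks of 10 000 randomly drawn exons (with
replacement when the annotation is smaller, as for synthetic genomes);
background frequencies also use overlapping windows, for consistency with
the foreground.  Significance is the binomial upper tail P(X ≥ M) under
Bin(N, f), computed through the regularized-incomplete-beta survival
function (stable to N ~ 10⁶); BH correction is applied within each
group's 4096 tests, significance at q < 0.01.  A k-mer absent from the
background but present in the foreground gets p = 0 and a flag; an
optional pseudocount of 0.5/(background windows) replaces the zero for
small synthetic backgrounds.

Positional roles: at each position a k-mer is positive, negative, dual
(significant in both regulation groups) or none.  K-mers significant
anywhere partition into same_role, one_position_only, and opposing —
opposing includes dual-vs-single mismatches so the three classes
partition the union.

Consensus clustering scores k-mer pairs by the best ungapped overlap over
shifts −2..+2 (distance = 6 − matches), average-linkage, cut at distance
2; members align to the lexicographically smallest k-mer (ties prefer the
smaller |shift|, then the smaller shift) and columns covered by at least
half the members take the IUPAC code of the tied majority bases.  PWM
similarity is the maximum over placements of the mean per-position log2
odds against a uniform background (probability floor 10⁻⁶), with a
one-sided Mann–Whitney shift test of the significant set against all 4096
k-mers.

Motif-pair distances are pooled within (exon, side) groups using genomic
instance positions; the null repositions each instance uniformly within
its own sequence, 100 shuffles, with the one-sided permutation p-value
(1 + #{null ≤ observed}) / (shuffles + 1).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study design the pipeline targets: a 2 Mb
two-chromosome genome (90 coding genes with 4–8 exons of 150–240 bp,
introns 1.2–2.8 kb, intergenic gaps 6–9 kb, 6 ncRNAs, a 20% multi-TSS
subset), CpG islands rewritten GC/CpG-rich and spaced so all four context
classes exist, blockwise conservation elevated inside planted T-DMRs,
overlapping 50 bp probes every 40 bp with 1000 non-genomic controls and a
small dead-probe fraction, and log2-Gaussian intensities.  Planted truth:
100 T-DMRs (70 coupled to an internal exon of a coding gene — upstream /
within-exon / downstream in 40/20/40 proportions — 30 uncoupled), a
planted M difference of exactly Δ between tissues inside each region, AS
effects scaled by n/(n−1) so the expected SI equals `as_effect` exactly
after within-gene normalization, and motifs written at Poisson-distributed
extra sites to reach a chosen enrichment fold over the empirical genome
background (fold 1 plants nothing).  All randomness flows from one root
seed through named substreams; a fixed configuration is byte-reproducible.

Deliberate simplifications: replicate noise is i.i.d. Gaussian (no
spatial correlation along the array, no probe GC/affinity effects), the
methylation level does not depend on CpG density, expression noise is
homoscedastic, and planted AS exons leak −SI/(n−1) into their siblings
through the gene mean (inherent to NI, not a bug).  Passing benchmarks
therefore demonstrate the correctness and calibration of the inference
machinery under the declared noise model — not performance on real
arrays, where correlated noise and probe effects would lower power.

## Problem sizes

The standard T-DMR benchmark uses ~2 Mb / ~51k probes with 100 planted
regions; the motif benchmark a ~5 Mb genome with 280 downstream-negative
couplings (≈ 240 kb of group sequence, ≥ 200 kb) and a 10 000-exon
background; distance calibration 60 fixed pairs over 100 shuffles.  These
sizes give stable statistics (binomial sampling error well inside the
asserted tolerances) while the full suite and the acceptance script each
complete in well under a minute.

## Known limitations

- The exon-level AS test is unmoderated 4-df Welch; at realistic noise a
  planted |SI| of 0.8 is recovered for ~80–85% of exons.  Variance
  moderation would raise this but the splicing thresholds are defined
  against the plain statistic.
- The permutation FDR enumerates balanced splits only (3v3 → 18 usable),
  so its null resolution is coarse.
- Consensus clustering is deterministic but greedy in its reference
  choice; PWMs from small clusters are sparse.
- BED round-trips quantize conservation to 4 decimals and T-DMR minimum
  p-values through the BED score column (−log10, 4 decimals).
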