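# Methods

This note documents the models and procedures implemented in `sorgvar`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic data do and do not establish.

## The simulated study

The simulator (`sorgvar.simdata`) emulates short-read resequencing of
three diploid inbred lines against an annotated reference: one grain-like
line and two sweet-like lines, sequenced at 12× per line with 44-bp
paired-end reads from ~500-bp-insert libraries. Defaults
(`SimConfig`):

| parameter | default | meaning |
|---|---|---|
| `genome_length` / `n_chromosomes` | 1 Mb / 2 | reference size; chromosomes split evenly |
| `gc_fraction` | 0.44 | background base composition |
| `n_genes` | 150 | gene models written into the reference |
| `intron_mean` | 444 bp | mean intron length (60-bp floor + exponential tail) |
| `read_length` / `insert_mean` / `insert_sd` | 44 / 500 / 50 | library geometry |
| `depth_per_line` | 12× | per-line fold coverage |
| `base_error_rate` | 0.005 | per-base miscall probability |
| `residual_het` | 0.02 | fraction of planted SNPs left heterozygous |
| `duplicate_rate` | 0.02 | PCR-duplicate pair injection rate |
| `multimap_fraction` | 0.05 | reads tagged with >1 equally good placement |
| `snps_per_line` | 600 | planted SNPs per line (≈0.6/kb) |
| `indels_per_line` | 50 | planted 1–10-bp indels, all lengths guaranteed |
| PAVs / CNVs per line | 3 / 3 | kb-scale absences; CNV segments ≥2.4 kb at ratios 0, 3, 2.5 |

The genome is gene-dense relative to a real cereal genome (150 genes/Mb
versus roughly one gene per 20 kb in sorghum): at 1 Mb a realistic density
would leave too few genes for the category-stratified ratio tables, the
enrichment statistics and the three sweet-gene channels to have workable
counts. Variant densities per line are likewise at the upper end of what
inter-varietal comparisons produce. Neither choice affects the calling
machinery, which operates read by read and site by site.

Gene models are constructed, not sampled from annotation: every bona fide
gene has an ATG start, a terminal stop, a CDS divisible by three with no
internal stop, and GT…AG intron boundaries; categories
(bona fide / low-confidence / transposon / pseudogene at 0.8/0.1/0.05/0.05)
are labels used by the downstream accounting, with identical structural
construction — the category mix stratifies bookkeeping, it does not model
decayed pseudogene structure. Pfam-family and pathway memberships are
drawn from a skewed synthetic catalogue (25 families, 12 pathways) and
travel as GFF3 attributes.

### Read generation

Reads are emitted as already-aligned, coordinate-sorted SAM against the
reference rather than FASTQ, so no external aligner is required. Each
line's mutated chromosome is built by applying its homozygous SNPs and
indels and removing its deletions; fragments are sampled from the mutated
sequence and mapped back through a block coordinate map:

* reads across a planted 1–10-bp indel carry the gapped CIGAR;
* reads that would cross a kb-scale deletion breakpoint are dropped
  (unalignable), while pairs straddling it survive with stretched spans;
* reads need ≥3 matched bases on each end, giving the small coverage dip
  real aligners show at event edges;
* heterozygous sites are sampled per fragment at 50/50 from the two
  haplotypes;
* insert sizes are truncated normal (±3.9σ), so no concordant pair ever
  exceeds the 4σ discordance threshold by construction;
* duplicates are re-emitted pairs with fresh names; the I/O layer flags
  them by identical (chrom, start, mate start, strand), and every caller
  counts non-redundant evidence only.

Copy-number **gains** are simulated as tandem duplications: the extra
copies contribute fragments sampled on the circularised segment, so both
reads of each extra pair fall inside the segment and the depth profile has
sharp edges; fragments spanning a copy junction wrap around and become
discordant (shortened or reversed apparent span), as at real duplication
junctions. Partial **losses** (ratio 0.5) modulate fragment-start rates
over a window shifted by half the inner fragment span so the depth trough
is centred; full losses (ratio 0) are sequence deletions and therefore
also produce absence signatures — a deliberate overlap, since a
homozygous multi-kb deletion genuinely is both a depth loss and a PAV.

What the simulator does **not** model: per-cycle error profiles and
quality decay, soft-clipped or chimeric alignments, reference bias,
GC-coverage bias, and repeat-induced mismapping beyond the per-read
multiplicity tag. Passing tests on this substrate therefore demonstrate
the correctness of the calling logic under the stated read geometry and
noise, not robustness to every artefact of real libraries.

## Callers

**SNP genotyper.** For a site with `n_ref`/`n_alt`/`n_other` reads, the
per-read emission is `1−e` for the true allele and `e/3` for each other
base; heterozygotes average the two alleles. The posterior over
{ref/ref, ref/alt, alt/alt} uses a uniform prior; quality is
−10·log10(1 − posterior of the best genotype). The parameter `e`
(default 0.01) is the genotyper's assumed error rate, deliberately
decoupled from the simulator's true rate. The scientific content is the
filter cascade (depth 3–50 per line, mean mapping multiplicity < 1.5,
novel-allele quality > 20, 5-bp adjacency with both members of a close
pair removed, het only at ≥3 reads per allele); the genotyper is the
simplest model that makes those filters meaningful, and its exact
posterior is verified in tests against an independent per-read product
oracle.

**Indels.** Signatures are keyed by (chrom, position, type, length,
sequence), so recovery is exact or nothing. "Crossing" gapless reads must
cover both bases flanking the gap anchor — the minimal reading of a read
that "crosses" the locus. Same-locus ties keep the better-supported
signature; exact ties emit nothing (ambiguous locus). The strand
requirement is implemented on read strands.

**PAVs.** The insert model is estimated from the data
(median span and 1.4826·MAD of concordant pairs) rather than taken from
configuration, as a pipeline on real data would. Only stretched-span pairs
are clustered into absences; shortened-span and wrong-orientation pairs
signal inserted or rearranged sequence, which cannot be resolved without
assembly and is out of scope. A cluster's interval is the median of inner
read edges; its implied length is the median span minus the insert mean,
which overshoots the true interval by roughly half the inner fragment gap
on each side — breakpoint precision is bounded by the library geometry,
not by the clustering.

**CNVs.** The expectation E is the per-line genome-wide mean depth over
covered bases (zero-coverage bases excluded, so large absences do not
drag the expectation down). The Poisson tail is evaluated at round(d) and
doubled, clamped to [0, 1]; `scipy.stats.poisson` supplies the tail and is
checked against direct pmf summation to 1e−12. Smoothing merges
sub-200-bp runs into their longer neighbour, shortest-run-first (heap +
linked list): processing the shortest runs first makes single-base Poisson
dips vanish into their local context before any long run is considered,
which keeps fragment boundaries at the depth step; a left-to-right sweep
was observed to let a long aberrant run creep over adjacent noise chunk by
chunk. The p ≤ 0.35 acceptance threshold is unusually permissive but is
the procedure's stated default, exposed as a configuration knob
(`CnvConfig.p_max`). At 12×, segments at ratio 3 or 0 are recovered with
breakpoints within ~100 bp; ratio-2.5 segments sit close to the 2.0
classification threshold and can be split by correlated coverage dips —
they are planted deliberately to exercise that borderline regime.

## Annotation and downstream statistics

Effects are assigned by strand-aware codon re-translation with the
standard genetic code; any change in the initiator codon is start_loss,
a change in the annotated stop that yields a sense codon is stop_loss
(stop→stop is synonymous), and any substitution in the GT/AG dinucleotides
is splice_disrupt even if the substituted pair looks splice-like — the
annotated site is what is disrupted. Genes with a CDS not divisible by
three get region-only annotation with a warning. With overlapping input
annotations the longest-CDS transcript is canonical. Each variant receives
exactly one region and one effect.

Ratio tables count protein-changing substitutions (plain non-synonymous
plus the stop/start classes) as non-syn; the Total row uses union-of-sites
semantics — a site shared between lines is counted once — and ratios are
rounded half-up to two decimals, reporting 0.00 where the denominator is
zero. The pathway test is the hypergeometric upper tail, which equals
one-sided Fisher's exact, so one implementation serves both names; raw
p-values are reported (0.01 family, 0.1 pathway thresholds) with a
Benjamini–Hochberg option available but off by default, matching the
reporting conventions of the analysis this package implements.
Sliding-window clustering assigns genes by midpoint with a 100-kb step —
both declared choices where the procedure is underdetermined.

Sweet-vs-grain selection requires identical position *and* alternate
allele for a shared SNP, uses ≥50% reciprocal overlap for shared PAVs
(breakpoints are imprecise), and excludes at gene level on the grain
line's non-synonymous SNPs; a `large_effect_mode` flag restricts the
qualifying classes to the four gene-disabling ones instead. The simulator
plants two independent shared sites per SNP- and indel-channel contrast
gene so that gene-level recovery does not hinge on a single site surviving
the read-level filters (a site can legitimately be discarded, e.g. at
mean mappability exactly 1.5).

## Numerical and degenerate-input conventions

Coordinates are 0-based half-open internally, converted at every I/O
boundary (SAM/VCF/GFF3 1-based, BED 0-based). Zero-depth sites yield no
genotype call; an empty FASTA, a CDS outside its exon, and overlapping CDS
segments are errors; a gene without a category attribute defaults to
bona fide with a logged warning. Base-quality ties in `top_alt` break
lexically. The CNV caller requires E > 0 and rejects empty or all-zero
depth tracks. All generator outputs are byte-identical for identical
configurations including the seed.

## Problem sizes

The test suite runs two simulations: a 200-kb single-chromosome design for
integration tests (~15 s) and the full 1-Mb three-line 12× design shared
by the acceptance tests (~75 s); `scripts/acceptance.py` re-runs the
1-Mb design from scratch. These sizes keep every caller in its intended
operating regime (hundreds of SNPs, tens of indels, and multiple kb-scale
structural events per line) while remaining single-CPU friendly.

## Known limitations

Single alternate allele per site (the most frequent non-reference base);
no multi-transcript effect fan-out; no GC correction of depth ratios; PAV
breakpoints at library-geometry resolution; no assembly of unmapped reads,
so novel presence (sequence absent from the reference) is only signalled,
never resolved; enrichment statistics on the synthetic catalogue
demonstrate the machinery, not biology.
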