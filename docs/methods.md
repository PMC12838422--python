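# Methods

## Coordinate and labelling model

Internally every interval is 0-based half-open; GTF I/O is 1-based inclusive
and BED I/O 0-based half-open (the bedtools convention). Junction flank
positions are defined on UTR-trimmed coding exons in *transcript*
orientation: a non-last exon donates (d1 = last coding base, offsets count
inward), a non-first exon accepts (a1 = first coding base). On the minus
strand the arithmetic mirrors (donor dk at `exon_start + k − 1`) and both the
flank's reference base and every substitution label are reverse-complemented
onto the coding strand — "G>T at d1" always means the biological guanine of
the donor consensus, regardless of which reference strand the gene sits on.
Exons shorter than three coding bases emit only the offsets they contain;
single-exon transcripts emit nothing. A genomic position may carry several
labels through different exons or genes; the non-redundant site key is
(contig, position, strand, role, offset) with gene lists unioned.

Two counting conventions coexist deliberately, because they answer different
questions and give different totals: composition tables count *sites*
(unique positions, once each however many alternate alleles were seen),
substitution matrices and proportion splits count *unique variants*
(contig, pos, ref, alt per position label). Output headers name which
convention each table uses. Nonsense and ref-stop ("other") variants are
annotated but excluded from all silent/missense statistics. Percentages are
printed to one decimal with round-half-even.

## Filtering and statistics

Cancer-dataset records with population allele frequency ≥ 0.1% are removed;
population records are split at the same boundary into rare (< 0.1%) and
common (≥ 0.1%, boundary inclusive). A missing AF counts as 0 — a cancer
variant without population frequency must not be silently discarded.

Gene-level scores divide a gene's unique-variant count by its coding exon
count; ranking is descending by that score with ties broken by raw count and
then gene id (a total order), with a configurable floor (default 0.4) before
taking the top M (default 100). Gene-set overlap uses the upper-inclusive
hypergeometric tail P[X ≥ k] via `scipy.stats.hypergeom.sf`, which is
log-space stable; the selected set is "genes with a variant recurring at
least twice". LOEUF bins are left-closed at 0.33/0.66/1 (0.33 falls in the
second bin, 1 in the last); genes without a LOEUF value are excluded and
reported in a `missing` column, never imputed. The dataset comparison
collapses the bins at 0.66 into a 2×2 low/high table; the chi-square test
applies the Yates continuity correction exactly when the table is 2×2,
matching the classical R default. Kruskal–Wallis uses the tie-corrected H
with a chi-square reference distribution; when every observation is
identical, H is defined as 0 and p as 1. Note the chi-square reference
deviates from the exact permutation null by up to ~0.06 at n = 8; the test
suite checks H against a first-principles midrank oracle exactly and the
p-value against a permutation null within that approximation band.
Conservation summaries report linear-interpolation quartiles of per-site
PhastCons-style scores (validated to lie in [0, 1]); unscored sites are
excluded and counted.

AUC is the rank concordance statistic computed from midranks — the
probability a random positive outscores a random negative with half credit
for ties — which equals the trapezoidal area under the empirical ROC curve;
both representations are produced and the identity is asserted in tests.
Variants lacking a tool's score are reported as unscored, never counted as
failed, and excluded from AUC denominators. Threshold rules preserve each
tool's published boundary semantics: strict `>` for SpliceAI/Pangolin/
MaxEntScan-diff/SPiP, `≥` for CADD, and left-closed bands for AbSplice
(0.05/0.2) and the inverted MaxEntScan alternate-allele score (< 6.2 high
potential, 6.2–8.5 moderate, ≥ 8.5 low).

## The synthetic-data generator

The generator emulates the full input surface: genome FASTA, GENCODE-dialect
GTF (canonical-tagged transcripts, a fraction with an extra untagged isoform
and with UTR stubs so selection and trimming are exercised), VCF v4.2 and
TSV variant tables with AF/occurrence/tissue, a wide per-tool score table,
binary validated-splice labels, 5-level and 3-level clinical category
labels, a gene→LOEUF table, gene-set lists and a per-position conservation
bedgraph — plus a ground-truth JSON of everything planted.

Defaults are chosen once to match the reported large-scale patterns and are
not tuned per run: exonic consensus G 80% at d1, A 64% at d2, G 49% / T 37%
at a1/a2 (the d3 preference is split across C and A); 500 genes of 8–16
exons (mean ≈ 12, close to the ~10.5 exons per canonical transcript in real
annotation); 12,000 cancer + 8,000 population variants with 85% on junction
flanks, spread over positions in proportion to the reported per-position
unique-SNV tallies; per-position 12-type substitution tables whose
reference-base marginals plant the variant-site composition (87% G at d1,
69% at a1) and whose dominant entries are G>T ≈ 0.40 / G>A ≈ 0.40 at d1;
missense fractions 0.78 at d1 and 0.861 at a1 (0.70–0.74 elsewhere, inside
the reported 66–86% band); allele frequencies from a two-component
log10-normal mixture straddling the 0.1% cutoff with 10% missing;
zero-truncated geometric occurrence counts (q = 0.88, boosted recurrence
q = 0.72 in "hot" genes) giving ≈ 17–18% of unique variants recurring; 20%
hot genes that attract cancer variants with 4× weight and draw LOEUF from a
low-bin-enriched mixture, versus a high-bin mixture for the rest; gene sets
(CGC/TSG/oncogene-like) sampled with 6× hot-gene bias; conservation scores
near 1 (Beta(60, 1), median ≈ 0.99) at cancer-variant sites versus broad
Beta(1.1, 0.9) at population-only sites; and per-tool score distributions
conditional on a latent splice-altering flag, Beta(8, 2) vs Beta(2, 8) on
each tool's scale (inverted for the MaxEntScan alternate score; Gaussians
for the difference score), with per-tool coverage matching the reported
annotation rates. The latent flag is a property of the variant: a variant
drawn in both datasets keeps one consistent flag. The clinical-category
probabilities reproduce the reported d1 margins (16.4% pathogenic-side,
6.5% benign-side; 47/43/10 splice-altering/low-frequency/normal); the
remaining mass sits on "uncertain", so the uncertain share is higher than
in real data, where further categories exist.

**How consequences are planted.** The consequence of an SNV is dictated by
its codon context, so it cannot be sampled independently of the genome.
The generator therefore samples, per variant, the position label, the
substitution type, and a target consequence from the planted mixture — and
then *selects* an unused (site, alt) pair whose true translated consequence
matches the target, preferring a never-used site, then an already-used
site's free allele slot (which costs only site uniqueness), then relaxation
of the consequence target (nonsense/other before the opposite class so the
silent/missense ratio is disturbed last). When a substitution class is
exhausted the variant is skipped rather than distorted, so degenerate
configurations (all mass on one substitution) stay exact. Consequences are
always computed from the actual codon, never fabricated. Intron boundaries
are always written GT..AG on the coding strand; CDS lengths are forced to
multiples of 3.

One RNG stream per output concern (genome, each variant dataset, scores,
labels, conservation, LOEUF, gene sets), all derived from the single seed,
so adding a dataset cannot perturb the others and identical config + seed
yields byte-identical files.

**What the generator does not emulate** — and hence what green tests do not
show about real data: trinucleotide mutational-signature context, realistic
chromosome lengths and gene density, population-genetic AF structure,
overlapping genes, alternative splicing beyond one extra isoform, and
predictor scores with realistic error structure (the planted Beta(8, 2) /
Beta(2, 8) separation yields AUC ≈ 0.96–0.999, cleaner than real splice
predictors achieve). Recovery tests demonstrate the *pipeline's*
correctness, not biological effect sizes.

## Problem sizes and numerical choices

The default simulated study is 500 genes / 20,000 variants (~1.5 Mb contig),
which the full pipeline processes in ~15 s; unit tests use 12–200 genes.
Statistical recovery is asserted within 3 standard errors of the planted
parameter (binomial or multinomial as appropriate; Hanley–McNeil for AUC);
the 12-type spectrum check allows a 0.02 absolute floor because nonsense
outcomes are excluded from the measured matrix, which perturbs proportions
slightly beyond multinomial noise. The replicated constraint-enrichment
power check runs the ranking/binning/chi-square stage on 100 gene-level
draws from the same planted models rather than 100 full genome simulations;
the full-genome path is exercised once at study scale. Determinism is tested
byte-for-byte on FASTA/GTF/VCF/TSV outputs. The annotated-variant
intermediate is written with shortest-round-trip float formatting so that
restarted stages reload scores exactly (a rounded score could flip a
threshold call); summary tables round to 6 significant digits.

The published full-scale tallies used for arithmetic cross-checks (per-
position unique-SNV counts, ClinVar d1 classification counts, SpliceVarDB
d1 outcome percentages) live in `spliceflank.reference` as documented
reference patterns; they come from database releases (COSMIC v98, gnomAD
v4.1, GENCODE v43, ClinVar 2024-09, SpliceVarDB) that are not redistributed
here, and nothing in the package fits to them.

## Known limitations

* Consequence calling handles SNVs only; indels and MNVs are dropped at
  ingestion with a logged count.
* Intronic splice positions (the GT/AG dinucleotides and deeper intronic
  context) are out of scope; only the three exonic flank bases per side are
  analysed.
* The hypergeometric "selected" set on dense synthetic data can approach the
  universe size, which makes overlap p-values conservative; on sparse real
  data the selection is far smaller.
* Multi-gene sites credit each gene's tally but count once in per-position
  totals; the first listed gene provides the codon context for consequence
  calling, which matters only if real overlapping genes disagree in frame.
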