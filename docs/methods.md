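# Methods

This note documents the models, conventions, and design choices behind
`ma_mutkit`, in the spirit of a statistical-software methods appendix.

## The experimental design being modelled

A mutation-accumulation (MA) experiment starts from one selfing ancestor
plant. In **line mode**, independent single-seed-descent lineages are
propagated for *g* generations; drift through the single-seed bottleneck
makes selection nearly powerless, so surviving mutations approximate the
spontaneous input. In **population mode**, a group of ~35 selfing plants is
propagated together; selection and shared parentage both operate, so a
mutation arising in generation *k* can be carried by several sequenced
final-generation plants. Final-generation genomes plus a pooled ancestral
("background") sample are sequenced, and de novo mutations are those calls
present homozygous in a descendant but absent — and confidently
reference-homozygous — in the background.

## Synthetic data generator

`genome.generate_reference` builds a plant-like genome: i.i.d. bases at a
target GC fraction (default 0.36, Arabidopsis-like); non-overlapping genes
(each 5'UTR – CDS – intron – CDS – 3'UTR, CDS rewritten to a valid ORF so
coding effects and Ka/Ks site counts are well defined); TE intervals
disjoint from genes; a callable mask covering 96.9% of the genome by
default (random 100–1000 bp dropout blocks, matching the accessibility
typical of deep short-read MA data); and a methylation landscape assigning
every cytosine its context from its own sequence (CG; CHG = C-H-G;
CHH otherwise, H ∈ {A,T,G}, on both strands) and a methylated status with
per-context probabilities 0.24 / 0.10 / 0.04 — plausible plant-like values,
configurable, not estimates from any dataset. Read counts per cytosine are
Poisson(20)+1 with methylated sites at level 0.85 and unmethylated sites at
the 0.02 non-conversion error floor.

`simulate.simulate_ma` draws each lineage's mutation count from
Poisson(rate × callable sites × g). Substitution identity is drawn first
from the six-class spectrum weights; the site is then drawn from callable
sites with the compatible focal base, weighted by the methylation and TE
mutability multipliers (Gumbel top-k weighted sampling without
replacement). Sampling class-first makes the realized class frequencies an
unbiased estimate of the weights regardless of genome composition, which is
the property the spectrum-recovery checks rely on. Indels are deletions
with probability `del_fraction` (default 0.75, matching the strong deletion
bias of plant MA data) with lengths from a 1–3 bp-dominated pmf. Population
mode propagates a constant-size selfing population where each offspring
inherits the mutation list of one uniformly chosen parent; the real
experiments' crossing scheme is unpublished, so this neutral
single-parent model is an explicit assumption. Truth mutations are emitted
homozygous: selfing fixes or loses heterozygous mutations quickly, and the
identification target is fixed homozygous variants. Per-lineage random
substreams are derived by CRC-hashing (seed, label, lineage index), so
adding lineages never perturbs existing ones.

`simulate.emit_variant_calls` wraps truth mutations in passing call records
(hom-alt genotype, DP ≈ 30–50, alt reads on both strands, benign QD/FS/MQ)
and injects labelled decoys, each engineered to be removed by exactly one
filter: low-DP records, single-strand SNVs, SNVs < 10 bp from an indel
(whose companion indel is itself a background variant), indel pairs ≤ 20 bp
apart, heterozygous records, records matching a background variant, and
records at background-heterozygous sites. Records are spaced ≥ 30 bp apart
so filters never interact by accident; placements colliding with existing
records are redrawn, with a bounded retry count. The background table
carries explicit hom-ref records (GT 0/0 with depth) at every candidate
site because the cascade requires positive evidence that the ancestor is
non-variant there.

### What the generator does not emulate

No reads, no sequencing error, no alignment artifacts, no recombination or
outcrossing, no TE transposition. Passing tests therefore demonstrate that
the *statistical pipeline* is correct given faithful call tables — not that
upstream alignment/calling on real reads is error free. The planted-SNV
validation here correspondingly checks the cascade at the call level; its
published analogue (98% recovery) includes read-level losses this package
does not model, which is why the noiseless synthetic check must recover
100% and the published figure is context, not a target.

## Identification cascade

Hard-filter thresholds are the standard GATK hard-filter sets for SNVs and
indels (see README). Absent rank-sum annotations never fail a record — they
are undefined at sites with no reference reads, which is exactly the
expected state of a true homozygous variant. The stringent criteria are
applied as set-valued predicates so the result is order independent:

1. depth ≥ 8 (SNV) / ≥ 5 (indel) in the MA sample; background hom-ref at
   DP ≥ 5 (sites without that support are uncallable, not callable-negative);
2. ≥ 1 alt read per strand, SNVs only;
3. subtraction of background variants by (chrom, pos, alt) and of sites
   heterozygous in the background;
4. SNVs within < 10 bp of *any* called indel of the same sample (retained or
   discarded) removed — discarded indels still mark alignment-hostile loci;
5. indel pairs with ≤ 20 bp between their reference spans: both members
   removed (conservative reading; the anchor convention — gap between
   closest span ends — is a documented choice);
6. genotype hom-alt, with alt-read fraction ≥ 0.8 as the in-silico stand-in
   for manual IGV inspection, which has no published algorithmic rule.

Indels whose inserted/deleted unit tandemly repeats at the site are flagged
`needs_validation` instead of dropped: such calls are real candidates that
merely need orthogonal confirmation. Multi-allelic records are split before
filtering. The cascade is verified against a brute-force oracle that
re-derives the accepted set by exhaustive scan on randomized instances.

## Statistics

* Rates: *m = n/g*, *mu = n/(g·b)*. Treatment summaries are the mean ± SEM
  of per-lineage rates (SD with n−1); the pooled estimate n/Σ(g·bᵢ) is also
  reported but the mean is primary. Comparisons use the equal-variance
  two-tailed Student's *t* test, with Welch behind a flag.
* Conditional spectra divide class counts by callable A:T or C:G sites ×
  g × lineages. Undefined Ts/Tv (no transversions) is an explicit flag.
* Trinucleotide contexts collapse by reverse complement to 32 classes
  (focal A or C representative); genomic denominators count each position
  once on the forward strand. G test: G = 2 Σ O ln(O/E), chi-square with
  k−1 df, zero cells contributing 0 (the x·ln x → 0 limit). Context
  elevation uses the pooled-variance two-proportion Z test; its normal
  approximation is accurate at moderate counts but diverges from exact
  binomial tails at extreme significance, so calibration is asserted on
  test size (type-I error ≈ 0.05) and oracle agreement at adequate counts.
* GC windows are non-overlapping 1-kb tiles binned at 0.005 GC resolution,
  rate = n/(m·g·1000) with m windows per bin. A sliding interpretation
  would double-count sites and break the conservation invariant.
* Gene density: 100-kb tiles (scaled down proportionally on small synthetic
  genomes), split at the median per-bin gene bp — the published grouping
  states no threshold; the median gives balanced groups and is reported in
  the output. Per-bin rates feed the t test.
* Annotation precedence (exonic/splicing > UTR > intronic >
  upstream/downstream > ncRNA/pseudogene > TE > intergenic) mirrors
  ANNOVAR-style defaults; splicing = within 2 bp of an intron boundary;
  upstream/downstream = within 1 kb of transcription start/stop. TE
  membership is always reported as a flag alongside the primary class.
* Fitness-affecting rate: U = 2 × 0.66 × mu_coding × L_coding — per-site
  coding rate × the assumed fraction of coding mutations under selection ×
  diploid copy number × coding length. The 0.66 constraint is a literature
  convention, configurable.
* Ka/Ks uses Nei–Gojobori equal-rate site counting (changes to/from stop
  treated as nonsynonymous; stop codons in-frame are skipped), with the
  Jukes–Cantor correction off by default because MA counts are far below
  the saturation regime. This is a counting estimator; model-based tools
  can differ by ~±15% on the same counts.
* Methylation status: one-sided binomial test of methylated reads against
  the 0.02 non-conversion error rate, Benjamini–Hochberg at q ≤ 0.05 — the
  standard bisulfite-caller convention; the original analysis names only
  "corrected p ≤ 0.05". Enrichment is a two-sided Fisher test of
  (mutated vs other cytosines) × (methylated vs not) per context, Bonferroni
  ×3 across contexts reported alongside raw p. The logistic model is fit as
  a binomial GLM on the four collapsed covariate patterns (identical
  likelihood to row-level logistic regression); complete separation is
  detected and raised, never silently returned.
* Overlap expectation uses the callable-mask size as the accessible-site
  denominator (configurable; the published basis is unstated and the two
  candidates differ by ~3%). Indels are matched at the exact left-normalized
  start coordinate. Fisher's exact p is cross-checked against an exhaustive
  hypergeometric tail-sum oracle on small tables.

## Numerical and testing conventions

Internal coordinates are 0-based half-open; VCF/GFF3 on disk are 1-based.
All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; every simulation API is a pure function of
(inputs, seed). Test problem sizes are chosen for desk-scale runs: 2 × 100 kb
genomes for identification tests, 2 × 500 kb (≈ 10⁶ callable sites) for
parameter-recovery experiments, 20 seeds for rate recovery, ≥ 10⁴ mutations
for spectrum recovery, 1000 replicates for test-size calibration, and 10⁶
sites × 10 seeds for logistic effect recovery. Statistical assertions use
analytic error bands (binomial 99% CIs, 2–3 SEs) rather than tuned
tolerances. The pipeline demo (`ma-mutkit run`) completes in seconds on one
CPU.

## Known limitations

Rates recomputed from treatment-level aggregates use a single 116 Mb
accessible-site figure for every lineage, so they match published per-line
means only to within a percent or two. The population-mode transmission
model ignores selection and nonuniform fecundity. The zygosity filter's
alt-fraction threshold is a proxy for manual inspection and read-level
evidence. Region classes ncRNA/pseudogene exist in the classification
vocabulary but the synthetic annotation does not generate such features.
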