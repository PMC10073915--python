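# Methods

This note records the models, parameter choices and numerical
conventions behind `sexbiasevo`, and what the synthetic-data tests do
and do not demonstrate about real data.

## Study design emulated

The pipeline targets a three-population comparison: one wild breed and
two domesticated breeds selected under different sex-specific regimes
(a meat type, implying stronger male-directed selection, and an egg
type, implying stronger female-directed selection). Expression is bulk
RNA-seq FPKM from two tissues — gonad (strongly sexually dimorphic) and
liver (a somatic control) — with 5 males and 5 females per breed and
tissue. Genotypes are whole-genome biallelic SNPs for 8 diploid
individuals per breed. Body weights are adult phenotypes per sex, 25
individuals per sex by default.

## Sex-bias calling

* **Expression filter.** A gene counts as expressed in a tissue when
  FPKM ≥ 0.5 in at least one sample of that tissue (boundary
  inclusive); filtering is per tissue, so gonad and liver keep
  different gene universes. Sex-chromosome and immune/MHC genes are
  removed from user-supplied lists because their expression differences
  confound sexual conflict (incomplete avian Z dosage compensation;
  immune loci under their own balancing regimes).
* **Test.** Significance comes from a Welch t-test on
  log₂(FPKM + 0.5), two-sided, with Benjamini–Hochberg FDR applied per
  breed × tissue family at 0.05. With 5 samples per sex an exact rank
  test cannot reach FDR-corrected significance (the smallest achievable
  two-sided p is 1/126), so a parametric test on the log scale is the
  default; a Mann–Whitney option exists for heavy-tailed data.
* **Fold change.** Linear ratio of sex means after a 0.5 pseudocount,
  larger sex over smaller, so FC ≥ 1 by construction. Bins are closed
  on the left: low [2, 4), medium [4, 10), high [10, ∞) — "greater than
  10" is treated as ≥ 10 for continuity of the partition.
* **Degenerate inputs.** Zero variance in both sexes yields p = 1 when
  the means are equal and p = 0 otherwise (the noise-free limit).
* **Dynamics labels.** BLG/BAG/BCG/conserved depend only on each
  gene's (direction, magnitude) triple across the three breeds; a gene
  missing a call in any breed is "other". BCG requires both domestics
  to oppose the wild direction; a half-flip is "other".
* **Clustering.** Samples are clustered on log₂(FPKM + 0.5) with
  Euclidean distance and complete linkage. Node support is the ordinary
  bootstrap proportion over gene resampling (B = 1000 by default):
  the fraction of replicate trees containing the node's exact sample
  set. This is simpler and more conservative than multiscale
  (approximately unbiased) bootstrap corrections; supports are
  comparable within a tree, not calibrated p-values.

## Windowed diversity and Tajima's D

* **Windows** are non-overlapping 10 kb tiles anchored at each gene's
  genomic start; a partial tail window is never emitted, so every
  window statistic has the same denominator. This removes the
  uncertainty of ragged terminal windows at the cost of discarding up
  to 10 kb per gene; genes shorter than one window contribute nothing.
* **π** uses the unbiased per-site pairwise estimator
  2j(m−j)/(m(m−1)) with the *reduced* allele total m at sites with
  missing haplotypes, summed and divided by the full window length —
  unreported positions count as monomorphic, the convention of windowed
  VCF diversity tools. π is therefore a per-bp quantity comparable
  across windows.
* **Tajima's D** is computed complete-case per region (sites with any
  missing haplotype in the breed are dropped from both S and the π
  sum), keeping the S-based and π-based θ estimates on the same site
  set. D is NaN when S = 0 or n < 4. Both per-window and arbitrary
  per-region calls are supported, since gene-level and window-level
  reporting are both in use in the field.
* D is invariant to haplotype relabeling and to swapping ref/alt at any
  site; both invariances are property-tested.

## dN/dS (NG86)

* **Reconstruction.** Substitution happens in genomic frame, then
  minus-strand genes are reverse-complemented into coding orientation.
  Heterozygous sites take the ALT allele by default — a single sequence
  per individual must be chosen, and ALT captures the individual's
  derived variation; REF and seeded-random policies are available. A
  VCF REF allele disagreeing with the reference sequence is an error,
  not a silent skip.
* **Counting.** Nei–Gojobori (1986) with equal pathway weighting:
  per-codon expected synonymous sites s = Σ (synonymous one-step
  changes)/3 with stop-creating changes counted as nonsynonymous;
  per-codon-pair differences averaged over all orderings of the
  differing positions, excluding stop-passing pathways unless every
  pathway is blocked (then all count). Proportions are corrected with
  Jukes–Cantor, d = −¾ ln(1 − 4p/3), NaN at p ≥ ¾. ω = dN/dS is NaN
  when dS = 0 — reported, flagged, and excluded from means rather than
  coerced to 0 or ∞.
* **Partner and averaging.** Default divergence partner is the
  outgroup ortholog CDS (per individual, then averaged within breed);
  orthologs must be length-matched because codon-aware alignment is out
  of scope — length-mismatched genes are skipped with a reason.
* **Outlier rule.** A gene is removed from all breeds when its ω lies
  outside Tukey fences Q1 − k·IQR / Q3 + k·IQR of exactly one breed
  while inside all others' (k = 3 by default, configurable). The rule
  targets artefacts private to one population sample (e.g. a local
  misalignment) while keeping genes that are genuinely fast in several
  breeds.

## Size dimorphism

SSD = 100 · μ̂_M/(μ̂_M + μ̂_F), scale-invariant and within (0, 100).
Breed comparisons use the delta method on this ratio:
Var(R) ≈ (μ_F² s²_M/n_M + μ_M² s²_F/n_F)/(μ_M + μ_F)⁴, Z on the
difference of two breeds' ratios with a two-sided normal p. This is the
minimal test using individual weights and sample sizes; it converges to
the plain two-sample Z when one sex's weights are held fixed (checked
numerically). Two-sample mean and pooled two-proportion Z-tests are
provided for mean-weight and count-share contrasts.

## Synthetic data: what it does and does not emulate

* **Expression** is log-normal around a per-gene baseline
  (log₂ FPKM uniform in [2, 8]) with sex shifts of ±log₂(FC)/2 and
  log₂-scale noise σ = 0.25 — chosen as typical biological replicate
  spread for bulk FPKM at moderate expression. Dynamics classes are
  planted per tissue; gonad defaults (8% conserved, 8% bias-lost, 1%
  bias-acquired, 0.2% bias-converted) mirror a strongly dimorphic
  embryonic gonad, liver defaults an order of magnitude lower. Planted
  fold changes are log-uniform within the low/medium/high bins
  (high capped at 30). Not emulated: count-level (negative binomial)
  noise, expression-dependent variance, correlated genes, batch
  effects — sensitivity numbers on synthetic data are upper bounds for
  real FPKM matrices.
* **Genotypes** come from a genealogy-free neutral site-frequency
  model: per window S ~ Poisson(θ L a₁(n)) and derived counts i with
  probability ∝ 1/i, which gives E[window π] = θ and E[D] ≈ 0 exactly
  as needed for calibration. Sites are unlinked: no linkage
  disequilibrium, no genealogical variance inflation, no demography.
  Multi-breed panels give each breed private sites (others homozygous
  reference). Tests on this model validate the *estimators*, not
  demographic inference.
* **Coding divergence** proposes uniform single-base changes, accepts
  synonymous always and nonsynonymous with probability ω, rejects
  stop-creating changes, and stops at the target substitutions-per-site
  (default 0.05). Because the NG86 site counts include stop-creating
  changes as nonsynonymous opportunity while the generator never takes
  them, the estimator is expected to sit ≈5% below a planted ω — an
  inherent property of this estimator/process pair, visible in the
  recovery numbers (≈0.94 for planted 1.0) and within the stated
  tolerances.
* **Weights** are Normal per sex, truncated at zero by redrawing, with
  default means planting SSD ≈ 53.2% (wild), 51.7% (meat) and 51.1%
  (egg) at ~8% coefficient of variation.
* All generators consume a single explicit seed; equal seeds give
  byte-identical outputs.

## Problem sizes and runtime

The test-suite and acceptance-script problem sizes are chosen so each
check has clear statistical headroom at interactive runtimes: 1,000
random matrices for the π oracle, 500 instances for the Tajima oracle,
500 × 10 kb windows for neutral recovery (standard error of mean D
≈ 0.045, well inside the ±0.1 band), 10,000 codons per ω-recovery
alignment with the acceptance script averaging 6 replicate alignments
(Monte-Carlo sd ≈ 3%), and 1,500 genes × 3 breeds for bias-calling
sensitivity. The noise-free dynamics check runs with pseudocount 0,
since at σ = 0 the pseudocount's only effect is to shrink fold changes
of genes planted exactly at the 2× threshold below it — a property of
the regularisation, not of label recovery.

## Known limitations

* No count-model differential expression; FPKM is taken as given.
* Single-exon gene models; multi-exon CDS must be supplied directly as
  FASTA.
* No codon-aware alignment: indel-divergent orthologs are skipped.
* The bootstrap support is not an approximately-unbiased p-value.
* The two-proportion Z-test is provided for direction-share contrasts
  without a claim about which published p-values it reproduces, since
  their exact inputs are not recoverable.
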