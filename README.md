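# sexbiasevo

Comparative analysis of **sex-biased gene expression** and its
**population-genomic signatures** across one wild and two domesticated
populations — the study design used to ask how domestication (and the
relaxed sexual selection that comes with it) reshapes the transcriptome
and the genome of a species such as the duck.

The package is aimed at evolutionary and population geneticists who have
an FPKM expression matrix, per-individual genotypes in a VCF, reference
and outgroup coding sequences, and body-weight phenotypes, and want the
full chain from bias calling to selection statistics as tested,
reusable code. A synthetic-data generator plants known truth for every
stage, so the whole pipeline is verifiable without any downloads.

## What it computes

**Sex-bias calling.** After dropping genes with FPKM < 0.5 in every
sample of a tissue (and user-supplied sex-chromosome / immune-gene
exclusion lists), a gene is sex-biased in a breed × tissue when its
fold change

&nbsp;&nbsp;FC = (x̄_M + c) / (x̄_F + c)  (or the reciprocal, whichever ≥ 1, pseudocount c = 0.5)

is ≥ 2 and a Welch t-test on log₂(FPKM + c) survives Benjamini–Hochberg
FDR < 0.05. Biased genes are binned by FC into low [2, 4), medium
[4, 10) and high [10, ∞) classes. Across breeds, genes are labelled
**BLG** (bias-lost: biased in the wild breed only), **BAG**
(bias-acquired: biased in both domestics only), **BCG** (bias-converted:
direction flipped in both domestics), conserved, or other. Sample
structure is summarised by Euclidean complete-linkage clustering with
gene-bootstrap node support.

**Diversity and the site-frequency spectrum.** Genes are tiled into
10 kb windows (partial tails dropped). Per window and breed, nucleotide
diversity uses the unbiased per-site estimator π_site = 2j(m−j)/(m(m−1))
summed over sites and divided by window length, and Tajima's
D = (π − S/a₁) / √(e₁S + e₂S(S−1)) with the 1989 constants. Breed and
bias-category contrasts use the Wilcoxon rank-sum test.

**Coding-sequence evolution.** Each individual's CDS is reconstructed
by substituting its VCF alleles into the reference (heterozygotes → ALT
by default) and compared with the outgroup ortholog by the
Nei–Gojobori (1986) method: expected synonymous/nonsynonymous site
counts, pathway-averaged difference counts, Jukes–Cantor correction
d = −¾ ln(1 − 4p/3), and ω = dN/dS averaged within breeds, with genes
that are ω-outliers (3 × IQR Tukey fences) in exactly one breed removed.

**Sexual size dimorphism.** SSD = 100 · x̄_M/(x̄_M + x̄_F) per breed
from individual weights; breed pairs are compared with a delta-method
Z-test on the SSD difference, plus plain two-sample and two-proportion
Z-tests for mean and count comparisons.

## Worked example

```bash
python examples/01_sex_bias_calling.py
```

```
tissue breed  n_expressed  n_biased  n_male_biased  n_female_biased  proportion_pct  male_share_pct  female_share_pct
 gonad  wild         1000       156             74               82            15.6              47                52

Strongest calls (fc = linear fold change, larger sex over smaller):
gene_id        fc direction            q magnitude
 g00131 28.125525    female 2.100894e-07      high
 g00718 23.287846    female 4.660350e-08      high
 g00996 23.171667      male 1.595026e-07      high
 g00065 22.579016    female 6.735545e-07      high
 g00251 21.868179      male 6.735545e-07      high

156 genes called biased vs 162 planted; the difference is genes whose
planted fold change sits below the 2x threshold after noise.
```

Of 1000 simulated gonad genes, 15.6% are called sex-biased (47% of them
male-biased), and the strongest calls are high-magnitude (FC ≥ 10)
genes with tiny q-values; recovery against the planted truth is nearly
complete. The other scripts in `examples/` walk through bias dynamics,
windowed π and Tajima's D, dN/dS, SSD, and the full pipeline.

The same runs from the shell:

```bash
sexbiasevo simulate --out-dir demo --seed 1        # inputs + config.yaml
sexbiasevo run --config demo/config.yaml           # all stages -> demo/report/
```

`demo/report/` then holds `bias_calls.tsv`, `summary_counts.tsv`,
`dynamics.tsv`, `windowed_pi.tsv`, `tajima_d.tsv`, `pi_by_category.tsv`,
`dnds.tsv`, `dnds_by_category.tsv`, `ssd.tsv` and a run log with the
seed and parameter echo.

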