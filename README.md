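# riskloci

Linking GWAS risk loci to the regulatory chromatin of the disease cell
type: a tested, reusable pipeline for LD-region construction,
chromatin-state enrichment, genotype reconciliation, molecular QTL
scanning, allelic-imbalance testing, and transcription-factor motif
disruption scoring.

## Who this is for

Most GWAS risk variants fall in non-coding DNA and act through gene
regulation. Given a list of sentinel SNPs (the strongest association
per locus), per-sample chromatin-state segmentations, molecular data
layers (chromatin accessibility, H3K27ac, DNA methylation, gene
expression), and genotypes, this package answers, locus by locus: does
the risk region overlap active regulatory elements more than expected?
Does the risk genotype shift accessibility, histone acetylation,
methylation, or the expression of nearby genes? Is chromatin
accessibility allele-specific at heterozygous sites? Which
transcription-factor binding motifs does the risk allele disrupt?

Because the underlying patient-level data of such studies are
controlled-access, the package ships a first-class synthetic-data
module that generates seeded cohorts with the same statistical
structure (LD-blocked haplotypes, 12-state segmentations in 200-bp
bins, genotype-dependent signal matrices with latent confounders,
overdispersed allele-specific read counts), each with truth tables, so
every stage is testable end to end with no download.

## The statistics at the core

- **LD0.2 regions.** For sentinel *s*, the risk locus spans all SNPs
  with *r*² ≥ 0.2 to *s* (boundary inclusive). The background is the
  merged union of all per-SNP LD regions, with any merged interval
  overlapping a risk locus removed.
- **Chromatin-state enrichment.** For locus *i*, state *j*, and one
  sample, *E*ᵢⱼ = log₂(*C*ⱼ;ᵢ / *C*ⱼ;B), where *C*ⱼ;ᵢ is the fraction
  of the locus covered by state *j* and *C*ⱼ;B the same fraction over
  the background regions. Zero fractions propagate as NaN/±inf rather
  than pseudocounts.
- **QTL model.** Per layer: eligibility filtering by genotype subgroup
  (presence in ≥ max(2, 10% of a subgroup)), principal-component
  residualization of latent confounders, rank-based inverse-normal
  transform, then for each (sentinel, feature) pair a linear regression
  of the transformed value on the 0/1/2 dosage with a two-sided *t*
  test (n−2 df) and Benjamini–Hochberg control at FDR < 0.05.
  Expression candidates are restricted to TADs spanning the LD region.
- **Allelic imbalance.** Reference/alternative read counts are pooled
  over heterozygotes whose per-sample reference ratio lies in
  [0.1, 0.9]; a beta-binomial null (shapes α, β) is fitted by maximum
  likelihood on background SNPs; each testable SNP (≥3 heterozygotes,
  ≥10 pooled reads) gets a two-sided minimum-likelihood test against
  that null, with BH control at FDR < 0.1 and a normal-approximation
  95% CI on the pooled ratio.
- **Motif disruption.** Sequences score against a PWM as
  Σₚ ICₚ·log₂(qₚ(base)/bg(base)) (relative-entropy weighting,
  pseudocount 10⁻³); both alleles are scanned over all SNP-covering
  windows on both strands; score p-values come from the exact tail of
  the background score distribution (exhaustive for L ≤ 8, lattice
  convolution otherwise).
- **Genotype reconciliation.** Imputed probability triples are called
  with an uncertainty cutoff of 0.1, SNPs with information measure
  < 0.85 are dropped, calls in copy-number-altered intervals are
  masked, WGS calls require depth ≥ 10 with quality flags and
  normal/tumor agreement, samples under 90% imputed-vs-WGS concordance
  are excluded, SNPs under 90% concordance become WGS-only, remaining
  conflicts resolve to WGS, and WGS fills imputed gaps.

## Worked example

```python
from riskloci.pipeline import RunConfig, run_pipeline

result = run_pipeline(RunConfig(seed=1, outdir="out"))
print(result.counts)
```

prints (seed 1):

```
{'n_loci': 42, 'loci_any_qtl': 36, 'loci_qtl_accessibility': 15,
 'loci_qtl_h3k27ac': 9, 'loci_qtl_methylation': 28,
 'loci_qtl_expression': 24, 'loci_allelic_imbalance': 8,
 'loci_active_element': 39}
```

Of the 42 simulated risk loci, 39 contain a proxy SNP in an active
promoter or strong enhancer in at least one sample, 36 show a
significant QTL in at least one molecular layer (15/9/28/24 for
accessibility/H3K27ac/methylation/expression — the planted counts were
14/9/28/23, so the scan recovered every planted effect plus two
FDR-level false positives), and 8 loci carry a significantly imbalanced
SNP. `out/overview.tsv` holds the per-locus table (QTL flags per layer,
candidate genes, imbalance flag, enrichment group, active-element
flag); `out/manifest.json` echoes every threshold used.

The same pipeline is exposed as a CLI:

```bash
riskloci all --seed 1 --outdir out
```

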