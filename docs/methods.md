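# Methods

This note documents the models, conventions, and numerical choices
behind `riskloci`, in the order the pipeline runs them, plus what the
synthetic cohorts do and do not emulate.

## Coordinates and conventions

All intervals are 0-based half-open (BED convention), on a single
linear contig. Two-sided p-values of discrete tests (Fisher exact,
Hardy–Weinberg exact, beta-binomial) use the minimum-likelihood rule:
sum the null probabilities of all outcomes no more likely than the
observed one. This matches R's `fisher.test` convention and is applied
uniformly so that the three tests are mutually consistent.

## Synthetic cohorts

The generator (`riskloci.simulate`) produces a seeded bundle whose
statistical structure matches what each downstream stage assumes. All
randomness flows from one root seed through named substreams
(`config.rng("panel")`, `...("segmentation", sample)`, ...), so stages
are individually reproducible and the whole bundle is a pure function
of the config.

**Haplotype panel.** SNPs sit in independent LD blocks (25 SNPs,
400 bp apart, one block per locus plus background blocks). Within a
block, SNP t+1 copies SNP t per haplotype with probability
√decay and is otherwise redrawn from the block allele frequency
(uniform in [0.3, 0.7]); the lag-1 *r*² then equals the configured
decay (0.9 by default, giving proxies out to roughly ±12 SNPs at the
0.2 threshold), and decay = 1 degenerates to exact copies. This
block-copy scheme trades coalescent realism for a directly tunable
*r*² profile; it produces no inter-block LD, no recombination
hotspots, and no allele-frequency/LD coupling.

**Cohort sizes and planted structure.** Defaults emulate the study
design the package addresses: 42 risk loci, 99 samples, and a locus
partition of 34 strongly active / 5 weakly active / 3 inactive.
Strongly active loci draw 80% of their 200-bp bins from the three
active states in every sample; weakly active loci carry a single
active bin at one proxy SNP in one sample; active states are
suppressed inside non-active loci so the partition is recoverable.
Outside loci, bins follow a fixed genome-wide state frequency vector
dominated by low-signal heterochromatin (58%).

**Feature layers.** Each locus contributes one feature per layer
(accessibility, H3K27ac, methylation, expression) centered at its
sentinel, plus null features far from any locus. Planted features
follow value = intercept + β·dosage + Λ·factors + ε with β = 1 (in
units of the noise SD, ε ~ N(0,1)), three latent factors with
N(0, 0.5²) loadings, and layer signs: accessibility, H3K27ac, and
expression share the effect sign; methylation opposes it (more
methylation with less activity). Planted-QTL loci per layer default to
14/9/28/23 with a deliberately structured overlap whose union is 36 of
42 loci.

**Allele counts.** Roughly 4–5 proxy SNPs per locus (189 candidates at
the default scale) plus 2,000 background SNPs. Allelic imbalance is a
variant-level (cis) property: each SNP carries one latent reference
ratio, Beta(α, β)-distributed under the null (α = 20.5, β = 20.3 by
default) and fixed at the configured ratio (0.8) for planted SNPs, so
the truth table states the true generating value and pooled
heterozygote counts are exactly beta-binomial. Homozygote counts carry
a 0.5% sequencing-error allele, which exercises the 0.1–0.9 ratio
filter. Read totals are Poisson(40)+1 per sample and SNP.

**What passing tests do not show.** The generator has no read-level
mapping bias (counts are assumed bias-filtered upstream), no
population structure or relatedness beyond what tests plant
explicitly, no correlated noise between layers, no copy-number signal
in the molecular matrices, and exact HWE in background genotypes.
Passing tests therefore demonstrates correctness of the statistical
machinery under the stated model, not robustness to artifacts real
cohorts contain.

## Statistical primitives

Implemented in `riskloci.stats`, using `scipy.special` only for
gammaln/Φ/Φ⁻¹:

- **Fisher exact**: hypergeometric enumeration over the table support;
  odds ratio (a·d)/(b·c) with ∞ on a zero denominator.
- **Wilcoxon rank-sum**: statistic W = #(x > y) + ½·ties (the
  Mann–Whitney U of x). Exact mode enumerates the permutation
  distribution via the Gaussian-binomial recurrence (no ties, ≤10 per
  group); normal mode uses the tie-corrected variance and a 0.5
  continuity correction — the R default for larger samples.
- **Inverse-normal transform**: Φ⁻¹((r − 0.5)/n) on average ranks.
  Constant input is an error, not silent zeros: a constant feature
  reaching the transform indicates a broken upstream step.
- **HWE exact**: Levene's conditional distribution of the heterozygote
  count given allele counts.
- **Beta-binomial**: log-pmf via log-gamma identities; the MLE
  optimizes (log α, log β) by L-BFGS-B from a method-of-moments start
  (with a (1,1)-start fallback), parameters capped at 10⁶ where the
  distribution is numerically binomial. A 200×200 log-grid search
  cross-checks the optimizer in tests.

Degenerate inputs are rejected loudly (all-zero tables, empty samples,
k > n, constant vectors); ties in discrete p-value comparisons use a
10⁻⁹ relative slack so float rounding cannot split tied outcomes.

## LD regions and background

Proxies use *r*² ≥ 0.2 with the threshold inclusive, and the locus is
the min-to-max proxy span (half-open at max+1) — the spanning-interval
reading of an LD region. Haplotype *r*² is D²/(p_A p_a p_B p_b);
genotype *r*² is the squared Pearson correlation of dosages; a TSV of
precomputed *r*² values is accepted in place of panel computation. The
background is built per SNP (each SNP's own LD region), merged, and
any merged interval overlapping a risk locus is dropped entirely —
region-level exclusion is the conservative reading, and trimming
instead would keep bases whose LD mates sit inside risk loci.

## Enrichment and locus groups

Coverage fractions are base-exact (partial bins weighted by overlap)
and sum to one by construction. E = log₂ of the fraction ratio with
NaN (locus fraction 0) and +inf (background fraction 0) sentinels
propagated, never replaced by pseudocounts; medians exclude NaN and
treat +inf as the largest float. "Enriched for active elements" means
strictly E > 0 for at least one of {ActProm, StrEnh1, StrEnh2} — no
threshold beyond the sign is imposed. Locus groups follow a
deterministic rule on median-across-samples E: the Active family
positive puts a locus in group 1 (or 2 with transcription also
positive), else the Weak family in group 3 (or 4), else group 5. This
grouping is a reconstruction — a reasonable heuristic, not a fitted
classifier.

Permutation-based expected counts resample length-matched intervals
uniformly from the background (intervals chosen with probability
proportional to the number of admissible placements), with the +1
empirical-p correction. Placement matches lengths only — no GC or
SNP-density matching.

## Genotype reconciliation

The rule order is: information-measure cut (< 0.85) → probability
calling (uncertainty > 0.1 withholds the call; exactly 0.1 calls) →
CNA masking (both sources) → WGS validity (depth ≥ 10, quality flags,
normal = tumor) → per-sample concordance exclusion (< 90%) → per-SNP
WGS-only switch (< 90%) → WGS wins conflicts → WGS fills gaps.
Concordance denominators count calls non-missing in both sources; the
per-sample check can be restricted to a designated sentinel subset
(the fidelity-check SNPs), which is how a cohort can lose a discordant
sample without every SNP-level discordance also costing a sample.
Provenance codes (imputed / wgs_conflict / wgs_fill / wgs_only /
masked / excluded / missing) partition the output matrix exactly, and
the procedure is idempotent. Ancestry exclusion is consumed as a
precomputed flag; sample QC implements heterozygosity outliers
(> 3 SD) and relatedness as > 90% call identity, dropping the member
with the lower call rate.

## QTL scan

Latent confounders are removed by principal-component residualization:
components estimated on the column-standardized matrix, residuals of
the centered data orthogonal to the removed components. Defaults of
10/10/45/65 components per layer suit real-scale assays (hundreds of
thousands of features); the pipeline's synthetic runs residualize
exactly the number of planted factors, because removing 45 components
from an 80-feature synthetic matrix would absorb the signal itself.
The per-locus test window is the union of TADs intersecting the LD
region, applied to all layers for symmetry (the TAD restriction is
only strictly needed for expression); BH runs per layer across all
sentinel×feature tests. Dosage is the 0/1/2 risk-allele count;
regression drops missing dosages pairwise and requires ≥3 complete
observations and non-zero dosage variance.

## Allelic imbalance

Pooling sums counts over heterozygotes with per-sample reference ratio
inside the closed interval [0.1, 0.9]; testability requires ≥3
heterozygous samples with reads and ≥10 ratio-filtered pooled reads.
The null is fitted on pooled background-SNP counts (exclusion regions
removed first); at the default 2,000 background SNPs the MLE is stable
to a few percent, while fits on only a few hundred SNPs are noisy
enough to visibly distort downstream FDR calibration. The CI sample
size is the pooled read total — pooling ignores between-sample
variance beyond the beta-binomial, which is exactly the pooled model's
assumption.

## Motif scoring

The score is an information-content-weighted log-likelihood ratio
(relative-entropy weighting): a uniform column contributes nothing
regardless of the base. Normalized scores are max(0, raw)/max-score,
so the disruption delta lives in [−1, 1]; classification thresholds
(|Δ| ≥ 0.7 strong, ≥ 0.4 weak, boundary to the stronger label) are
configurable defaults, comparable within this package only. Score
p-values are exact 4^L enumerations for L ≤ 8; longer motifs use a
convolution over per-position contributions rounded to a 10⁻⁴ lattice
— the convolution is exact on the lattice, and the only approximation
is the per-position rounding (score error ≤ L·δ/2).

## Pipeline scale and determinism

The default end-to-end run (42 loci, 99 samples, 10 Mb genome, 2,000
background SNPs) completes in a few seconds; test-suite simulations
use 8-locus, 40-sample cohorts where distributional claims do not need
the full scale, and parameter-recovery runs use 5,000 SNPs where the
±15% claim does. Stage outputs are pure functions of (config, seed);
the run manifest records a config hash and every threshold, and a
matching hash short-circuits recomputation.

## Known limitations

Beyond the generator simplifications above: the locus-group rule is a
heuristic reconstruction; the permutation scheme resamples regions
(not labels) by length only; PEER is replaced by PCA residualization,
which removes linear latent structure but not the sparse priors PEER
imposes; differential-signal calling between cohorts (e.g. tumor vs
normal H3K27ac) is consumed as planted labels, not computed; and the
motif machinery reproduces scoring and p-values, not any specific
published tool's normalization.
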