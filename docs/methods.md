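# Methods

`breedscan` implements a selection-signature scan for multi-breed SNP-array
genotypes: per-SNP pairwise Fst by a mean-square (variance-components)
estimator, breed-specific standardization into the *di* statistic,
top-quantile outlier calling with ±50 kb candidate windows, gene
annotation, and a Balding–Nichols simulator that provides fully controlled
test data with a truth table. This note records the model, the numerical
conventions, and the design choices made where more than one convention is
defensible.

## The Fst estimator

For one SNP and one pair of populations, each diploid genotype contributes
two allele-indicator observations. With `s = 2` groups of allele-sample
sizes `m_i = 2 ×` (non-missing individuals), sample frequencies `p_i` and
weighted overall frequency `p̄`:

```
MSP = Σ m_i (p_i − p̄)² / (s − 1)          between-population mean square
MSG = Σ m_i p_i (1 − p_i) / Σ (m_i − 1)    within-population mean square
n_c = (M − Σ m_i² / M) / (s − 1),  M = Σ m_i
Fst = (MSP − MSG) / (MSP + (n_c − 1) MSG)
```

Conventions, each of which matters for exact reproducibility:

- **ANOVA units are allele observations**, two per diploid individual,
  the convention of the locus-specific Fst literature. A pair needs at
  least two non-missing genotypes per population; otherwise the SNP is
  undefined for that pair, recorded with a reason, and excluded from sums.
- **Negative estimates are retained.** At low differentiation the estimator
  is negative in expectation of its sampling noise (equal sample
  frequencies force `Fst = −1/(n_c − 1)` exactly). Clamping at zero would
  bias both the mean and the standard deviation that the *di*
  standardization divides by.
- **Boundaries**: `Fst = 1` exactly iff `MSG = 0, MSP > 0` (fixed
  difference); undefined iff both mean squares vanish (both populations
  monomorphic for the same allele). `Fst ≤ 1` always.
- **Missing data**: per-SNP, per-pair complete-case allele counts; no
  imputation.
- **Multi-locus combination is a ratio of sums**,
  `Σ(MSP − MSG) / Σ(MSP + (n_c − 1) MSG)` over the pair's defined SNPs —
  the standard weighting for variance-components estimators, stable under
  low-information SNPs. A mean of per-SNP ratios would up-weight noisy
  loci. When all SNPs share identical components the two coincide (tested).
- The linearized matrix is `Fst/(1 − Fst)`; a saturated pair (`Fst = 1`)
  linearizes to `+inf` and is flagged rather than silently propagated.
  Per-breed mean pairwise differentiation is the arithmetic mean of that
  breed's off-diagonal linearized entries; it is reported both unrounded
  and at 3 decimals, since published tables print 3 decimals and a mean of
  rounded entries can differ from a rounded mean of unrounded entries in
  the last digit.

## The di statistic

For focal breed `i`,

```
di = Σ_{j≠i} (Fst_ij − E[Fst_ij]) / sd[Fst_ij]
```

per SNP, with `E` and `sd` taken over all analyzed SNPs.

- **"All analyzed SNPs" is the common defined set**: the SNPs with a
  defined estimate in *every* pair. This makes each SNP's di a sum of
  exactly `n_breeds − 1` comparable z-scores and makes the constants
  identical whichever breed is focal; SNPs outside the common set are
  omitted and counted. Per-chromosome standardization was rejected as a
  genome-wide background is the natural null for a chip-scale scan.
- **Sample (n−1) standard deviation.** The difference to the population sd
  is negligible at chip scale but must be pinned for bit-reproducibility.
- Two identities follow by construction and are enforced in tests: each
  pair's standardized values have mean 0 / sd 1, and the mean di per focal
  breed is 0 to numerical tolerance (we assert |mean| < 1e-8).
- **Top-quantile selection**: the threshold is the empirical `1 − fraction`
  quantile (linear interpolation); SNPs with `di ≥ threshold` are selected,
  so ties at the threshold are included — deterministic and conservative
  toward inclusion. With all values tied, everything is returned.
- **Windows**: `[max(1, pos − flank), pos + flank]`, 1-based inclusive,
  default flank 50 kb; windows on a chromosome are merged when overlapping
  or book-ended (`end + 1 == start`). di is computed for any breed as
  focal; the machinery is breed-agnostic.

## Quality control

Four SNP filters in a fixed order — mapped/autosomal, call rate, MAF,
Hardy–Weinberg — each applied to the survivors of the previous one, so
per-criterion removals plus retained SNPs sum exactly to the input count.
Thresholds are strict as is conventional for chip QC command lines: pass
requires call rate > 0.95 and MAF > 0.05 (a SNP at exactly the threshold
fails), while HWE removal requires p strictly below 1e-4 (a SNP at exactly
1e-4 passes). Sample-level QC is out of scope.

The HWE test is **Levene's exact conditional test**: given the observed
allele counts, `P(het = h) ∝ n! / (n_AA! h! n_aa!) · 2^h`, and the
two-sided p-value sums the probabilities of all heterozygote configurations
no more probable than the observed one (ties included via a 1e-9 relative
slack in log space). The implementation uses log-gamma arithmetic; tests
compare it against an exact integer enumeration for every table with up to
50 individuals.

HWE (like call rate and MAF) is computed on all samples **pooled** by
default, matching a single-pass chip QC. Pooling structured samples
produces a heterozygote deficit at differentiated loci (Wahlund effect), so
a `per-breed` mode is provided that tests within each breed and removes a
SNP only if some single breed violates equilibrium; the trade-off is
demonstrated in a test.

## The simulator

`simulate_panel` draws, per SNP, an ancestral frequency `p` uniform on
`ancestral_maf_range`, then each population's frequency from
`Beta(p(1−F)/F, (1−p)(1−F)/F)` — the Balding–Nichols model, under which a
population's expected Fst to the ancestral pool is `F` — and genotypes as
binomial draws of two allele copies. Missing calls are injected
independently per genotype. "Planted selection" is an elevated `F`
(`selected_F`, default 0.5) at `n_selected` loci in one focal population:
this keeps planted loci polymorphic and Fst well defined, at the price that
the realized divergence of a planted locus is itself random (see
Limitations). Everything is deterministic given the seed.

Defaults emulate the study design the package targets: 4 breeds of
17/17/16/16 animals, 29 autosomes of 100 Mb, 10,000 SNPs (desk-scale;
`SimConfig.chip_scale()` switches to ~53K loci), background `F = 0.05` per
breed, 20 planted loci, 1% missing calls, ancestral frequencies uniform on
(0.1, 0.9). The breed divergence parameters are free parameters of the
testbed, not estimates for any real breeds — no divergence times or
effective sizes are published for them. Positions are drawn uniformly
without replacement per chromosome and sorted, as no map density is
specified for the chip.

What the simulator deliberately omits: linkage disequilibrium and haplotype
structure (every SNP is independent, so candidate "regions" contain exactly
the planted SNPs and their coincidental neighbours), demographic history
(splits, migration, admixture), sex chromosomes, and genotyping-error
models. Passing recovery tests therefore shows the statistic ranks truly
divergent independent loci correctly; it says nothing about LD-induced
clustering of signals or array artefacts in real data.

## Calibration and power at the default scale

On null panels the top-1% rule selects the tie-adjusted 1% by construction,
and the mean di is zero per focal breed. Planted-locus recovery in the
top-1% set at the default conditions (16–17 samples per breed, background
`F = 0.05`, `selected_F = 0.5`, 10,000 SNPs) averages roughly 30–40% across
seeds. Two effects bound it: the Balding–Nichols draw at `F = 0.5` is
`Beta(p, 1−p)`, which is broadly spread — a substantial fraction of planted
loci realize only modest frequency shifts and are genuinely not outliers —
and at ~16 samples per breed the per-SNP Fst sampling noise (sd ≈ 0.09 on
a null mean of 0.05) sets a high top-1% bar. Recovery rises with
`selected_F` and with sample size but the generative spread dominates;
planted loci are nonetheless enriched in the top set by ~30–40× over the
1% null expectation, which is the property the regular test suite asserts.

## qPCR relative expression

The Livak 2^−ΔΔCt procedure: technical replicates averaged on the Ct scale
per (sample, gene); ΔCt = Ct_target − Ct_reference per sample; ΔΔCt per
group and tissue against a declared calibrator group's mean ΔCt within the
same tissue; fold = 2^−ΔΔCt. The calibrator's own fold is 1 by
construction, a one-cycle ΔCt difference is a two-fold change, and
swapping calibrator and test groups inverts the fold. Per-sample fold
changes are emitted so significance testing can be done in any statistics
tool; amplification-efficiency correction (Pfaffl) is out of scope.

## Problem sizes

Tests and the acceptance script run at the desk scale above: 10,000-SNP
panels (about a second per full scan), exhaustive estimator checks at ≤ 6
samples per population, and exact-HWE enumeration at ≤ 50 individuals.
The chip-scale profile exists for users who want full-density runs.

## Known limitations

- The published pairwise differentiation table can be re-summarized (breed
  means, extreme pairs) from its printed entries, but the entries
  themselves cannot be re-derived without the study's genotypes; the
  multi-locus combination rule documented above is therefore a convention,
  not validated against that table.
- One published breed mean (the highland breed's 0.049) is not recoverable
  from the printed 3-decimal pairwise entries (which average to 0.048); it
  was evidently computed from unrounded values, so the package reports
  unrounded means alongside rounded ones.
- PLINK text round-trips are lossless only while both alleles of a SNP are
  observed; a monomorphic SNP's absent allele label cannot be recovered
  from PED text.
- The gene annotation is assembly-agnostic: chromosome naming differences
  are handled by an explicit alias table, and no promoter/flank extension
  is added beyond the candidate window itself.
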