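# Methods

This note records the models, conventions and numerical choices behind
each stage, what the synthetic generator does and does not emulate, and
the known limitations.

## HPV status calling (`opsccrna.hpv`)

A sample is called HPV-positive when its RNA-seq reads on the HPV
oncogenes satisfy E6 ≥ t or E7 ≥ t or Σ(E1,E2,E4,E5,E6,E7,L1,L2) ≥ t,
with t = 500 reads by default. Both clauses use ≥ ("at least"), and the
combined sum includes E6 and E7 — so E6 = E7 = 250 is positive through
the sum. The rule is monotone in every oncogene count; the firing clause
is reported for audit. The caller consumes a per-sample count table and
deliberately knows nothing about alignment: producing the oncogene counts
is upstream of this package.

## Normalization and differential expression (`opsccrna.expression`)

**TPM.** `rate_g = count_g / (length_g/1000)`, scaled so each sample sums
to 10⁶. TPM is used for correlation screens and survival binarization.

**Size factors.** Median-of-ratios: over genes with nonzero counts in all
samples, the median per sample of count / geometric mean. Exactly
scale-equivariant: doubling a library doubles its factor.

**DE test.** A deliberately plain negative-binomial Wald test, not a
re-implementation of any shrinkage estimator:

1. normalize counts by size factors;
2. per gene, estimate dispersion α in Var = μ + αμ² by method of moments
   from the Bessel-corrected pooled within-group variance, floored at
   1e-8;
3. LFC = log₂(μ̂_A + ½) − log₂(μ̂_B + ½) (pseudocount ½ stabilizes zeros);
4. delta-method SE: Var(log₂ μ̂) = (1/ln 2)² (1/(μ̂+½) + α)/n per group;
5. two-sided normal p, Benjamini–Hochberg FDR; significant ⇔ |LFC| > 1
   and FDR < 0.05.

With a batch column the contrast is estimated within each batch and
pooled by inverse-variance weighting — a transparent approximation of a
batch-adjusted design matrix. Batches must contain both groups.

*Calibration.* At n = 10 + 10 the plug-in dispersion and the normal (not
t) reference make the test mildly anti-conservative: the measured type-I
fraction at nominal 0.05 sits near 0.06–0.07 depending on the draw. This
is inherent to the unshrunken Wald construction and is documented rather
than patched; downstream stages consume ranks and thresholds, which are
insensitive to this margin.

**ΔΔCt.** ΔCt = Ct_target − Ct_reference per condition,
ΔΔCt = ΔCt_condition − ΔCt_control, relative expression 2^(−ΔΔCt)
(control ≡ 1). Ct values outside (0, 45) are rejected.

## Preranked GSEA (`opsccrna.gsea`)

Ranking is descending by the Wald statistic by default (robust to SE
differences); LFC ranking is available. Ties break lexicographically on
gene id.

The ES is the classical weighted Kolmogorov–Smirnov running sum: hits add
|stat|^p / Σ_hits |stat|^p (p = 1 default), misses subtract 1/(N − N_hits);
the ES is the extremum of largest magnitude. Numerical conventions: on an
exact magnitude tie between the positive peak and the negative trough the
positive extremum is reported, and all permutation tail counts use a
1e-12 slack so ties that are exact in rational arithmetic are not split
by floating-point noise. The leading edge is the hits at or before the
extremum (after, for negative ES).

The null is gene-level: k hit positions drawn uniformly without
replacement, one null sample per distinct set size (1000 draws by
default; exhaustive enumeration of all k-subsets available for small
lists, where it matches brute-force enumeration to 1e-12).
NES = ES / mean(|null ES| of the same sign); nominal p is the same-sign
null tail with a +1 pseudo-count; FDR compares each observed NES against
the pooled sign-matched null NES distribution (positive and negative
branches separately), clipped to [0, 1]. Set-size bounds default to
5–500. Phenotype permutation is intentionally not offered — the input is
a preranked list.

## Survival (`opsccrna.survival`)

Binarization uses the type-7 empirical quantile (the convention of
standard statistical environments); the high arm is *strictly above* the
cutoff, which keeps the high group the minority under ties at Q3. Genes
are split at Q3 of TPM, miRNAs at the median of raw counts.

Kaplan–Meier is the product-limit estimator over distinct event times;
at tied times events precede censorings, and censored subjects leave the
risk set after their time. Greenwood variance is computed for reporting
only. The log-rank statistic sums observed-minus-hypergeometric-expected
events over the pooled event times (χ² with 1 df, two-sided). RMST is the
exact step integral of the KM curve on [0, τ]; τ defaults to the smaller
of the two arms' maximum observed times so both integrals live on a
commonly observed window, and the reported difference is low − high.

## Correlation screens and deconvolution (`opsccrna.screens`)

Spearman ρ is Pearson on mid-ranks (average ranks on ties),
pairwise-complete; p from the t approximation with n − 2 df, or an exact
permutation p for n ≤ 8 (available to n = 10 on request). Screens flag
|ρ| > 0.4 with p < 0.05 in the configured direction, sorted for waterfall
display. Correlation matrices are symmetric with unit diagonal; a
constant gene yields NaN entries rather than an error. A worked-example
note: ρ is defined from n = 3 pairs (the minimum that makes it
meaningful), though screens require ≥ 4 shared samples.

Deconvolution solves min ‖S f − m‖² subject to f ≥ 0 and Σf ≤ 1 by NNLS
on an augmented system (a heavily weighted sum row plus a non-negative
slack variable, weight 10⁶·max|S|); 1 − Σf is the uncharacterized
remainder. Scale convention: signature columns are cell-type expression
profiles on a *common column total*, and the mixture is total-normalized
onto that scale before fitting, making fractions invariant to the
mixture's units. The remainder is therefore interpretable only when the
unmodeled compartment carries comparable library mass on the marker
panel — the situation the synthetic mixtures construct. A rank-deficient
signature triggers a warning and is flagged in the result. The TIL10
signature and quanTIseq's own filtering/scaling are out of scope; the
deconvolver is generic with a pluggable signature.

## miRNA seed-site scanning and triage (`opsccrna.mirna`)

The seed is miRNA nucleotides 2–8 (5′→3′). The scanner finds reverse
complements on the UTR sense strand and classifies: 8mer (positions 2–8
matched + A opposite position 1), 7mer-m8 (2–8), 7mer-A1 (2–7 + A), 6mer
(2–7). Matching is strict Watson–Crick, no G:U wobble; T ≡ U; coordinates
are 0-based half-open with the matched substring reported. Overlapping
classifications at one core location collapse to the highest-priority
type, so no position is double-reported. miRNAs sharing a mature sequence
are collapsed into one entry keyed by the joined ids.

Triage: (1) negative correlation screen (ρ < −0.4, p < 0.05) of miRNA
raw counts against target expression; (2) ≥ 1 canonical seed site in the
target 3′UTR, with the intersection reported Venn-style; (3)
median-binarized survival per surviving miRNA, flagging an inversion when
the low-expression arm has the lower RMST. The survival step is
direction-only — significance is reported alongside but not required, as
a three-gene candidate shortlist is a hypothesis generator, not a test.
Database-dependent target predictions are intentionally replaced by the
built-in scanner, so external-database candidate counts are not
reproducible by design. Thermodynamic and conservation scoring are out
of scope.

## Scratch-assay quantification (`opsccrna.imaging`)

Per-pixel Shannon entropy (bits) of the intensity histogram in a disk
footprint, computed on the 8-bit scale with mirror padding at borders
(the image is reflected by the radius before the rank filter runs, so
border pixels see a full footprint). The footprint radius is not a given
of the assay; the default is 5 px, it is configurable, and results are
radius-sensitive — the output records it. The Otsu threshold histograms
the entropy map into 256 bins over [min, max] and returns the bin edge
maximizing between-class variance, taking the lowest edge on plateau
ties. A = count of pixels with entropy strictly below the threshold;
open-wound % = 100 · A_t / A_0 with A_0 from the first frame — exactly
100 at t0, unclamped above 100 (wounds can widen). The threshold is
recomputed per frame by default (`t0_fixed` reuses the first frame's
threshold for dim series). RGB input is luma-converted. No morphological
cleanup is applied by default; none is part of the measurement's
definition.

Because entropy smears over the footprint, the measured area
underestimates the true wound by a boundary band of roughly the radius on
each edge — at 256×256 and radius 5 this stays under 5% of the frame for
wound fractions in [0.1, 0.6], which is the accuracy the tests pin.

## Synthetic data (`opsccrna.synthetic`)

The generator emulates a two-arm OPSCC cohort and all sidecar assays;
every generator is a pure function of (config, seed), default seed
20240228.

- **Counts.** NB(μ, α) with Var = μ + αμ² via gamma–Poisson; gene means
  log-uniform over 10¹–10³; α = 0.1; cohort 23 vs 39 samples (the
  HPV-negative/positive split of a 62-patient cohort). A planted set of
  50 genes carries +2 log₂FC in the negative arm. A hub gene and three
  partner genes share a per-sample latent factor through a Gaussian
  copula at Pearson r = 2 sin(πρ_s/6) so the *Spearman* correlations hit
  the configured targets (0.62, 0.82, 0.69 — the strength of a hub
  TF/partner module); NB marginals come from the latent CDF transform.
  The hub and partners are excluded from the planted DE set so their
  cross-sample variation is the latent factor rather than the group
  shift — otherwise the group contrast would dominate the copula signal
  and confound both the correlation screen and the survival direction.
  An optional two-level batch shift (off by default) multiplies a random
  20% of genes in one batch.
- **Survival.** T ~ Exponential with log-hazard β·z (z = standardized
  expression; β = 1 by default, giving a hazard ratio of e per SD — an
  effect of the order a strongly prognostic transcript shows), baseline
  median 60 months. Censoring is independent uniform: C ~ U(0, c_max)
  with c_max calibrated by root-finding so the expected censored fraction
  equals the configured rate (0.79, matching a cohort with 79% alive at
  last follow-up); observed time is min(T, C).
- **Images.** 256×256 8-bit frames: high-variance speckle (σ = 40) for
  the monolayer, near-constant intensity (σ = 1.5) for the wound band,
  whose width tracks the configured area fraction with a zero-mean
  sinusoidal edge perturbation (whole periods) so Otsu faces a realistic
  boundary; the true mask is returned. A zero texture σ is refused —
  wound and monolayer would be indistinguishable by construction.
- **miRNA system.** One repressor (copula ρ = −0.7 to the target, 8mer
  site planted in a 500-nt random UTR), one equally anti-correlated miRNA
  whose seed matches are actively scrubbed from the UTR, one uncorrelated
  miRNA with a planted site, and 10 background miRNAs. Together with
  survival driven by the target, exactly the repressor should survive
  triage.
- **Signature mixtures.** Block-structured marker signature (5 dedicated
  markers per type, columns on a common total) plus an extra marker block
  carrying an unmodeled "other" profile; mixtures are S·f with Dirichlet
  fractions scaled below 1, so both the fractions and the remainder are
  exactly recoverable in the noiseless case. A dense log-normal variant
  (fractions summing to 1) covers the general-signature case.

What the generator does **not** emulate: read-level sequencing noise, GC
or length biases, batch structure beyond one two-level shift, non-NB
overdispersion, informative censoring, competing risks, cell-type
expression heterogeneity within a signature, imaging artifacts
(vignetting, debris, focus drift), or non-canonical miRNA pairing.
Passing tests therefore demonstrate correctness of the statistical
machinery under its stated model, not robustness to those real-data
effects.

## Pipeline (`opsccrna.pipeline`)

Stages communicate through files, never in-memory state, so each is
independently re-runnable; every TSV is written with 6-significant-digit
floats and each run writes a manifest (outdir-relative paths, thresholds,
seed, version), making reruns with the same config byte-identical.
Cohort summaries report counts and percentages of the full cohort,
rounded half-up to one decimal, with missing values as their own level.
The group contrast is "A vs B" in metadata label order; with the default
labels the HPV-negative arm is A, so planted enrichment appears with
positive NES. The command-line surface is the set of numbered drivers in
`analysis/`; the library functions are the stable API.

## Problem sizes

Defaults were chosen as the smallest sizes at which each statistical
claim is comfortably identifiable: 2000 genes for FDR calibration, 500
replicates for type-I rates (SE ≈ 1%), 100 cohorts of 200 for direction
probabilities, 1000 permutations for GSEA (the permutation count the
workflow standardizes on), 100 random pairs for the seed-scanner oracle.
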