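# Methods notes

## Data model

Measurements live in a single long/tidy table keyed by (patient, tissue,
method, gene); each method is globally quantitative or categorical, and
missing data is row absence — there are no sentinel values. All pairwise
comparisons are complete-case: a sample enters a comparison only when both
sides measured it. The canonical iteration order is ascending lexicographic
patient id (and alphabetical tissue within patient), so every output is
deterministic for a given input.

## Discretization

The threshold rule maps x ∈ [1.5, 2.5] to the diploid state, below to
deletion, above to amplification; both boundaries are inclusive, so the
rule is total and monotone in x. The alternative vendor band rule keeps a
value only when it is within ±0.4 of an integer (≤1 deletion, 2 normal, ≥3
amplification) and excludes the open gaps (n + 0.4, n + 0.6). Two numerical
choices: rounding is half-away-from-zero (half-integers are moot — they are
0.5 from either integer and always fall in a gap), and the band comparison
carries a 1e-9 tolerance so decimal boundaries such as 4.4, which have no
exact binary representation, remain inclusive. States beyond three (e.g.
single- vs two-copy loss) are deliberately collapsed.

## Normal-tissue QC

Assay trustworthiness is judged on normal tissue only, where the expected
copy number is 2. A (method, gene) group is dropped when the median of its
normal-tissue values leaves [1.5, 2.5] (midpoint convention for even n;
boundaries inclusive; the two exclusion conditions are disjunctive since a
median cannot be both below 1.5 and above 2.5). A reference-gene
configuration — all methods normalized against one reference gene — is
dropped wholesale when more than a threshold proportion (default 0.5; the
criterion is inherently a judgment call, so the threshold is exposed) of
its pooled normal-tissue values leave that window. Tumor values never
influence QC.

## PABAK

PABAK = (k·Po − 1)/(k − 1) with Po the observed agreement. k is the number
of *defined* categories (3), not of observed ones, so sparse tables do not
silently change formula; a 2×2 table uses k = 2 and recovers 2·Po − 1. The
statistic is symmetric under transposition and invariant to consistent
label permutation, and strictly increases when mass moves onto the
diagonal. Agreement bands follow the conventional cut-points (≤0.20 poor,
≤0.60 moderate, ≤0.80 substantial, above near-perfect; negative values are
labelled as such). In matrices, (gene, pair) cells with no aligned calls
are reported as missing — never as zero — and medians are taken over
available cells only; gene rows are emitted in decreasing per-gene median
order, the standard display convention for these panels. Tumor and normal
samples are pooled by default, with a tissue filter available.

## Passing–Bablok regression

All pairwise slopes S_ij for i < j are computed; pairs with x_i = x_j
contribute no slope, and slopes exactly −1 are discarded (they carry no
information about the shifted median). With N valid slopes and K of them
below −1, the slope estimate is the (N odd) rank-(N+1)/2 + K order
statistic or (N even) the mean of ranks N/2 + K and N/2 + 1 + K. The
intercept is median(y − k·x). Slope CI bounds are the order statistics at
ranks M1 + K and M2 + K, where M1 = round((N − C)/2) with half-to-even
rounding, M2 = N − M1 + 1 and C = z_{1−α/2}·√(n(n−1)(2n+5)/18); the
intercept CI pairs each slope bound with the median residual of the
opposite bound. When n is small enough that a rank falls outside [1, N]
(e.g. n = 4 at α = 0.05), the rank is clamped to the extreme order
statistic — the conservative full-range CI — and the results object records
`ci_clamped`; this keeps the bias flags defined for degenerate exact-linear
inputs, where the slope set has zero width anyway. Bias flags: proportional
iff CI(k) excludes 1, constant iff CI(b) excludes 0.

The relative discrepancy uses the absolute difference, d_i = |y_i − x_i| /
max(x_i, y_i), defined as 0 when both values are 0: it is a magnitude, is
plotted as non-negative, and must be symmetric in the two methods.
Quartiles use the linear-interpolation convention. Panels pool points
across genes and samples shared by a method pair (one scatter per pair);
per-gene fits are available behind a flag.

## Differential testing

Per (gene, method), a two-sided paired Wilcoxon signed-rank test of tumor
vs normal. Zero differences are discarded before ranking (the classic
convention — chosen over Pratt's so the exact-enumeration null is
well-defined); the exact distribution is used for n ≤ 25 tie-free absolute
differences, otherwise the normal approximation with continuity
correction; if every difference is zero the test is uninformative and p = 1
is returned with a warning. Per gene, available per-method p-values are
pooled by the *plain* harmonic mean m/Σ(1/p_i) (not the calibrated
harmonic-mean-p procedure — the reference-table arithmetic confirms the
plain version); absent methods are skipped, never imputed. Holm is applied
across genes only. Full precision is kept internally; report tables add
3-decimal display columns, and the bundled reference table's corrected
column is reproduced by applying Holm to the pooled column at its displayed
precision, which is how that table's own arithmetic was done. Pooled
p-values in (0.05, 0.1) are annotated as trend-level; the annotation never
affects computation. Spearman rank correlation (average ranks, t
approximation) is included as a minor report statistic.

## Synthetic cohorts

The generator's defaults mirror the benchmarking study design it is built
to exercise: 13 patients with paired tumor/normal samples, an 87-gene
cancer panel, and five platforms — two categorical callers on a shared
microarray signal with symmetric 10% misclassification each, a quantitative
hybridization panel with a positive constant bias, and two near-identity
quantitative PCR chemistries (noise sd 0.2 and 0.15 respectively).
Specific default values:

* Latent tumor CN per gene ∼ {0: 0.03, 1: 0.13, 2: 0.74, 3: 0.07, 4: 0.03}
  — mostly diploid, deletions ≈1.6× as frequent as amplifications, as
  targeted panels typically observe in high-grade serous tumors.
* Normal tissue is diploid everywhere (no germline events).
* Tumor purity per patient ∼ Uniform(0.5, 0.9) unless fixed; dilution is
  linear two-compartment mixing, the simplest model consistent with bulk
  intratumor heterogeneity, so effective CN = 2 is purity-invariant.
* The panel platform's constant bias is +0.3 copies: positive (the panel
  reads high relative to PCR) but small enough that its normal-tissue
  medians stay inside the [1.5, 2.5] QC window — a platform whose default
  parameters fail its own QC would make an incoherent default roster.
* Quantitative noise is Gaussian truncated at 0; truncation slightly
  biases extreme deletions upward.
* An optional shared-noise term (default off) perturbs the common signal of
  a categorical caller group before discretization; real inter-platform
  noise correlations are unknown, so no value is asserted.

What the generator does *not* emulate: probe/droplet-level detail, GC or
homology artifacts, subclonal mixtures beyond the single purity parameter,
germline CNVs, or batch effects. Tests passing on synthetic cohorts
therefore validate the statistical machinery and its calibration under the
stated noise model — not platform-specific artifact behavior on real
tissue.

## Problem sizes in the test suite

Stochastic guarantees are checked at sizes chosen to keep the full suite
fast while leaving comfortable margins: bias-flag recovery uses 100
replicates of 50 pooled points (noise sd 0.1, offset 0.5 or factor 1.3);
family-wise error control uses 200 fully null cohorts of 8 genes × 13
patients × 2 platforms; the Passing–Bablok estimator is checked against
brute-force enumeration on 500 random datasets with n ≤ 8 plus the
exhaustive set of 5004 small contingency tables for PABAK.

## Known limitations

* The Passing–Bablok CI is the classical rank approximation; no bootstrap
  alternative is provided, and tiny-n CIs are conservative (clamped).
* The harmonic mean of dependent p-values is a summary, not a calibrated
  test; family-wise control comes from the Holm step across genes.
* Cohen's/weighted kappa, Deming regression and Bland–Altman limits are out
  of scope by design.
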