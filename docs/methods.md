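# Methods

## The model

`rhmap` maps trait-associated genomic windows in clonally propagated
panels by regional heritability: instead of testing single markers, each
run of 100 consecutive SNPs (advancing by 50, so adjacent windows share
half their markers) becomes its own variance component. For plot-level
records `y` the two-kernel linear mixed model is

    y = Xβ + Z u_seg + Z u_bg + e
    u_seg ~ N(0, σ²_seg K_seg),  u_bg ~ N(0, σ²_bg K_bg),  e ~ N(0, σ²_e I)

with `X` the fixed design (grand mean plus trial-within-year-within-
location cells, reference cell dropped), `Z` the plot→clone incidence, and
`K_seg`, `K_bg` VanRaden genomic relationship matrices built from the
window's SNPs and from all genome SNPs respectively. The background
kernel absorbs polygenic variation and doubles as the population-structure
control. The window's genomic heritability is

    h²_seg = σ²_seg / (σ²_seg + σ²_bg + σ²_e)

and significance comes from a likelihood-ratio test against the shared
background-only null (one fit per scan), with p-values from the χ²₁ upper
tail. Because σ²_seg sits on the boundary under the null, that p-value is
conservative; the boundary-correct ½χ²₀ + ½χ²₁ mixture is available via
`lrt(..., mixture=True)` but is not the default.

Per-segment p-values are converted to q-values and local false discovery
rates (LFDR) by a re-implementation of the Storey estimator family: π̂₀
from tail counts over a λ grid (0.05…0.95) smoothed by a cubic polynomial,
step-up q-values, and an LFDR from a Gaussian kernel density of the
p-values on the probit scale (Silverman bandwidth), with the density
forced monotone non-increasing in p before the ratio π̂₀/f̂(p). Windows
overlap, so the tests are positively dependent; the estimators are applied
to the full set anyway (conservative for π̂₀) and no effective-test
correction is made. Segments at LFDR ≤ 0.05 are called significant; the
largest p-value among them is the scan's empirical threshold on the p
scale, which the power simulation consumes.

## GRM construction

G = M Mᵀ / (2 Σ p(1−p)) with M the column-centered dosage matrix. The
centering question (frequency-centering versus a literal −1/0/1 coding) is
resolved in favor of frequency-centering, which is what the 2Σp(1−p)
denominator presumes; `coding="raw"` retains the literal coding for
comparison. Monomorphic markers contribute nothing under frequency
centering and are dropped with a logged count rather than raised, except
that an entirely monomorphic subset is an error. No diagonal bending by
default; `ridge=1e-6` is available for near-singular downstream solves.

## REML

Variance components maximize the restricted likelihood. The engine uses
EM updates — monotone by construction and safe at the zero boundary —

    σ²_k ← σ²_k + σ⁴_k (y′P G_k P y − tr(P G_k)) / q_k

with an average-information Newton step attempted after a 3-iteration
burn-in, backtracked (step fractions 1, ½, ¼, 0.1, 0.01) and accepted only
when feasible and likelihood-improving; components pinned at the floor
with a negative gradient are excluded from the Newton step. Kernel
components are floored at 10⁻¹⁰ × Var y; the residual is floored at
10⁻⁶ × Var y, because below that the restricted likelihood is flat for
PSD kernels while V turns numerically singular (genuine σ²_e ≈ 0 optima
do occur here: the desk-scale GRM has a compressed eigenvalue spread, so
σ²_bg and σ²_e are only weakly identifiable). Convergence is a relative
log-likelihood change below 10⁻⁸ (default, max 1000 iterations), never
declared before the first Newton attempt; non-convergence is reported,
not hidden, and if float wobble on a flat ridge ever decreases the
likelihood beyond a 10⁻⁵ relative slack the engine stops at the best
iterate. In the scan, each alternative fit warm-starts at the shared
null's optimum with a near-zero segment component, so its likelihood can
only climb from the null's and LRT statistics cannot go materially
negative (residual float noise below 0.05 is clamped to zero, which is
conservative). The restricted log-likelihood is
reported without its data-independent constant, identically for all models
on the same data, so nested differences are exact LRT statistics.

Single-kernel models (the scan's null, whole-genome heritability, the
Model-3 reference fit) take an exact fast path: eigen-rotation of
V = σ²_e(I + λ G), profiling out σ²_e, and a bounded scalar search over
log λ ∈ [−25, 25]. The fast path evaluates the same constant-free
log-likelihood expression, so LRTs may mix the two paths freely.

BLUPs are back-solved at the estimates: û_k = σ̂²_k K_k Z′V⁻¹(y − Xβ̂),
which satisfies the decomposition Σ_k Zû_k + ê = y − Xβ̂ exactly (a unit
test asserts this to 10⁻¹⁰).

## Candidate validation (Models 2 and 3)

A candidate SNP set (markers within 2.5 kb of a gene list, or within a
1-Mb span centered on scan hits) partitions the genome into kernels K_s
(candidates) and K_g (the rest). Model 2 is the two-kernel model above
with these kernels. Accuracy is estimated by 5-fold cross-validation with
10 repeats: per fold, Model 2 is fitted on the training clones' plots and
held-out clones' candidate effects are predicted through the candidate
kernel's train–test cross-covariance at the training REML estimates,

    ŝ_test = σ̂²_s K_s[test, train] Z′_tr V⁻¹_tr (y_tr − X_tr β̂).

Per repeat, the pooled held-out ŝ is correlated with the Model 3 clone
values — a single-kernel fit with identity covariance (clones treated as
unrelated) fitted once on all data, not per fold. Model 3's identity
covariance follows its distributional statement; a GRM override gives the
whole-genome-accuracy variant. Reported accuracy is the mean and SD over
the 10 repeat cycles.

The pathway-enrichment helper computes expectation = region × pathway /
genome and, following the Poisson-process reading, the Poisson point mass
at the observed gene count; a hypergeometric variant is one flag away.
For the published counts (650 region genes, 123 pathway genes, 33,030
genome genes, 3 observed) the expectation is 2.42 and the Poisson pmf
0.2125 — the source prints 0.22, a one-digit rounding-level discrepancy
the acceptance suite records rather than hides.

## Hide-a-causal-SNP power simulation

Per test: five adjacent windows are chosen at random on a chromosome; a
random SNP in the middle window receives an effect β = ±√(f·Var(y)/Var(x))
with f = 0.10, which inflates the phenotypic variance by 10% (the literal
reading; `post_injection_share=True` instead makes the QTL hold 10% of the
post-injection variance). The injected SNP is masked from the causal
window's GRM and, by default, from the background kernel too; because
adjacent windows overlap by half, the SNP always remains inside exactly
one flanking window's kernel, so detection comes either through linked
markers in the masked window or through the flank that still carries the
SNP — which is precisely why adjacent-segment capture is worth tallying.
A flag restores background inclusion. The
five windows are each tested against the shared background-only null, and
the test is detected if any window's p-value falls below 0.00024 (the
published empirical LFDR-0.05 threshold, used directly rather than
re-derived per replicate). Adjacent-only capture — a flanking window
significant while the middle window's p is higher — is tallied separately
to inform how far candidate-gene extraction should reach. The full-scale
tally, which `scripts/acceptance.py` runs, is 12 repetitions × 18
chromosomes = 216 tests (binomial SE near 0.03); the in-suite check uses
4 × 18 = 72 tests to keep the suite interactive.

## Synthetic data

Genotypes: per chromosome, marker positions are uniform draws and allele
frequencies uniform on [maf_min, 1−maf_min]; haplotypes follow a
first-order copying chain (repeat the previous marker's allele with
probability `ld_rho`, else draw fresh at the population frequency), and
dosage is the sum of two haplotypes. Markers below the realized MAF floor
are removed. The chain has a single dial for adjacent-marker LD and
nothing else: no long-range LD, recombination hotspots, allele-frequency/
LD coupling, genotyping error, or missingness (upstream data are assumed
imputed). Defaults — 451 clones, 18 chromosomes, 300 SNPs/chromosome,
maf_min 0.05, ld_rho 0.7 (measured adjacent r² ≈ 0.5, a moderate-LD
regime; real GBS panels are ~30× denser with near-perfect adjacent r²) —
are the package's study conditions.

Phenotypes: y = grand mean + trial effect + Σ β_q·dosage_q + polygenic
background + residual. The background is drawn with covariance
proportional to the whole-genome GRM of the simulated panel itself (so the
scan's background kernel is correctly specified under the null) and
rescaled to hold exactly `h2_background` of the total phenotypic variance
in sample; QTL effects are sized against realized dosage variance with
random sign. Total phenotypic variance is residual_variance / (1 −
h2_background − Σ QTL fractions); heritability fractions are defined net
of fixed effects. Trial effects are N(0, fixed_effect_sd²) per
trial-within-year-within-location cell; clones land in one plot each by
default (augmented, unreplicated entries), with `plots_per_clone` and an
unbalanced `trials_per_cell` override available.

Because the generator is this simple, a passing suite shows that the
machinery is correct under its stated assumptions — not that the scan
would behave identically on real GBS data with block LD structure,
relatedness clusters, or genotype-by-environment interaction.

## Problem sizes and numerical choices

The test suite runs its heavier checks at deliberately reduced sizes, a
package design choice so the full suite stays interactive: REML
calibration at 60–400 clones, the scan's type-I calibration on a 150-clone
× 3-chromosome panel with 20-SNP windows (~177 null segments), CV ordering
at 200 clones, power monotonicity on a 150-clone panel with shared seeds
(common random numbers make the monotonicity exact per test), and one
shared 451-clone 72-test power run. Ties and degenerate inputs: variance
components are floored, never negative; LRT statistics are clamped at
zero; an all-monomorphic kernel subset, a singular fixed design, a
zero-variance response, and out-of-range dosages are hard errors.

## Known limitations

- The copying-chain LD model understates long-range LD; power transfers
  to real panels only qualitatively.
- The scan refits every window against one shared null; with
  `exclude_segment_from_background` the null is refitted per window and
  the scan is ~2× slower.
- LFDR needs ≥ 50 tests; smaller scans fall back to q-values.
- No multi-trait models, spatial adjustment, dominance kernels, or
  marker-effect (SNP-BLUP) parameterizations.
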