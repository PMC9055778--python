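# Methods

## Scales and edge cases

Methylation is carried as β = Meth/(Meth + Unmeth) ∈ [0, 1] for
interpretation and clustering, and as M = logit2(β) for correction:
location/scale adjustment on a bounded scale can leave the unit interval,
while M is unbounded and maps back through the stable inverse
β = 2^M/(1 + 2^M) (computed from exp2(−|M|) so that |M| ~ 1000 yields a
subnormal β rather than overflow).

`shift_betas` prepares a β matrix for the logit transform: missing cells
(both signals zero) become β = 0.5 (M = 0), exact 0/1 become ε and 1 − ε
(ε default 1e−4: small relative to the 0.01 shift cut-off, large enough to
keep |M| < 14), and probes that are constant after substitution get i.i.d.
Gaussian noise of SD 1e−8 on the β scale. Noise is confined to
zero-variance probes because its only purpose is to keep the
variance-dividing empirical-Bayes standardisation defined on constant
features; with zero noise the operation is idempotent. The noise is added
on the β scale before the transform (the alternative — on M — changes
nothing material at SD 1e−8; the choice is configurable by transforming
first). `signals_to_beta` emits missing for both-zero cells regardless of
the offset, so the 0.5 substitution is applied uniformly downstream; the
offset defaults to 0, with 100 available for parity with common pipelines.

## Modal-probe detection

Univariate k-means is solved exactly: for sorted data the optimal partition
is contiguous, and a dynamic programme over prefix sums (O(k n²), numba-
compiled) returns the global minimum within-cluster sum of squares for all
k ≤ kmax at once. Data are centred before the DP to avoid cancellation on
near-constant probes.

Model selection: each k ∈ {1..4} is scored with a hard-assignment Gaussian
mixture BIC — cluster-specific means and (floored, 1e−6) variances and
mixing proportions n_c/n, parameter count 3k − 1, orientation
BIC = 2 log L − (3k − 1) log n (larger better). The mixing-proportion term
is what keeps a single Gaussian from being split profitably. The two
best-scoring k are candidates; a candidate qualifies only if every cluster
has ≥ 5 samples and adjacent centroids are ≥ 0.1 β apart (the separation
rule is stated in β units, which is why clustering runs on β, not M). The
largest qualifying candidate wins, k = 1 always qualifies, BIC ties break
toward smaller k, and any k > 4 is recoded to 4.

Two-stage protocol: stage 1 selects k on the samples outside a caller-
supplied list of excluded slides (slides with the strongest batch-effects,
typically chosen from PCA review — automatic selection is deliberately out
of scope); stage 2 re-clusters all samples at that k, so every sample is
assigned. With an empty exclusion list the result equals single-stage
selection.

## Correction back-ends

`eb_location_scale` is the parametric empirical-Bayes location/scale
algorithm: per probe, a linear fit of batch indicators plus declared
covariates (categoricals dummy-coded, continuous linear); standardisation
by the covariate fit and the pooled residual SD (variance computed with
denominator n); per-batch location γ̂ and scale δ̂² on the standardised
scale; normal prior on locations and inverse-gamma on scales with
hyperparameters from the method of moments across probes; posterior
estimates iterated to a relative tolerance of 1e−4 (max 100 iterations);
adjusted data rescaled and the covariate fit restored. The reference
distribution is the covariate-adjusted grand mean (batch-size-weighted); no
reference batch. Continuous covariates enter linearly by default; a
dichotomisation helper threshold (e.g. a 6% immune-fraction cut) is left to
the caller's sample sheet. A single-level batch yields a no-op model;
zero-variance probes and batch-covariate confounding are rejected with
explicit messages. The implementation is cross-checked in the test suite
against Bioconductor's sva::ComBat on a fixture (agreement to 1e−4).

`mean_center` subtracts per-batch means of covariate-fit residuals — no
scale adjustment, idempotent. It stands in as the deliberately simple
second back-end; a constrained-PCA corrector is not implemented.

## Diagnostics

Cluster assignments are frozen from the pre-correction clustering: the
statistic must register clusters that correction destroyed, which
re-clustering the corrected data would mask. LVR = log2(s²_post/s²_pre)
with the cluster-aware variance defined in the README; probes with zero
pre-variance receive a missing LVR and remain in the table (their β shift
is still reported). The mean β shift uses the absolute convention — a
signed mean would let opposing batch moves cancel and defeat the ≥ 0.01
gate — with a signed variant available for sensitivity analysis. The
maximal probe-wise β difference is the span max(Δβ) − min(Δβ) over samples
and is binned low (< 0.01), moderate ([0.01, 0.10], closed because the
neighbouring bins are open), high (> 0.10). Classification comparisons are
non-strict at the cut-offs; the cut-offs are log2(1.5) ≈ 0.584 and 0.01 by
default and configurable. Exported reference matrices round numeric columns
to 4 decimal places.

## Association tests

Fisher's exact test is computed by full enumeration of margin-preserving
tables (log-gamma arithmetic, probabilities ≤ that of the observed table
summed). Tables with more than 30 cells, or whose enumeration bound exceeds
2×10⁶ tables, raise an explicit error directing the caller to the
Monte-Carlo χ² test (p = (1 + #{χ²_perm ≥ χ²_obs})/(B + 1), B default
10,000, vectorised permutations, seeded). scipy's r×c `fisher_exact` is
Monte-Carlo, hence the in-package enumeration; scipy's exact 2×2 path is
used directly. Cell composition uses a one-way ANOVA F test.

The HWE exact test (Levene–Haldane: the conditional distribution of the
heterozygote count given allele counts) is applied to autosomal probes with
2 or 3 clusters, mapping ordered cluster sizes to genotype classes — for
k = 3 the middle cluster is the heterozygote; for k = 2 the larger cluster
is taken as the common homozygote, the smaller as the heterozygote and the
absent class as 0, which makes rare-allele-like patterns (e.g. 81/18)
HWE-consistent. "In HWE" means non-rejection at the adjusted threshold.
P values are BH-FDR adjusted within factor across probes (via statsmodels);
associations use adjusted p < 0.001. A probe may carry several factor
flags; probes with none are labelled unknown.

## Synthetic studies

The generator emulates the structure the diagnostics assume, additively on
the M scale, then converts to β. Defaults define the reference study:
8 slides × 12 arrays (96 samples) in 2 superbatches; 2,000 probes — 1,400
clean, 200 batch-susceptible (per-probe per-slide shifts ~ N(0, 0.5 M) plus
a 0.03 M-per-row slide-position trend), 150 ASM trimodal (β centroids
0.1/0.5/0.9, genotypes i.i.d. HWE at maf 0.3), 100 gender-bimodal
(β 0.25 vs 0.75, males higher), 100 cell-gradient (slope 4 M per unit cell
fraction; fractions from a 80/20 mixture near 0.03 and 0.30), 50
boundary-constant (exactly constant at β ≈ 1e−4 or 1 − 1e−4, exercising the
zero-variance path); observation noise SD 0.15 M. Gender and treatment are
blocked across slides, as a careful design would be; genotypes cannot be
blocked, and in the default unbalanced mode each ASM probe's genotypes are
sorted along the slide order (minor homozygotes first) with 10% of
positions re-shuffled — the configuration under which an undeclared
genotype is erroneously corrected. Balanced mode leaves genotypes random.

What the generator does not emulate: probe-type (I/II) signal differences,
dye bias, spatial correlation beyond the linear row trend, correlated
slide severities across probes, cell-type deconvolution error, or missing
data patterns. Passing recovery tests therefore demonstrate the statistics'
behaviour under the assumed additive-on-M model, not performance on raw
array data.

One quantitative consequence of honest HWE sampling: with maf 0.3 and 96
samples the minor-homozygote count is Binomial(96, 0.09), so about 6% of
ASM probes have fewer than 5 minor homozygotes and are capped at k = 2/1 by
the minimum-cluster-size rule; expected k = 3 recovery is ~94%, varying a
few points with the seed.

## Problem sizes and determinism

The reference study (2,000 × 96) runs end to end in well under a minute;
calibration checks use 1,000 null replicates with B = 999 permutations.
All randomness flows from explicit seeds (numpy Generator); pipelines are
deterministic given config and seed, and exports are byte-stable.

## Known limitations

* Exact Fisher enumeration is practical only for small tables (the 30-cell
  /2×10⁶-table guard); larger tables fall back to the seeded Monte-Carlo χ².
* Absolute Tm values depend on the strand-concentration constant (default
  C_T 0.25 µM) and carry no salt correction; only relative/threshold use is
  meaningful. The internal-CpG count treats "CR" as a degenerate CpG; exact
  manifest semantics for real arrays may differ.
* The HWE test is applied to cluster sizes, not re-thresholded genotype
  calls; misassigned samples near cluster boundaries perturb the counts.
* Correction assumes batch effects are additive location/scale on M;
  multiplicative or rank-distorting artefacts are out of model.
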