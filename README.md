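# methbatch

Post hoc batch-effect diagnostics for Infinium-style DNA-methylation
matrices (450K/EPIC-like probe × sample β matrices).

## The problem

BeadChip methylation arrays are processed a glass slide (8–12 arrays) at a
time, several slides per run, and systematic slide-level technical variance
— batch-effects — survives even careful preprocessing. Batch-correction
tools (ComBat-style empirical-Bayes adjustment) remove this variance, but
they only know about *sample-wise* biological covariates the analyst
declares (gender, cell composition). *Feature-wise* biology — above all
allele-specific methylation (ASM), where a SNP at the probed CpG makes the
cohort's β values trimodal — cannot be declared. When such clustering is
unevenly spread over slides, the corrector mistakes it for technical
variance and collapses biologically meaningful clusters.

`methbatch` implements the diagnostic workflow that detects both failure
modes after correction:

1. **Modal-probe detection.** Per probe, exact univariate k-means (dynamic
   programming over contiguous partitions of the sorted β values) with BIC
   selection of k ∈ {1..4}, under the acceptance constraints that every
   cluster has ≥ 5 samples and adjacent centroids differ by ≥ 0.1 β. A
   two-stage protocol first fixes k with the worst-affected slides set
   aside, then re-clusters all samples.
2. **Correction.** β → M = logit2(β); an empirical-Bayes location/scale
   corrector (parametric ComBat algorithm) or a mean-centring corrector
   adjusts M per batch while retaining declared covariates; M → β.
3. **The log-variance ratio (LVR).** With cluster assignments frozen from
   the *pre*-correction fit, the cluster-aware variance pools within-cluster
   sums of squares over clusters and divides by n − 1:

   s²(x, C) = Σ_c Σ_{i∈c} (x_i − x̄_c)² / (n − 1),  LVR = log2(s²_post / s²_pre)

   Correction that removes batch variance drives LVR < 0; correction that
   destroys genuine clustering inflates within-cluster dispersion and drives
   LVR > 0 even while the ordinary SD falls. Combined with the mean absolute
   β shift, probes are classified:

   * LVR ≤ −log2(1.5) (= −0.584) and shift ≥ 0.01 → **batch-effect susceptible**
   * LVR ≥ +log2(1.5) (= +0.584) and shift ≥ 0.01 → **erroneously corrected**
4. **Attribution.** Modal probes are tested against gender/batch/superbatch
   (Fisher exact, or Monte-Carlo χ² for large tables), cell composition
   (one-way ANOVA) and Hardy–Weinberg assortment of cluster sizes
   (Levene–Haldane exact test), BH-FDR adjusted at p < 0.001.

A synthetic-study generator with per-probe ground truth (slide shifts,
HWE genotypes, gender/cell structure, boundary-constant probes) makes every
stage testable end to end.

## Worked example

```python
import methbatch as mb
result = mb.run_pipeline(mb.PipelineConfig(study=mb.StudyConfig(seed=1), seed=1))
print(result.summary)
```

On the reference study (96 samples on 8 slides, 2,000 probes of six
archetypes, seed 1) this prints

```
n_probes: 2000                          n_modal_probes: 444
mean_max_probewise_beta_diff: 0.0918    median_max_probewise_beta_diff: 0.0245
pct_low: 4.35  pct_moderate: 78.55  pct_high: 17.10
n_batch_susceptible: 201  n_erroneously_corrected: 145  n_unclassified: 1654
```

and the classification against the generating truth is

```
classification     batch_susceptible  erroneously_corrected  unclassified
asm_trimodal                       5                    145             0
batch_susceptible                196                      0             4
boundary_constant                  0                      0            50
cell_gradient                      0                      0           100
clean_unimodal                     0                      0          1400
gender_bimodal                     0                      0           100
```

196/200 probes carrying simulated slide shifts are re-found as
batch-susceptible, while 145/150 ASM probes — whose genotype clustering was
unbalanced across slides and undeclared to the corrector — are flagged as
erroneously corrected. Gender- and cell-driven clustering, declared as
covariates, is preserved (unclassified), and the near-boundary constant
probes are kept out of both classes by the β-shift gate. The `examples/`
directory walks through each capability (`python examples/02_correct_and_diagnose.py`
prints the table above).

A thin CLI mirrors the stages: `methbatch simulate|correct|cluster|report|consensus`.

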