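"""Batch-correct a study and classify probes with the LVR statistic.

Runs the full workflow on the reference synthetic study: modal clustering on
the uncorrected data, empirical-Bayes correction of M values with gender and
cell fraction declared, then per-probe diagnostics. Probes whose cluster-
aware variance shrinks by >= 50% with a mean beta shift >= 0.01 are
batch-effect susceptible; probes whose variance inflates by >= 50% were
erroneously corrected (their clustering was biological, not technical).
"""

import pandas as pd

import methbatch as mb

result = mb.run_pipeline(mb.PipelineConfig(study=mb.StudyConfig(seed=1), seed=1))

print("dataset summary:")
for key, val in sorted(result.summary.items()):
    print(f"  {key}: {val:.4f}" if isinstance(val, float) else f"  {key}: {val}")

print("\nclassification vs generating archetype:")
table = pd.crosstab(
    result.truth.table["archetype"], result.diagnostics["classification"]
)
print(table.to_string())

print(
    "\nBatch-susceptible probes should be re-found as batch_susceptible "
    "(variance removed as intended), while the undeclared, slide-unbalanced "
    "ASM probes are flagged erroneously_corrected: the corrector mistook "
    "their genotype clustering for technical variance and collapsed it."
)
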