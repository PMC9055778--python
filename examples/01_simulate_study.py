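"""Generate a synthetic Infinium-like study and inspect its structure.

The generator builds a 96-sample, 2,000-probe study on the M scale: slides
carry additive shifts on batch-susceptible probes, ASM probes are trimodal
with Hardy-Weinberg genotypes, gender and cell composition drive further
modality, and a handful of probes sit constant at the beta boundary.
"""

import methbatch as mb

beta, sheet, truth = mb.generate_study(mb.StudyConfig(seed=1))

print(f"beta matrix: {beta.shape[0]} probes x {beta.shape[1]} samples")
print(f"beta range: [{beta.values.min():.4g}, {beta.values.max():.4g}]")
print("\nprobes per archetype:")
print(truth.table["archetype"].value_counts().to_string())
print("\nsamples per slide / superbatch:")
print(sheet.groupby(["superbatch", "slide"]).size().to_string())

asm = truth.probes_of("asm_trimodal")[0]
counts = truth.genotypes.loc[asm].value_counts().sort_index()
print(f"\ngenotype counts for ASM probe {asm} (minor-allele copies 0/1/2):")
print(counts.to_string())
print(
    "\nWith maf = 0.3 these counts should sit near the Hardy-Weinberg "
    "expectation 96 x (0.49, 0.42, 0.09) = (47, 40, 9)."
)
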