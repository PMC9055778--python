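"""Detect modal probes and attribute them to biological/technical factors.

Each multi-modal probe is tested for association of its clusters with
gender, slide, superbatch (Fisher exact or Monte-Carlo chi-square), cell
fraction (ANOVA) and for Hardy-Weinberg-consistent assortment of its
cluster sizes (Levene-Haldane exact test), with BH-FDR at 0.001.
"""

import methbatch as mb

beta, sheet, truth = mb.generate_study(mb.StudyConfig(seed=1))
pre = mb.shift_betas(beta, seed=1)
clusters = mb.cluster_probes_two_stage(pre, sheet, excluded_slides=[])

modal = {p: m for p, m in clusters.items() if m.k > 1}
print(f"{len(modal)} of {len(clusters)} probes are multi-modal")

attribution, tally = mb.attribute_modal_probes(clusters, sheet, seed=1)
for factor in ("gender", "cell"):
    col = f"sig_{factor}"
    print(f"probes attributed to {factor}: {int(attribution[col].eq(True).sum())}")
print(f"HWE-consistent modal probes: {int(attribution['hwe_consistent'].eq(True).sum())}")

asm_probe = truth.probes_of("asm_trimodal")[0]
model = clusters[asm_probe]
print(f"\nASM probe {asm_probe}: k={model.k}, "
      f"centroids={[round(float(c), 3) for c in model.centroids]}, "
      f"cluster sizes={[int(s) for s in model.cluster_sizes]}")
p = mb.hwe_exact(model.cluster_sizes)
print(f"HWE exact p = {p:.3f} -> cluster sizes assort like genotype classes, "
      "so this modality is genetic, not technical: do not batch-correct it.")
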