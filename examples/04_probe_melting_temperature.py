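"""Probe melting temperature and internal CpG count.

Probes with low nearest-neighbour melting temperature hybridise less
robustly and tend to need more between-batch correction; Tm < 70 C is a
useful stratum when summarising susceptibility.
"""

import methbatch as mb

type2 = mb.ProbeRecord(
    "cg_example_II", "II",
    "TAATTTAATACRAACTTATTATAATAATATAAATAAAAATATTATTATTA",
)
type1 = mb.ProbeRecord(
    "cg_example_I", "I",
    "ACGTTGCAATACCGCATTAACGGTTACGTTGCAATACGCATTAACGGTTA",
    sequence_b="ATGTTGCAATACTGCATTAACGGTTATGTTGCAATACGCATTAACGGTTA",
)

for rec in (type2, type1):
    tm = mb.probe_tm(rec)
    cpg = mb.internal_cpg_count(rec.sequence_a)
    stratum = "low-Tm (<70 C)" if tm < 70 else "typical"
    print(f"{rec.probe_id} (Type {rec.infinium_type}): "
          f"Tm = {tm:.2f} C ({stratum}), internal CpGs = {cpg}")

print(
    "\nType II probes resolve their degenerate R bases as A or G and the two "
    "Tms are averaged; Type I averages its A and B allele bodies. AT-rich "
    "bisulphite-converted bodies like the Type II example melt low, which is "
    "one reason such probes are more batch-effect prone."
)
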