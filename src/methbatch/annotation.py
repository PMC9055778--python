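"""Probe-level covariates that stratify batch-effect susceptibility.

Probes with low duplex melting temperature hybridise less robustly and need
more between-batch correction, so a nearest-neighbour Tm estimate and the
number of CpG dinucleotides internal to the probe body are useful strata.

Tm uses the unified nearest-neighbour DNA/DNA stack parameters of Allawi &
SantaLucia (dH in kcal/mol, dS in cal/(mol K)) with terminal initiation
terms and no correction for mono- or divalent cation concentration:

    Tm = 1000 * dH / (dS + R ln(C_T / 4)) - 273.15

with R = 1.9872 cal/(mol K) and total strand concentration C_T (default
0.25 uM, configurable). Absolute values therefore differ from salt-corrected
estimates by a roughly constant offset; only relative/threshold behaviour
(e.g. a < 70 C stratum) is meaningful.

Infinium type I designs carry two probe bodies (A and B alleles); their Tms
are averaged. Type II bodies use the degenerate purine R at CpG-cytosine
positions: Tm is the average of the all-R-as-A and all-R-as-G variants.
"""

from __future__ import annotations

from dataclasses import dataclass
import re

__all__ = ["ProbeRecord", "nn_tm", "probe_tm", "internal_cpg_count", "NN_PARAMS"]

GAS_CONSTANT = 1.9872  # cal / (mol K)
DEFAULT_CT = 0.25e-6  # total strand concentration, mol/L

# Allawi & SantaLucia unified NN parameters: (dH kcal/mol, dS cal/mol/K).
# The ten unique stacks; the other six follow by reverse-complement symmetry.
NN_PARAMS = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}

_INIT_GC = (0.1, -2.8)  # initiation with a terminal G.C pair
_INIT_AT = (2.3, 4.1)  # initiation with a terminal A.T pair


@dataclass
class ProbeRecord:
    """One array probe: body sequence(s), design type and annotation flags."""

    probe_id: str
    infinium_type: str  # "I" or "II"
    sequence_a: str
    sequence_b: str | None = None  # Type I B probe
    chromosome: str | None = None
    snp_at_site: bool = False
    snp_within_10bp: bool = False
    cross_hybridising: bool = False

    def __post_init__(self) -> None:
        if self.infinium_type not in ("I", "II"):
            raise ValueError(f"infinium_type must be 'I' or 'II', got {self.infinium_type!r}")
        if self.infinium_type == "I" and "R" in self.sequence_a.upper():
            raise ValueError("degenerate R bases are a Type II feature")


def nn_tm(sequence: str, ct: float = DEFAULT_CT) -> float:
    """Nearest-neighbour melting temperature in Celsius (no salt correction)."""
    seq = sequence.upper()
    if len(seq) < 8:
        raise ValueError(f"sequence too short for a meaningful Tm: length {len(seq)}")
    invalid = set(seq) - set("ACGT")
    if invalid:
        raise ValueError(
            f"invalid characters {sorted(invalid)}; resolve degenerate bases first"
        )
    dh, ds = 0.0, 0.0
    for a, b in ((seq[0], None), (seq[-1], None)):
        h, s = _INIT_GC if a in "GC" else _INIT_AT
        dh += h
        ds += s
    for i in range(len(seq) - 1):
        h, s = NN_PARAMS[seq[i : i + 2]]
        dh += h
        ds += s
    import math

    return 1000.0 * dh / (ds + GAS_CONSTANT * math.log(ct / 4.0)) - 273.15


def probe_tm(record: ProbeRecord, ct: float = DEFAULT_CT) -> float:
    """Per-probe Tm: Type I averages the A and B bodies; Type II averages the
    all-R-as-A and all-R-as-G resolutions of its degenerate bases."""
    if record.infinium_type == "I":
        if not record.sequence_b:
            raise ValueError(f"Type I probe {record.probe_id} lacks a B-probe sequence")
        return 0.5 * (nn_tm(record.sequence_a, ct) + nn_tm(record.sequence_b, ct))
    seq = record.sequence_a.upper()
    return 0.5 * (
        nn_tm(seq.replace("R", "A"), ct) + nn_tm(seq.replace("R", "G"), ct)
    )


def internal_cpg_count(sequence: str) -> int:
    """Count CpG dinucleotides internal to a probe body.

    The degenerate R base stands at a CpG position in Type II designs, so
    both the literal "CG" and the degenerate "CR" spellings count as one
    internal CpG.
    """
    seq = sequence.upper()
    invalid = set(seq) - set("ACGTR")
    if invalid:
        raise ValueError(f"invalid characters {sorted(invalid)} in probe sequence")
    return len(re.findall("C[GR]", seq))
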