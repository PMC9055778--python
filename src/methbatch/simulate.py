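"""Synthetic Infinium-like studies with known batch structure and ground truth.

The generator emulates the statistical structure that the diagnostic
workflow assumes, on the M scale (effects are additive there, matching the
scale on which batch correction operates) before converting to beta:

* slides of 8-12 arrays grouped into superbatches (processing runs),
  with gender and treatment blocked across slides as a careful design would;
* ``batch_susceptible`` probes carrying per-slide additive M shifts and a
  per-row slide-position trend;
* ``asm_trimodal`` probes with a C->T style SNP at the probed CpG: genotypes
  drawn per sample from Hardy-Weinberg equilibrium at the configured minor
  allele frequency, minor-allele count 0/1/2 mapping to three beta centroids;
* ``gender_bimodal`` probes with higher methylation in males;
* ``cell_gradient`` probes driven linearly by a per-sample cell fraction,
  itself drawn from a two-component mixture (a majority of low-immune
  samples, a minority with a high immune component);
* ``boundary_constant`` probes that are exactly constant near the beta
  boundary (they exercise the zero-variance edge case);
* ``clean_unimodal`` probes with nothing but noise around a base level.

In unbalanced mode (the default) genotypes of ASM probes are concentrated
along the slide order — minor-allele homozygotes land on the first slides —
which is the configuration under which correction software, blind to the
undeclared genotype, erroneously converges the batch means. Balanced mode
spreads genotypes uniformly. Gender stays blocked across slides in both
modes: a sample-wise covariate can be declared to the corrector, a
feature-wise genotype cannot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    BetaMatrix,
    read_matrix_tsv,
    read_sample_sheet,
    write_matrix_tsv,
    write_sample_sheet,
)
from .transforms import ilogit2, logit2

__all__ = ["StudyConfig", "SyntheticTruth", "generate_study", "write_fixture", "read_fixture"]

ARCHETYPES = (
    "clean_unimodal",
    "batch_susceptible",
    "asm_trimodal",
    "gender_bimodal",
    "cell_gradient",
    "boundary_constant",
)

DEFAULT_PROBE_COUNTS = {
    "clean_unimodal": 1400,
    "batch_susceptible": 200,
    "asm_trimodal": 150,
    "gender_bimodal": 100,
    "cell_gradient": 100,
    "boundary_constant": 50,
}

DEFAULT_CENTROIDS = {
    "asm_trimodal": (0.1, 0.5, 0.9),
    "gender_bimodal": (0.25, 0.75),
}


@dataclass
class StudyConfig:
    """Desk-scale defaults: 8 slides x 12 arrays (96 samples), 2 superbatches,
    2,000 probes, per-observation M noise SD 0.15, slide shifts SD 0.5."""

    n_slides: int = 8
    arrays_per_slide: int = 12
    n_superbatches: int = 2
    slide_rows: int = 6
    slide_cols: int = 2
    probe_counts: dict = field(default_factory=lambda: dict(DEFAULT_PROBE_COUNTS))
    maf: float = 0.3
    batch_sd_m: float = 0.5
    position_slope_m: float = 0.03
    noise_sd_m: float = 0.15
    cluster_centroids_beta: dict = field(default_factory=lambda: dict(DEFAULT_CENTROIDS))
    cell_slope_m: float = 4.0
    balanced: bool = False
    unbalance_mixing: float = 0.1  # fraction of samples re-shuffled after sorting
    seed: int = 0

    def __post_init__(self) -> None:
        if self.slide_rows * self.slide_cols != self.arrays_per_slide:
            raise ValueError(
                f"slide layout {self.slide_rows}x{self.slide_cols} does not hold "
                f"{self.arrays_per_slide} arrays"
            )
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"maf must lie in (0, 0.5], got {self.maf}")
        unknown = set(self.probe_counts) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes: {sorted(unknown)}")
        if any(v < 0 for v in self.probe_counts.values()):
            raise ValueError("probe counts must be >= 0")
        if self.n_slides < self.n_superbatches:
            raise ValueError("need at least one slide per superbatch")

    @property
    def n_samples(self) -> int:
        return self.n_slides * self.arrays_per_slide

    @property
    def n_probes(self) -> int:
        return sum(self.probe_counts.values())


@dataclass
class SyntheticTruth:
    """Ground truth: per-probe archetype/k, ASM genotypes, per-slide shifts."""

    table: pd.DataFrame  # index probe_id; columns archetype, true_k
    genotypes: pd.DataFrame  # asm probes x samples, minor-allele counts
    slide_shifts: pd.DataFrame  # susceptible probes x slides, M-scale shifts

    def probes_of(self, archetype: str) -> pd.Index:
        return self.table.index[self.table["archetype"] == archetype]


def _make_sample_sheet(config: StudyConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_samples
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    slides = np.repeat([f"SL{s + 1:02d}" for s in range(config.n_slides)],
                       config.arrays_per_slide)
    # superbatch: contiguous blocks of slides (processing runs)
    per_batch = int(np.ceil(config.n_slides / config.n_superbatches))
    slide_to_sb = {
        f"SL{s + 1:02d}": f"SB{s // per_batch + 1}" for s in range(config.n_slides)
    }
    rows = np.tile(np.repeat(np.arange(1, config.slide_rows + 1), config.slide_cols),
                   config.n_slides)
    cols = np.tile(np.arange(1, config.slide_cols + 1),
                   config.slide_rows * config.n_slides)
    # blocked design: gender and treatment alternate within each slide
    gender = np.tile(
        np.resize(["F", "M"], config.arrays_per_slide), config.n_slides
    )
    treatment = np.tile(
        np.resize(["control", "control", "treated", "treated"], config.arrays_per_slide),
        config.n_slides,
    )
    # cell fraction: low-immune majority, high-immune minority
    high = rng.random(n) < 0.2
    cell = np.where(
        high,
        rng.normal(0.30, 0.05, n),
        rng.normal(0.03, 0.01, n),
    )
    cell = np.clip(cell, 0.001, 0.6)
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "slide": slides,
            "position_row": rows,
            "position_col": cols,
            "superbatch": [slide_to_sb[s] for s in slides],
            "gender": gender,
            "treatment": treatment,
            "cell_fraction": cell,
        }
    )


def _draw_genotypes(config: StudyConfig, rng: np.random.Generator, n_probes: int) -> np.ndarray:
    """Minor-allele counts per probe x sample, i.i.d. HWE(maf) within a probe.

    Unbalanced mode sorts each probe's genotypes in descending minor-allele
    count along the slide order, then re-shuffles a ``unbalance_mixing``
    fraction of positions, concentrating minor homozygotes on the first
    slides.
    """
    q = config.maf
    p_geno = np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])
    n = config.n_samples
    geno = rng.choice(3, size=(n_probes, n), p=p_geno)
    if not config.balanced:
        geno = -np.sort(-geno, axis=1)  # minor-allele-rich samples first
        n_mix = int(round(config.unbalance_mixing * n))
        for i in range(n_probes):
            idx = rng.choice(n, size=n_mix, replace=False)
            geno[i, idx] = geno[i, rng.permutation(idx)]
    return geno


def generate_study(config: StudyConfig) -> tuple[BetaMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate (beta matrix, sample sheet, truth), deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    sheet = _make_sample_sheet(config, rng)
    n = config.n_samples

    slide_codes = pd.factorize(sheet["slide"], sort=True)[0]
    male = (sheet["gender"] == "M").to_numpy()
    cell = sheet["cell_fraction"].to_numpy()
    row_pos = sheet["position_row"].to_numpy()

    probe_rows: list[np.ndarray] = []
    truth_rows: list[dict] = []
    geno_frames: dict[str, np.ndarray] = {}
    shift_frames: dict[str, np.ndarray] = {}
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"cg{counter:06d}"

    for archetype in ARCHETYPES:
        count = config.probe_counts.get(archetype, 0)
        if count == 0:
            continue
        if archetype == "asm_trimodal":
            geno = _draw_genotypes(config, rng, count)
            centroids = np.asarray(config.cluster_centroids_beta["asm_trimodal"])
            centroid_m = logit2(centroids)
        for j in range(count):
            pid = next_id()
            noise = rng.normal(0.0, config.noise_sd_m, n)
            if archetype == "clean_unimodal":
                base = logit2(rng.uniform(0.1, 0.9))
                m = base + noise
                true_k = 1
            elif archetype == "batch_susceptible":
                base = logit2(rng.uniform(0.1, 0.9))
                shifts = rng.normal(0.0, config.batch_sd_m, config.n_slides)
                m = (
                    base
                    + shifts[slide_codes]
                    + config.position_slope_m * (row_pos - row_pos.mean())
                    + noise
                )
                shift_frames[pid] = shifts
                true_k = 1
            elif archetype == "asm_trimodal":
                g = geno[j]
                m = centroid_m[g] + noise
                geno_frames[pid] = g
                true_k = int(np.unique(g).size)
            elif archetype == "gender_bimodal":
                lo, hi = config.cluster_centroids_beta["gender_bimodal"]
                m = np.where(male, logit2(hi), logit2(lo)) + noise
                true_k = 2
            elif archetype == "cell_gradient":
                base = logit2(rng.uniform(0.2, 0.5))
                m = base + config.cell_slope_m * cell + noise
                true_k = 2
            else:  # boundary_constant: exactly constant, near the boundary
                level = 13.0 if rng.random() < 0.5 else -13.0
                m = np.full(n, level)
                true_k = 1
            probe_rows.append(m)
            truth_rows.append({"probe_id": pid, "archetype": archetype, "true_k": true_k})

    m_matrix = np.vstack(probe_rows)
    beta_vals = ilogit2(m_matrix)
    probe_ids = [r["probe_id"] for r in truth_rows]
    beta = BetaMatrix(
        pd.DataFrame(beta_vals, index=pd.Index(probe_ids, name="probe_id"),
                     columns=sheet["sample_id"].tolist())
    )
    truth = SyntheticTruth(
        table=pd.DataFrame(truth_rows).set_index("probe_id"),
        genotypes=pd.DataFrame.from_dict(
            geno_frames, orient="index", columns=sheet["sample_id"].tolist()
        ),
        slide_shifts=pd.DataFrame.from_dict(
            shift_frames,
            orient="index",
            columns=sorted(sheet["slide"].unique()),
        ),
    )
    truth.genotypes.index.name = "probe_id"
    truth.slide_shifts.index.name = "probe_id"
    return beta, sheet, truth


def write_fixture(directory, study: tuple[BetaMatrix, pd.DataFrame, SyntheticTruth]) -> dict[str, Path]:
    """Write beta.tsv, samplesheet.tsv, truth.tsv (+ genotype/shift sidecars)."""
    beta, sheet, truth = study
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": directory / "beta.tsv",
        "samplesheet": directory / "samplesheet.tsv",
        "truth": directory / "truth.tsv",
        "genotypes": directory / "truth_genotypes.tsv",
        "slide_shifts": directory / "truth_slide_shifts.tsv",
    }
    try:
        write_matrix_tsv(beta.frame, paths["beta"])
        write_sample_sheet(sheet, paths["samplesheet"])
        truth.table.to_csv(paths["truth"], sep="\t")
        truth.genotypes.to_csv(paths["genotypes"], sep="\t")
        truth.slide_shifts.to_csv(paths["slide_shifts"], sep="\t")
    except OSError as exc:
        raise OSError(f"failed writing fixture under {directory}: {exc}") from exc
    return paths


def read_fixture(directory) -> tuple[BetaMatrix, pd.DataFrame, SyntheticTruth]:
    directory = Path(directory)
    beta = BetaMatrix(read_matrix_tsv(directory / "beta.tsv"))
    sheet = read_sample_sheet(directory / "samplesheet.tsv")
    truth = SyntheticTruth(
        table=pd.read_csv(directory / "truth.tsv", sep="\t", index_col=0),
        genotypes=pd.read_csv(directory / "truth_genotypes.tsv", sep="\t", index_col=0),
        slide_shifts=pd.read_csv(directory / "truth_slide_shifts.tsv", sep="\t", index_col=0),
    )
    return beta, sheet, truth
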