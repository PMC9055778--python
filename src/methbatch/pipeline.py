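"""End-to-end orchestration, PCA overview and cross-dataset consensus.

``run_pipeline`` chains the stages in the order the diagnostics require:
edge-case beta handling -> logit transform -> two-stage modal clustering on
the UNcorrected data -> batch correction on M -> back-transform ->
probe-wise diagnostics and classification -> factor attribution -> exports.
Clustering precedes correction deliberately: the cluster-aware variance must
see the clusters that correction may destroy.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .containers import BetaMatrix, MMatrix, read_matrix_tsv, read_sample_sheet
from .transforms import shift_betas, beta_to_m, m_to_beta
from .clustering import cluster_probes_two_stage
from .correction import fit_correction, apply_correction
from .diagnostics import (
    LVR_CUT,
    SHIFT_CUT,
    diagnostics_table,
    summarise_diagnostics,
    write_reference_matrix,
)
from .associations import attribute_modal_probes
from .simulate import StudyConfig, generate_study

__all__ = ["PipelineConfig", "PipelineResult", "pca_overview", "run_pipeline", "consensus"]

logger = logging.getLogger("methbatch")


def pca_overview(
    m: MMatrix,
    annotation: pd.DataFrame | None = None,
    sheet: pd.DataFrame | None = None,
    n_components: int = 4,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample-space PCA of probe-centred M values, autosomal probes only.

    X and Y chromosome probes (per the annotation's ``chromosome`` column)
    are removed first: X inactivation in females is otherwise a dominant,
    uninformative source of sample correlation. Probes are centred, not
    scaled. Returns (coordinates, explained variance fractions).
    """
    if m.shape[1] < 3:
        raise ValueError("PCA overview needs at least 3 samples")
    frame = m.frame
    if annotation is not None and "chromosome" in annotation.columns:
        chrom = annotation["chromosome"].astype(str).str.removeprefix("chr")
        sex_probes = annotation.index[chrom.isin(["X", "Y"])]
        frame = frame.drop(index=sex_probes.intersection(frame.index))
    else:
        logger.warning("no chromosome annotation supplied; PCA uses all probes")
    k = min(n_components, frame.shape[1] - 1, frame.shape[0])
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(frame.to_numpy().T)  # samples x components
    coord_frame = pd.DataFrame(
        coords,
        index=frame.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    coord_frame.index.name = "sample_id"
    return coord_frame, pca.explained_variance_ratio_


@dataclass
class PipelineConfig:
    """Inputs and thresholds for one diagnostic run.

    Either ``beta_path``/``sheet_path`` or a :class:`StudyConfig` for
    simulation mode. Thresholds default to the published cut-offs.
    """

    beta_path: str | None = None
    sheet_path: str | None = None
    annotation_path: str | None = None
    study: StudyConfig | None = None
    batch_var: str = "slide"
    covariates: tuple[str, ...] = ("gender", "cell_fraction")
    excluded_slides: tuple = ()
    method: str = "eb_location_scale"
    lvr_cut: float = LVR_CUT
    shift_cut: float = SHIFT_CUT
    alpha: float = 0.001
    min_cluster_size: int = 5
    min_centroid_sep: float = 0.1
    kmax: int = 4
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.beta_path is None) == (self.study is None):
            raise ValueError("provide exactly one of beta_path or study")
        if self.beta_path is not None and self.sheet_path is None:
            raise ValueError("sheet_path is required with beta_path")
        for name in ("lvr_cut", "shift_cut", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PipelineResult:
    pre_beta: BetaMatrix
    post_beta: BetaMatrix
    clusters: dict
    diagnostics: pd.DataFrame
    attribution: pd.DataFrame
    tally: pd.DataFrame
    summary: dict
    truth: object | None = None
    paths: dict = field(default_factory=dict)


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    return wrap


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full diagnostic workflow; deterministic given the seed."""
    truth = None
    if config.study is not None:
        logger.info("simulation mode: generating study")
        beta_raw, sheet, truth = _stage("simulate")(generate_study, config.study)
        annotation = None
    else:
        beta_raw = _stage("read beta")(
            lambda p: BetaMatrix(read_matrix_tsv(p)), config.beta_path
        )
        sheet = _stage("read sheet")(read_sample_sheet, config.sheet_path)
        annotation = (
            pd.read_csv(config.annotation_path, sep="\t", index_col=0)
            if config.annotation_path
            else None
        )

    pre = _stage("shift_betas")(shift_betas, beta_raw, seed=config.seed)
    m_pre = _stage("beta_to_m")(beta_to_m, pre)

    logger.info("two-stage clustering (%d probes)", pre.shape[0])
    clusters = _stage("clustering")(
        cluster_probes_two_stage,
        pre,
        sheet,
        list(config.excluded_slides),
        kmax=config.kmax,
        min_cluster_size=config.min_cluster_size,
        min_centroid_sep=config.min_centroid_sep,
    )

    logger.info("batch correction (%s on %s)", config.method, config.batch_var)
    model = _stage("fit_correction")(
        fit_correction, m_pre, sheet, config.batch_var, config.covariates, config.method
    )
    m_post = _stage("apply_correction")(apply_correction, m_pre, model)
    post = _stage("m_to_beta")(m_to_beta, m_post)

    diag = _stage("diagnostics")(
        diagnostics_table, pre, post, clusters, config.lvr_cut, config.shift_cut
    )
    attribution, tally = _stage("attribution")(
        attribute_modal_probes,
        clusters,
        sheet,
        annotation,
        config.alpha,
        seed=config.seed,
    )
    summary = summarise_diagnostics(diag)
    summary["n_modal_probes"] = int(sum(1 for mdl in clusters.values() if mdl.k > 1))

    paths: dict[str, Path] = {}
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths["reference_matrix"] = out / "reference_matrix.tsv"
        paths["attribution"] = out / "attribution.tsv"
        paths["summary"] = out / "summary.json"
        try:
            write_reference_matrix(diag, paths["reference_matrix"])
            attribution.to_csv(paths["attribution"], sep="\t")
            with open(paths["summary"], "w") as fh:
                json.dump(summary, fh, indent=2, sort_keys=True)
        except Exception:
            for p in paths.values():  # remove partial outputs
                Path(p).unlink(missing_ok=True)
            raise

    return PipelineResult(
        pre_beta=pre,
        post_beta=post,
        clusters=clusters,
        diagnostics=diag,
        attribution=attribution,
        tally=tally,
        summary=summary,
        truth=truth,
        paths=paths,
    )


def consensus(tables: list[pd.DataFrame]) -> tuple[pd.DataFrame, dict]:
    """Cross-dataset consensus of per-probe classifications.

    ``tables`` are diagnostics tables (indexed by probe, with a
    ``classification`` column); the shared probe universe is the
    intersection. Returns a per-probe table with per-dataset counts and a
    tally of probes susceptible/erroneous in at least t datasets.
    """
    if not tables:
        raise ValueError("need at least one diagnostics table")
    common = tables[0].index
    for t in tables[1:]:
        common = common.intersection(t.index)
    if len(common) == 0:
        raise ValueError("no probes shared across datasets")

    n_sets = len(tables)
    sus = np.zeros(len(common), dtype=int)
    err = np.zeros(len(common), dtype=int)
    per_dataset = {}
    for d, t in enumerate(tables):
        cls = t.loc[common, "classification"]
        per_dataset[f"dataset_{d + 1}"] = cls.to_numpy()
        sus += (cls == "batch_susceptible").to_numpy()
        err += (cls == "erroneously_corrected").to_numpy()
    table = pd.DataFrame(per_dataset, index=common)
    table["n_datasets_susceptible"] = sus
    table["n_datasets_erroneous"] = err

    tallies = {
        "n_datasets": n_sets,
        "n_common_probes": int(len(common)),
        "susceptible_at_least": {
            t: int((sus >= t).sum()) for t in range(1, n_sets + 1)
        },
        "erroneous_at_least": {
            t: int((err >= t).sum()) for t in range(1, n_sets + 1)
        },
        "susceptible_all": int((sus == n_sets).sum()),
        "erroneous_all": int((err == n_sets).sum()),
    }
    return table, tallies
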