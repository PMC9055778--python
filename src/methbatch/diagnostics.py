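"""Probe-wise diagnostics of batch correction.

The central quantity is the log-variance ratio (LVR): the log2 ratio of a
cluster-aware sample variance computed after batch correction to the same
quantity before. The cluster-aware variance pools within-cluster sums of
squares (clusters fixed from the PRE-correction fit) and divides by n - 1,
reducing to the ordinary sample variance for unimodal probes. Correction
that removes technical between-batch variance drives LVR below 0; correction
that collapses biologically meaningful clusters inflates the within-cluster
dispersion and drives LVR above 0, even while the ordinary SD falls.

Classification combines LVR with the mean absolute beta shift so that
essentially-unmoved probes (e.g. fully (un)methylated sites whose tiny
variances make the ratio unstable) are never flagged:

* LVR >= log2(1.5) and mean shift >= 0.01  -> erroneously corrected
* LVR <= -log2(1.5) and mean shift >= 0.01 -> batch-effect susceptible
* otherwise                                -> unclassified
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import BetaMatrix
from .clustering import ClusterModel

__all__ = [
    "LVR_CUT",
    "SHIFT_CUT",
    "cluster_aware_variance",
    "lvr",
    "mean_beta_shift",
    "max_probewise_beta_diff",
    "adjustment_group",
    "classify_probe",
    "diagnostics_table",
    "summarise_diagnostics",
    "write_reference_matrix",
]

LVR_CUT = float(np.log2(1.5))  # 50% variance change
SHIFT_CUT = 0.01  # minimum mean |delta beta|


def cluster_aware_variance(x, assignments) -> float:
    """Within-cluster sums of squares pooled over clusters, divided by n - 1.

    Equals the textbook sample variance when all samples share one cluster.
    """
    x = np.asarray(x, dtype=float)
    assignments = np.asarray(assignments)
    n = x.size
    if n < 2:
        raise ValueError("cluster-aware variance needs at least 2 samples")
    if assignments.size != n:
        raise ValueError("assignments must cover every sample")
    ss = 0.0
    for lab in np.unique(assignments):
        xi = x[assignments == lab]
        ss += float(((xi - xi.mean()) ** 2).sum())
    return ss / (n - 1)


def lvr(pre, post, assignments) -> float:
    """log2(cluster-aware variance after / before); NaN if the pre variance is 0.

    Assignments come from the pre-correction clustering: the statistic must
    register clusters destroyed by the correction, which re-clustering the
    corrected data would hide. LVR > 0 means correction inflated the
    (cluster-aware) variance; LVR < 0 means it reduced it as intended.
    """
    v_pre = cluster_aware_variance(pre, assignments)
    v_post = cluster_aware_variance(post, assignments)
    if v_pre == 0.0:
        return float("nan")
    if v_post == 0.0:
        return float("-inf")
    return float(np.log2(v_post / v_pre))


def mean_beta_shift(pre, post, signed: bool = False) -> float:
    """Mean per-sample beta change induced by correction.

    Absolute convention by default (a signed mean would let opposing batch
    moves cancel and defeat the classification gate); ``signed=True`` gives
    the plain mean difference for sensitivity analyses.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError(f"length mismatch: {pre.shape} vs {post.shape}")
    d = post - pre
    return float(d.mean()) if signed else float(np.abs(d).mean())


def max_probewise_beta_diff(pre, post) -> float:
    """Span of per-sample beta changes: |max(post - pre) - min(post - pre)|.

    Zero for a uniform shift; large when one or more batches were moved much
    further than others.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError(f"length mismatch: {pre.shape} vs {post.shape}")
    d = post - pre
    return float(abs(d.max() - d.min()))


def adjustment_group(stat: float) -> str:
    """Bin a beta-difference statistic: low (<0.01), moderate ([0.01, 0.10]), high (>0.10)."""
    if stat < 0:
        raise ValueError(f"statistic must be non-negative, got {stat}")
    if stat < 0.01:
        return "low"
    if stat <= 0.10:
        return "moderate"
    return "high"


def classify_probe(
    lvr_value: float,
    shift: float,
    lvr_cut: float = LVR_CUT,
    shift_cut: float = SHIFT_CUT,
) -> str:
    """Classify one probe from its LVR and mean beta shift (non-strict cut-offs)."""
    if lvr_value is None or np.isnan(lvr_value):
        return "unclassified"
    if shift >= shift_cut and lvr_value >= lvr_cut:
        return "erroneously_corrected"
    if shift >= shift_cut and lvr_value <= -lvr_cut:
        return "batch_susceptible"
    return "unclassified"


def diagnostics_table(
    pre: BetaMatrix,
    post: BetaMatrix,
    clusters: dict[str, ClusterModel] | None = None,
    lvr_cut: float = LVR_CUT,
    shift_cut: float = SHIFT_CUT,
) -> pd.DataFrame:
    """One diagnostics row per probe.

    ``clusters`` maps probe id to its pre-correction :class:`ClusterModel`;
    probes without a model are treated as unimodal (k = 1). Probes with zero
    pre-correction variance get a missing LVR and stay in the table — they
    are reported, never dropped.
    """
    if not pre.probe_ids.equals(post.probe_ids) or not pre.sample_ids.equals(
        post.sample_ids
    ):
        raise ValueError("pre and post matrices must share probes and samples")
    clusters = clusters or {}
    pre_vals = pre.values
    post_vals = post.values
    n = pre_vals.shape[1]
    one_cluster = np.zeros(n, dtype=np.intp)

    rows = []
    for i, probe in enumerate(pre.probe_ids):
        model = clusters.get(str(probe))
        assignments = model.assignments if model is not None else one_cluster
        k = model.k if model is not None else 1
        p, q = pre_vals[i], post_vals[i]
        v_pre = cluster_aware_variance(p, assignments)
        v_post = cluster_aware_variance(q, assignments)
        lvr_value = lvr(p, q, assignments)
        shift = mean_beta_shift(p, q)
        span = max_probewise_beta_diff(p, q)
        rows.append(
            {
                "probe_id": str(probe),
                "k": k,
                "var_pre": v_pre,
                "var_post": v_post,
                "lvr": lvr_value,
                "mean_beta_shift": shift,
                "max_probewise_beta_diff": span,
                "sd_pre": float(p.std(ddof=1)),
                "sd_post": float(q.std(ddof=1)),
                "adjustment_group": adjustment_group(span),
                "classification": classify_probe(lvr_value, shift, lvr_cut, shift_cut),
            }
        )
    return pd.DataFrame(rows).set_index("probe_id")


def summarise_diagnostics(table: pd.DataFrame) -> dict:
    """Dataset-level summary: mean/median maximal beta difference, group and class tallies."""
    groups = table["adjustment_group"].value_counts(normalize=True) * 100.0
    classes = table["classification"].value_counts()
    return {
        "n_probes": int(len(table)),
        "mean_max_probewise_beta_diff": float(table["max_probewise_beta_diff"].mean()),
        "median_max_probewise_beta_diff": float(
            table["max_probewise_beta_diff"].median()
        ),
        "pct_low": float(groups.get("low", 0.0)),
        "pct_moderate": float(groups.get("moderate", 0.0)),
        "pct_high": float(groups.get("high", 0.0)),
        "n_batch_susceptible": int(classes.get("batch_susceptible", 0)),
        "n_erroneously_corrected": int(classes.get("erroneously_corrected", 0)),
        "n_unclassified": int(classes.get("unclassified", 0)),
    }


def write_reference_matrix(table: pd.DataFrame, path) -> None:
    """Export the per-probe reference matrix, numeric columns rounded to 4 dp."""
    out = table.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].round(4)
    out.to_csv(path, sep="\t")
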