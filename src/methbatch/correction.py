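"""Batch correction of M matrices with declared biological covariates.

Two back-ends behind one interface:

* ``eb_location_scale`` — the parametric empirical-Bayes location/scale
  adjustment: each probe is standardised by its covariate fit and pooled SD,
  per-batch location (gamma) and scale (delta^2) estimates are shrunk toward
  normal / inverse-gamma priors whose hyperparameters come from the method
  of moments across probes, the posterior estimates are iterated to a
  tolerance, and the standardised data are location/scale adjusted and
  rescaled.
* ``mean_center`` — per-batch means of the covariate-fit residuals are
  subtracted, with no scale adjustment.

Both operate on M values (beta is bounded, so location shifts on beta can
leave the unit interval; the logit scale is unbounded). Biological
covariates declared in the model are retained by construction: the batch
location estimates are taken on residuals from the covariate fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MMatrix

__all__ = ["CorrectionModel", "fit_correction", "apply_correction", "sequential_correction"]

EB_CONVERGENCE = 1e-4
EB_MAX_ITER = 100


@dataclass
class CorrectionModel:
    method: str
    batch_var: str
    covariates: tuple[str, ...]
    sample_ids: pd.Index
    probe_ids: pd.Index
    batch_levels: np.ndarray
    batch_codes: np.ndarray  # per sample
    design_cov: np.ndarray  # samples x (covariate columns, incl. intercept for mean_center)
    # eb_location_scale internals
    stand_mean: np.ndarray | None = None  # probes x samples
    var_pooled: np.ndarray | None = None  # probes
    gamma_hat: np.ndarray | None = None  # batches x probes (raw)
    delta_hat_sq: np.ndarray | None = None
    gamma_star: np.ndarray | None = None  # shrunk
    delta_star_sq: np.ndarray | None = None
    prior_params: dict = field(default_factory=dict)
    # mean_center internals
    cov_coef: np.ndarray | None = None  # covariate columns x probes
    batch_residual_means: np.ndarray | None = None  # batches x probes

    @property
    def n_batches(self) -> int:
        return len(self.batch_levels)


def _build_design(
    sheet: pd.DataFrame, sample_ids, batch_var: str, covariates
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    sheet = sheet.set_index("sample_id").loc[list(sample_ids)]
    if batch_var not in sheet.columns:
        raise ValueError(f"sample sheet lacks batch variable {batch_var!r}")
    batch_codes, batch_levels = pd.factorize(sheet[batch_var].astype(str), sort=True)
    counts = np.bincount(batch_codes)
    if counts.min() < 2:
        small = batch_levels[np.argmin(counts)]
        raise ValueError(f"batch level {small!r} has fewer than 2 samples")

    cov_cols = [np.ones(len(sheet))]
    for cov in covariates:
        if cov not in sheet.columns:
            raise ValueError(f"sample sheet lacks covariate {cov!r}")
        col = sheet[cov]
        if pd.api.types.is_numeric_dtype(col):
            cov_cols.append(col.to_numpy(dtype=float))
        else:
            codes, levels = pd.factorize(col.astype(str), sort=True)
            for lev in range(1, len(levels)):  # drop first level
                cov_cols.append((codes == lev).astype(float))
    design_cov = np.column_stack(cov_cols)  # includes intercept

    n_batch = len(batch_levels)
    batch_onehot = np.zeros((len(sheet), n_batch))
    batch_onehot[np.arange(len(sheet)), batch_codes] = 1.0
    # full design: batch indicators replace the intercept
    full = np.column_stack([batch_onehot, design_cov[:, 1:]])
    if n_batch > 1 and np.linalg.matrix_rank(full) < full.shape[1]:
        raise ValueError(
            "batch confounded with covariate: the design matrix "
            "(batch indicators + covariates) is rank deficient"
        )
    return batch_codes, batch_levels.to_numpy() if hasattr(batch_levels, "to_numpy") else np.asarray(batch_levels), design_cov, full


def fit_correction(
    m: MMatrix,
    sheet: pd.DataFrame,
    batch_var: str = "slide",
    covariates=(),
    method: str = "eb_location_scale",
) -> CorrectionModel:
    """Fit a batch-correction model on an M matrix.

    ``covariates`` name sample-sheet columns of biological variance to
    retain: categorical columns are dummy-coded, numeric columns enter the
    linear design as given. A single-level batch yields a no-op model.
    Probes with zero variance are rejected (inject noise via shift_betas
    first); a batch confounded with a covariate is rejected explicitly.
    """
    if method not in ("eb_location_scale", "mean_center"):
        raise ValueError(f"unknown method {method!r}")
    covariates = tuple(covariates)
    batch_codes, batch_levels, design_cov, full = _build_design(
        sheet, m.sample_ids, batch_var, covariates
    )
    Y = m.values  # probes x samples
    if not np.isfinite(Y).all():
        raise ValueError("M matrix must be finite")
    zero_var = Y.var(axis=1) == 0.0
    if zero_var.any():
        probe = m.probe_ids[np.argmax(zero_var)]
        raise ValueError(
            f"probe {probe!r} has zero variance; empirical-Bayes standardisation "
            "would divide by zero — apply shift_betas noise injection first"
        )

    model = CorrectionModel(
        method=method,
        batch_var=batch_var,
        covariates=covariates,
        sample_ids=m.sample_ids,
        probe_ids=m.probe_ids,
        batch_levels=batch_levels,
        batch_codes=batch_codes,
        design_cov=design_cov,
    )
    n_batch = len(batch_levels)
    if n_batch == 1:
        return model  # nothing to correct; apply is the identity

    n_array = Y.shape[1]
    counts = np.bincount(batch_codes).astype(float)

    if method == "mean_center":
        coef, *_ = np.linalg.lstsq(design_cov, Y.T, rcond=None)
        resid = Y - (design_cov @ coef).T
        means = np.vstack(
            [resid[:, batch_codes == b].mean(axis=1) for b in range(n_batch)]
        )
        model.cov_coef = coef
        model.batch_residual_means = means
        return model

    # --- empirical-Bayes location/scale -----------------------------------
    X = np.column_stack([np.eye(n_batch)[batch_codes], design_cov[:, 1:]])
    B_hat, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # p x probes
    grand_mean = (counts / n_array) @ B_hat[:n_batch]
    var_pooled = ((Y - (X @ B_hat).T) ** 2).mean(axis=1)

    if design_cov.shape[1] > 1:
        stand_mean = grand_mean[:, None] + (design_cov[:, 1:] @ B_hat[n_batch:]).T
    else:
        stand_mean = np.tile(grand_mean[:, None], (1, n_array))

    Z = (Y - stand_mean) / np.sqrt(var_pooled)[:, None]
    gamma_hat = np.vstack([Z[:, batch_codes == b].mean(axis=1) for b in range(n_batch)])
    delta_hat_sq = np.vstack(
        [Z[:, batch_codes == b].var(axis=1, ddof=1) for b in range(n_batch)]
    )

    gamma_bar = gamma_hat.mean(axis=1)
    tau_sq = gamma_hat.var(axis=1, ddof=1)
    d_mean = delta_hat_sq.mean(axis=1)
    d_var = delta_hat_sq.var(axis=1, ddof=1)
    aprior = (2.0 * d_var + d_mean**2) / d_var
    bprior = (d_mean * d_var + d_mean**3) / d_var

    gamma_star = np.empty_like(gamma_hat)
    delta_star_sq = np.empty_like(delta_hat_sq)
    for b in range(n_batch):
        in_batch = batch_codes == b
        n_b = counts[b]
        g_old = gamma_hat[b].copy()
        d_old = delta_hat_sq[b].copy()
        Zb = Z[:, in_batch]
        for _ in range(EB_MAX_ITER):
            g_new = (n_b * tau_sq[b] * gamma_hat[b] + d_old * gamma_bar[b]) / (
                n_b * tau_sq[b] + d_old
            )
            sum2 = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * sum2 + bprior[b]) / (n_b / 2.0 + aprior[b] - 1.0)
            change = max(
                np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
                np.max(np.abs(d_new - d_old) / d_old),
            )
            g_old, d_old = g_new, d_new
            if change < EB_CONVERGENCE:
                break
        gamma_star[b] = g_old
        delta_star_sq[b] = d_old

    model.stand_mean = stand_mean
    model.var_pooled = var_pooled
    model.gamma_hat = gamma_hat
    model.delta_hat_sq = delta_hat_sq
    model.gamma_star = gamma_star
    model.delta_star_sq = delta_star_sq
    model.prior_params = {
        "gamma_bar": gamma_bar,
        "tau_sq": tau_sq,
        "aprior": aprior,
        "bprior": bprior,
    }
    return model


def apply_correction(m: MMatrix, model: CorrectionModel) -> MMatrix:
    """Apply a fitted correction model; samples must match the fit."""
    if not m.sample_ids.equals(model.sample_ids):
        raise ValueError("samples do not match the fitted model")
    if not m.probe_ids.equals(model.probe_ids):
        raise ValueError("probes do not match the fitted model")
    Y = m.values
    if model.n_batches == 1:
        return MMatrix(m.frame.copy())

    codes = model.batch_codes
    if model.method == "mean_center":
        corrected = Y - model.batch_residual_means[codes].T
    else:
        Z = (Y - model.stand_mean) / np.sqrt(model.var_pooled)[:, None]
        adj = (Z - model.gamma_star[codes].T) / np.sqrt(model.delta_star_sq[codes].T)
        corrected = adj * np.sqrt(model.var_pooled)[:, None] + model.stand_mean
    return MMatrix(
        pd.DataFrame(corrected, index=m.probe_ids, columns=m.sample_ids)
    )


def sequential_correction(
    m: MMatrix,
    sheet: pd.DataFrame,
    batch_vars,
    covariates=(),
    method: str = "eb_location_scale",
) -> MMatrix:
    """Remove several batch structures in sequence (e.g. superbatch, then slide)."""
    out = m
    for batch_var in batch_vars:
        model = fit_correction(out, sheet, batch_var=batch_var,
                               covariates=covariates, method=method)
        out = apply_correction(out, model)
    return out
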