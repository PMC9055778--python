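"""Conversions between signal, beta and M representations.

The two methylation metrics in routine use are the beta value,
``beta = Meth / (Meth + Unmeth)``, bounded in [0, 1] and directly
interpretable as a methylated fraction, and the M value,
``M = log2(Meth / Unmeth) = logit2(beta)``, unbounded and therefore the
appropriate scale for location/scale batch correction. ``shift_betas``
implements the edge-case policy needed before the logit transform: exact 0/1
values are nudged inside the open interval, missing values (both signals
zero) become beta = 0.5 (M = 0), and probes left with zero variance receive a
trace of Gaussian noise so that downstream empirical-Bayes correction, which
divides by a per-probe variance, cannot encounter an exact zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import BetaMatrix, MMatrix, SignalMatrices

__all__ = ["signals_to_beta", "beta_to_m", "m_to_beta", "shift_betas", "logit2", "ilogit2"]


def signals_to_beta(signals: SignalMatrices, offset: float = 0.0) -> BetaMatrix:
    """Form beta values from methylated/unmethylated intensities.

    beta = meth / (meth + unmeth + offset). Cells where both signals are zero
    are emitted as missing (NaN) regardless of the offset; they are resolved
    to beta = 0.5 later by :func:`shift_betas`. ``offset`` defaults to 0; a
    value of 100 reproduces the convention of several preprocessing stacks.
    """
    if offset < 0:
        raise ValueError(f"offset must be non-negative, got {offset}")
    meth = signals.meth.to_numpy()
    unmeth = signals.unmeth.to_numpy()
    denom = meth + unmeth + offset
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(denom > 0, meth / np.where(denom > 0, denom, 1.0), np.nan)
    both_zero = (meth == 0) & (unmeth == 0)
    beta = np.where(both_zero, np.nan, beta)
    return BetaMatrix(
        pd.DataFrame(beta, index=signals.probe_ids, columns=signals.sample_ids)
    )


def logit2(beta: np.ndarray) -> np.ndarray:
    """Elementwise M = log2(beta / (1 - beta)); caller guarantees beta in (0,1)."""
    beta = np.asarray(beta, dtype=float)
    return np.log2(beta) - np.log2(1.0 - beta)


def ilogit2(m: np.ndarray) -> np.ndarray:
    """Elementwise beta = 2**M / (1 + 2**M), overflow-safe for any finite M.

    Computed as exp2(-|M|) terms only, so |M| up to ~1000 maps to a subnormal
    beta strictly above 0 (or below 1) rather than overflowing.
    """
    m = np.asarray(m, dtype=float)
    e = np.exp2(-np.abs(m))
    return np.where(m < 0, e, 1.0) / (1.0 + e)


def beta_to_m(beta: BetaMatrix) -> MMatrix:
    """logit2 transform of a beta matrix; requires all values strictly in (0, 1)."""
    vals = beta.values
    if np.isnan(vals).any():
        raise ValueError(
            "beta matrix contains missing values; run shift_betas before beta_to_m"
        )
    if (vals <= 0.0).any() or (vals >= 1.0).any():
        raise ValueError(
            "beta values of exactly 0 or 1 cannot be logit-transformed; "
            "run shift_betas first"
        )
    return MMatrix(
        pd.DataFrame(logit2(vals), index=beta.probe_ids, columns=beta.sample_ids)
    )


def m_to_beta(m: MMatrix) -> BetaMatrix:
    """Inverse logit2; very large |M| asymptote to 0/1 without overflow."""
    return BetaMatrix(
        pd.DataFrame(ilogit2(m.values), index=m.probe_ids, columns=m.sample_ids)
    )


def shift_betas(
    beta: BetaMatrix,
    eps: float = 1e-4,
    noise_sd: float = 1e-8,
    seed: int | None = None,
) -> BetaMatrix:
    """Move beta values off the [0, 1] boundary and resolve missing cells.

    Substitution rules, applied in order:

    1. missing (NaN, e.g. both signals zero) -> 0.5 (so M = 0);
    2. exactly 0 -> ``eps``; exactly 1 -> ``1 - eps``;
    3. probes whose post-substitution values are all identical (zero
       variance) receive i.i.d. Gaussian noise of SD ``noise_sd`` on every
       value, then are re-clipped into the open interval.

    Noise is restricted to zero-variance probes because its sole purpose is
    to keep variance-dividing correction algorithms from failing on constant
    features; with ``noise_sd = 0`` the operation is idempotent.
    """
    if not (0.0 < eps < 0.5):
        raise ValueError(f"eps must lie in (0, 0.5), got {eps}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    if noise_sd > 0 and seed is None:
        raise ValueError("seed is required when noise_sd > 0")

    vals = beta.values.copy()
    vals[np.isnan(vals)] = 0.5
    vals[vals == 0.0] = eps
    vals[vals == 1.0] = 1.0 - eps

    if noise_sd > 0:
        constant = np.ptp(vals, axis=1) == 0.0
        if constant.any():
            rng = np.random.default_rng(seed)
            noise = rng.normal(0.0, noise_sd, size=(int(constant.sum()), vals.shape[1]))
            vals[constant] = vals[constant] + noise
    np.clip(vals, 1e-12, 1.0 - 1e-12, out=vals)
    return BetaMatrix(
        pd.DataFrame(vals, index=beta.probe_ids, columns=beta.sample_ids)
    )
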