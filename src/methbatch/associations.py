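"""Attribution of modal probes to biological and technical factors.

Each multi-modal probe is tested for association of its cluster assignment
with gender, batch (slide), superbatch (categorical factors: exact Fisher
test, or a Monte-Carlo chi-square when the contingency table is too large
for exact computation) and with a continuous cell-composition covariate
(one-way ANOVA). Autosomal probes with 2 or 3 clusters are additionally
tested for departure from Hardy-Weinberg equilibrium with the Levene-Haldane
exact test, treating ordered cluster sizes as genotype class counts — modal
patterns driven by a SNP at or near the probed CpG should assort like
genotypes. P values are Benjamini-Hochberg adjusted within each factor
across probes; associations use a stringent adjusted p < 0.001.
"""

from __future__ import annotations

import warnings
from math import comb, lgamma, log

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .clustering import ClusterModel

__all__ = [
    "TableTooLargeError",
    "fisher_cluster_association",
    "chisq_monte_carlo",
    "continuous_association",
    "hwe_exact",
    "bh_fdr",
    "attribute_modal_probes",
]

FISHER_MAX_CELLS = 30  # above this, callers switch to chisq_monte_carlo
_ENUM_CAP = 2_000_000  # hard cap on enumerated tables for the exact test


class TableTooLargeError(ValueError):
    """Raised when a contingency table exceeds the exact-test budget."""


def _contingency(a, b) -> np.ndarray:
    a_codes, _ = pd.factorize(pd.Series(a), sort=True)
    b_codes, _ = pd.factorize(pd.Series(b), sort=True)
    table = np.zeros((a_codes.max() + 1, b_codes.max() + 1), dtype=np.int64)
    np.add.at(table, (a_codes, b_codes), 1)
    return table


def _log_table_prob(table, row_m, col_m, n) -> float:
    lp = (
        sum(lgamma(r + 1) for r in row_m)
        + sum(lgamma(c + 1) for c in col_m)
        - lgamma(n + 1)
    )
    for v in np.asarray(table).flat:
        lp -= lgamma(v + 1)
    return lp


def _fisher_exact_enumerated(table: np.ndarray) -> float:
    """Two-sided exact conditional p by enumeration of all tables with the
    observed margins, summing probabilities <= that of the observed table."""
    row_m = table.sum(axis=1)
    col_m = table.sum(axis=0)
    n = int(table.sum())
    obs_lp = _log_table_prob(table, row_m, col_m, n)
    base_lp = (
        sum(lgamma(r + 1) for r in row_m)
        + sum(lgamma(c + 1) for c in col_m)
        - lgamma(n + 1)
    )
    r, c = table.shape
    # cheap upper bound on the number of tables before recursing: the first
    # r-1 rows each admit at most C(row_margin + c - 1, c - 1) compositions
    bound = 1.0
    for rm in row_m[:-1]:
        bound *= comb(int(rm) + c - 1, c - 1)
        if bound > _ENUM_CAP:
            raise TableTooLargeError(
                "contingency table admits too many margin-preserving tables "
                "for exact enumeration; use chisq_monte_carlo"
            )
    total = 0.0
    count = 0

    def recurse(row: int, remaining_cols: np.ndarray, lp_cells: float):
        nonlocal total, count
        if row == r - 1:
            # last row forced by column margins
            lp = base_lp + lp_cells - sum(lgamma(v + 1) for v in remaining_cols)
            if lp <= obs_lp + 1e-9:
                total += np.exp(lp)
            return
        # enumerate compositions of row_m[row] over columns, bounded by remaining
        target = int(row_m[row])

        def fill(col: int, left: int, lp_acc: float, used: list[int]):
            nonlocal count
            count += 1
            if count > _ENUM_CAP:
                raise TableTooLargeError(
                    "contingency table too large for exact enumeration; "
                    "use chisq_monte_carlo"
                )
            if col == c - 1:
                if left <= remaining_cols[col]:
                    used.append(left)
                    recurse(
                        row + 1,
                        remaining_cols - np.array(used),
                        lp_cells + lp_acc - lgamma(left + 1),
                    )
                    used.pop()
                return
            for v in range(min(left, int(remaining_cols[col])) + 1):
                used.append(v)
                fill(col + 1, left - v, lp_acc - lgamma(v + 1), used)
                used.pop()

        fill(0, target, 0.0, [])

    recurse(0, col_m.astype(np.int64).copy(), 0.0)
    return min(float(total), 1.0)


def fisher_cluster_association(assignments, factor) -> float:
    """Two-sided Fisher exact p for cluster x categorical-factor independence.

    Exact for any table whose cell count is within ``FISHER_MAX_CELLS`` and
    whose enumeration fits the budget; otherwise raises
    :class:`TableTooLargeError`, directing the caller to
    :func:`chisq_monte_carlo`.
    """
    table = _contingency(assignments, factor)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least 2 clusters and 2 factor levels")
    if table.size > FISHER_MAX_CELLS:
        raise TableTooLargeError(
            f"{table.shape[0]}x{table.shape[1]} table exceeds the "
            f"{FISHER_MAX_CELLS}-cell exact-test threshold; use chisq_monte_carlo"
        )
    if table.shape == (2, 2):
        return float(stats.fisher_exact(table).pvalue)
    return _fisher_exact_enumerated(table)


def chisq_monte_carlo(assignments, factor, B: int = 10_000, seed: int | None = None) -> float:
    """Chi-square independence test with a permutation (simulated) p value.

    p = (1 + #{permuted chi2 >= observed}) / (B + 1); deterministic given the
    seed. Degenerate tables (fewer than two clusters or factor levels) give
    p = 1 with a warning.
    """
    if B < 999:
        raise ValueError(f"B must be at least 999, got {B}")
    a_codes, a_levels = pd.factorize(pd.Series(assignments), sort=True)
    f_codes, f_levels = pd.factorize(pd.Series(factor), sort=True)
    C, L = len(a_levels), len(f_levels)
    if C < 2 or L < 2:
        warnings.warn("degenerate contingency table; returning p = 1", stacklevel=2)
        return 1.0
    n = a_codes.size

    def chi2_of(fc: np.ndarray) -> np.ndarray:
        # fc: (B, n) permuted factor codes
        flat = a_codes[None, :] * L + fc
        offsets = (np.arange(fc.shape[0]) * C * L)[:, None]
        counts = np.bincount(
            (flat + offsets).ravel(), minlength=fc.shape[0] * C * L
        ).reshape(fc.shape[0], C, L)
        row = counts.sum(axis=2, keepdims=True)
        col = counts.sum(axis=1, keepdims=True)
        expected = row * col / n
        with np.errstate(invalid="ignore", divide="ignore"):
            cells = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
        return cells.sum(axis=(1, 2))

    observed = float(chi2_of(f_codes[None, :])[0])
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(f_codes, (B, 1)), axis=1)
    sims = chi2_of(perms)
    return float((1 + int((sims >= observed - 1e-12).sum())) / (B + 1))


def continuous_association(assignments, covariate) -> float:
    """One-way ANOVA F-test p for a continuous covariate across clusters."""
    x = np.asarray(covariate, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("covariate must be finite")
    assignments = np.asarray(assignments)
    labels = np.unique(assignments)
    if labels.size < 2:
        raise ValueError("need at least 2 clusters")
    groups = [x[assignments == lab] for lab in labels]
    n = x.size
    k = labels.size
    df_within = n - k
    if df_within < 1:
        raise ValueError("every cluster is a singleton; no within-cluster variance")
    grand = x.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ss_within == 0.0:
        return 1.0 if ss_between == 0.0 else 0.0
    f_stat = (ss_between / (k - 1)) / (ss_within / df_within)
    return float(stats.f.sf(f_stat, k - 1, df_within))


def hwe_exact(cluster_sizes) -> float:
    """Levene-Haldane exact test for Hardy-Weinberg equilibrium on cluster sizes.

    ``cluster_sizes`` holds 2 or 3 counts ordered by cluster centroid. Three
    clusters map directly to genotype classes (hom, het, hom) with the middle
    cluster as heterozygotes. Two clusters map to the two most populous
    genotype classes of a rare-allele pattern: the larger cluster is the
    common homozygote, the smaller the heterozygote, and the absent minor
    homozygote class gets count 0. The p value is the sum of the conditional
    probabilities (given allele counts) of all heterozygote counts no more
    probable than the observed one.
    """
    sizes = [int(s) for s in cluster_sizes]
    if len(sizes) == 2:
        big, small = (sizes[0], sizes[1]) if sizes[0] >= sizes[1] else (sizes[1], sizes[0])
        n_aa, n_ab, n_bb = big, small, 0
    elif len(sizes) == 3:
        n_aa, n_ab, n_bb = sizes
    else:
        raise ValueError(f"expected 2 or 3 cluster sizes, got {len(sizes)}")
    if min(n_aa, n_ab, n_bb) < 0 or n_aa + n_ab + n_bb < 1:
        raise ValueError("cluster sizes must be non-negative with total >= 1")

    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab

    def logp(h: int) -> float:
        return (
            lgamma(n + 1)
            - lgamma((n_a - h) / 2 + 1)
            - lgamma(h + 1)
            - lgamma((n_b - h) / 2 + 1)
            + h * log(2.0)
            + lgamma(n_a + 1)
            + lgamma(n_b + 1)
            - lgamma(2 * n + 1)
        )
    obs = logp(n_ab)
    h_values = range(n_a % 2, min(n_a, n_b) + 1, 2)
    total = sum(np.exp(lp) for h in h_values if (lp := logp(h)) <= obs + 1e-9)
    return min(float(total), 1.0)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attribute_modal_probes(
    clusters: dict[str, ClusterModel],
    sheet: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
    alpha: float = 0.001,
    B: int = 10_000,
    seed: int | None = 0,
    cell_var: str = "cell_fraction",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attribute every modal probe (k > 1) to tested factors.

    ``sheet`` rows must be in the same sample order as the matrix the
    clusters were fitted on. Returns (per-probe attribution table,
    upset-style intersection tally). A probe may carry several factor flags;
    probes with none are labelled unknown.
    """
    modal = {pid: m for pid, m in clusters.items() if m.k > 1}
    factor_cols = {"gender": "gender", "batch": "slide", "superbatch": "superbatch"}
    available = {}
    for factor, col in factor_cols.items():
        if col in sheet.columns:
            available[factor] = sheet[col].to_numpy()
        else:
            warnings.warn(f"sample sheet lacks {col!r}; skipping {factor}", stacklevel=2)
    cell = sheet[cell_var].to_numpy(dtype=float) if cell_var in sheet.columns else None
    if cell is None:
        warnings.warn(f"sample sheet lacks {cell_var!r}; skipping cell factor", stacklevel=2)

    if not modal:
        empty = pd.DataFrame(index=pd.Index([], name="probe_id"))
        return empty, pd.DataFrame(columns=["count"])

    probe_ids = sorted(modal)
    records = {pid: {"k": modal[pid].k} for pid in probe_ids}

    raw: dict[str, dict[str, float]] = {f: {} for f in available}
    for factor, values in available.items():
        for pid in probe_ids:
            assignments = modal[pid].assignments
            try:
                p = fisher_cluster_association(assignments, values)
                used = "fisher"
            except TableTooLargeError:
                p = chisq_monte_carlo(assignments, values, B=B, seed=seed)
                used = "chisq_mc"
            raw[factor][pid] = p
            records[pid][f"test_{factor}"] = used
    if cell is not None:
        raw["cell"] = {
            pid: continuous_association(modal[pid].assignments, cell)
            for pid in probe_ids
        }

    # HWE on autosomal probes with 2 or 3 clusters
    def autosomal(pid: str) -> bool:
        if annotations is None or "chromosome" not in getattr(annotations, "columns", []):
            return True
        if pid not in annotations.index:
            return True
        chrom = str(annotations.loc[pid, "chromosome"]).removeprefix("chr")
        return chrom not in {"X", "Y"}

    hwe_ids = [pid for pid in probe_ids if modal[pid].k in (2, 3) and autosomal(pid)]
    raw["hwe"] = {pid: hwe_exact(modal[pid].cluster_sizes) for pid in hwe_ids}

    for factor, pvals in raw.items():
        if not pvals:
            continue
        ids = list(pvals)
        adj = bh_fdr([pvals[pid] for pid in ids])
        for pid, p_raw, p_adj in zip(ids, (pvals[pid] for pid in ids), adj):
            records[pid][f"p_{factor}"] = p_raw
            records[pid][f"q_{factor}"] = p_adj
            if factor == "hwe":
                # non-rejection = consistent with HWE assortment
                records[pid]["hwe_consistent"] = bool(p_adj >= alpha)
            else:
                records[pid][f"sig_{factor}"] = bool(p_adj < alpha)

    table = pd.DataFrame.from_dict(records, orient="index")
    table.index.name = "probe_id"

    if annotations is not None:
        for col in ("snp_at_site", "snp_within_10bp", "cross_hybridising"):
            if col in annotations.columns:
                table[col] = (
                    annotations[col].reindex(table.index).fillna(False).astype(bool)
                )
        if "chromosome" in annotations.columns:
            chrom = (
                annotations["chromosome"]
                .reindex(table.index)
                .astype(str)
                .str.removeprefix("chr")
            )
            table["chrX"] = (chrom == "X").to_numpy()
            table["chrY"] = (chrom == "Y").to_numpy()

    flag_cols = [
        c
        for c in table.columns
        if c.startswith("sig_")
        or c == "hwe_consistent"
        or c in ("snp_at_site", "snp_within_10bp", "cross_hybridising", "chrX", "chrY")
    ]
    flags = table[flag_cols].eq(True)  # NaN (untested) counts as no flag
    table["unknown"] = ~flags.any(axis=1)

    tally = (
        flags.assign(unknown=table["unknown"])
        .groupby(list(flags.columns) + ["unknown"])
        .size()
        .sort_values(ascending=False)
        .rename("count")
        .reset_index()
    )
    return table, tally
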