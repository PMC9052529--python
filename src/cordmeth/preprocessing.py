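"""Probe/sample QC, beta/M transforms, winsorization, and batch adjustment.

Quantiles throughout the package use linear interpolation between order
statistics (numpy's default, R's "type 7"); epimutation calls and
winsorization depend on this choice, so it is fixed rather than exposed.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .containers import BetaMatrix, MMatrix

log = logging.getLogger(__name__)

#: Probe-removal reasons, in the fixed precedence order used for counting.
FILTER_REASONS = ("chrom", "snp", "crossreactive")


def filter_samples(
    beta: BetaMatrix, max_failed_fraction: float = 0.05
) -> BetaMatrix:
    """Drop arrays with too many failed probes; impute the rest.

    Samples whose fraction of failed measurements exceeds
    ``max_failed_fraction`` are removed. Remaining failed entries are
    replaced by the CpG's row median across retained samples, keeping the
    matrix dense for deconvolution and batch adjustment.
    """
    if beta.failure_mask is None:
        return beta
    mask = beta.failure_mask.to_numpy(dtype=bool)
    failed_frac = mask.mean(axis=0)
    keep = failed_frac <= max_failed_fraction
    if not keep.any():
        raise ValueError("all samples exceed the failed-probe threshold")
    n_removed = int((~keep).sum())
    values = beta.values.loc[:, keep].copy()
    sub_mask = mask[:, keep]
    n_imputed = int(sub_mask.sum())
    if n_imputed:
        arr = values.to_numpy(dtype=float)
        arr_masked = np.where(sub_mask, np.nan, arr)
        row_med = np.nanmedian(arr_masked, axis=1)
        # rows failing everywhere fall back to 0.5
        row_med = np.where(np.isfinite(row_med), row_med, 0.5)
        arr[sub_mask] = np.broadcast_to(row_med[:, None], arr.shape)[sub_mask]
        values = pd.DataFrame(arr, index=values.index, columns=values.columns)
    log.info(
        "filter_samples: removed %d samples, imputed %d failed entries",
        n_removed, n_imputed,
    )
    return BetaMatrix(values=values, failure_mask=None)


def filter_probes(
    beta: BetaMatrix, annotation: pd.DataFrame
) -> tuple[BetaMatrix, dict[str, int]]:
    """Remove sex-chromosome, SNP-overlapping, and cross-reactive probes.

    ``annotation`` must carry one row per CpG (index or ``cpg_id`` column)
    with columns ``chrom``, ``snp_flag``, ``crossreactive_flag``. A probe
    matching several criteria is counted once, under the first matching
    reason in the fixed order chrom > snp > crossreactive.

    Returns the filtered matrix and the per-reason removal counts.
    """
    ann = annotation
    if "cpg_id" in ann.columns:
        ann = ann.set_index("cpg_id")
    missing = beta.cpg_ids.difference(ann.index)
    if len(missing):
        shown = ", ".join(map(str, missing[:10]))
        raise ValueError(
            f"{len(missing)} CpGs missing from annotation: {shown}"
        )
    ann = ann.loc[beta.cpg_ids]
    sex = ann["chrom"].astype(str).isin(["chrX", "chrY", "X", "Y"]).to_numpy()
    snp = ann["snp_flag"].astype(int).to_numpy() == 1
    xr = ann["crossreactive_flag"].astype(int).to_numpy() == 1
    counts = {
        "chrom": int(sex.sum()),
        "snp": int((snp & ~sex).sum()),
        "crossreactive": int((xr & ~sex & ~snp).sum()),
    }
    keep = ~(sex | snp | xr)
    values = beta.values.loc[keep]
    fmask = beta.failure_mask.loc[keep] if beta.failure_mask is not None else None
    log.info("filter_probes: removed %s", counts)
    return BetaMatrix(values=values, failure_mask=fmask), counts


def beta_to_m(beta: BetaMatrix, epsilon: float = 1e-3) -> MMatrix:
    """M = log2(b' / (1 - b')) with b' clipped to [epsilon, 1 - epsilon]."""
    if not 0 < epsilon < 0.5:
        raise ValueError("epsilon must lie in (0, 0.5)")
    b = beta.values.to_numpy(dtype=float)
    b = np.clip(b, epsilon, 1.0 - epsilon)
    m = np.log2(b / (1.0 - b))
    return MMatrix(
        values=pd.DataFrame(m, index=beta.cpg_ids, columns=beta.sample_ids),
        epsilon=epsilon,
    )


def m_to_beta(m: MMatrix) -> BetaMatrix:
    """Inverse transform: beta = 2^M / (1 + 2^M)."""
    arr = m.values.to_numpy(dtype=float)
    # logistic in base 2, numerically stable for large |M|
    b = np.where(arr >= 0, 1.0 / (1.0 + 2.0**-arr), 2.0**arr / (1.0 + 2.0**arr))
    return BetaMatrix(
        values=pd.DataFrame(b, index=m.values.index, columns=m.values.columns)
    )


def winsorize(
    values: pd.DataFrame, lower_q: float = 0.05, upper_q: float = 0.95
) -> pd.DataFrame:
    """Clamp each row at its lower_q / upper_q quantiles (type-7)."""
    if not 0 <= lower_q < upper_q <= 1:
        raise ValueError("need 0 <= lower_q < upper_q <= 1")
    arr = values.to_numpy(dtype=float)
    lo = np.quantile(arr, lower_q, axis=1, keepdims=True)
    hi = np.quantile(arr, upper_q, axis=1, keepdims=True)
    return pd.DataFrame(
        np.clip(arr, lo, hi), index=values.index, columns=values.columns
    )


def _eb_iterate(
    g_hat: np.ndarray,
    d_star_init: np.ndarray,
    g_bar: float,
    t2: float,
    a: float,
    b: float,
    Z_b: np.ndarray,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Standard parametric EB moment iterations for one batch.

    Alternates the posterior mean of the batch location (normal prior) and
    of the batch scale (inverse-gamma prior) until both stabilise.
    """
    n_b = Z_b.shape[1]
    g_old = g_hat.copy()
    d_old = d_star_init.copy()
    for _ in range(max_iter):
        g_new = (t2 * n_b * g_hat + d_old * g_bar) / (t2 * n_b + d_old)
        ssq = ((Z_b - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * ssq + b) / (n_b / 2.0 + a - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < tol:
            break
    return g_old, d_old


def combat_adjust(
    m: MMatrix,
    batch_labels: pd.Series | np.ndarray,
    covariate_design: Optional[np.ndarray] = None,
) -> MMatrix:
    """Parametric empirical-Bayes location/scale batch adjustment.

    Per probe, a linear model with batch indicators (and optional protected
    covariates) is fitted; data are standardised; per-batch location and
    scale parameters are shrunk towards their across-probe priors (normal
    and inverse-gamma, hyperparameters by method of moments, solved by the
    usual fixed-point iteration); the adjusted data are back-transformed.

    A single batch is returned unchanged. Covariate effects are preserved.
    """
    Y = m.values.to_numpy(dtype=float)
    batch = pd.Series(np.asarray(batch_labels), dtype="object")
    levels = pd.unique(batch)
    if len(levels) == 1:
        return MMatrix(values=m.values.copy(), epsilon=m.epsilon)
    counts = batch.value_counts()
    if (counts < 2).any():
        raise ValueError("every batch needs at least 2 samples")
    n_probes, n = Y.shape
    if n != len(batch):
        raise ValueError("batch labels do not match sample count")

    B = np.column_stack([(batch == lv).to_numpy(float) for lv in levels])
    design = B if covariate_design is None else np.column_stack(
        [B, np.asarray(covariate_design, dtype=float)]
    )
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError("singular design (covariates confounded with batch?)")

    # probe-wise GLS fit: coefficients for batches then covariates
    beta_hat = np.linalg.solve(design.T @ design, design.T @ Y.T)  # (q, probes)
    n_batches = B.shape[1]
    n_b = B.sum(axis=0)
    grand = (n_b / n) @ beta_hat[:n_batches]  # weighted grand mean per probe
    stand_mean = grand[:, None] * np.ones((1, n))
    if covariate_design is not None:
        cov_part = (design[:, n_batches:] @ beta_hat[n_batches:]).T
        stand_mean = stand_mean + cov_part
    var_pooled = ((Y - (design @ beta_hat).T) ** 2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-12)
    sd = np.sqrt(var_pooled)[:, None]
    Z = (Y - stand_mean) / sd

    bayes = Z.copy()
    for j, lv in enumerate(levels):
        sel = (batch == lv).to_numpy(bool)
        Z_b = Z[:, sel]
        g_hat = Z_b.mean(axis=1)
        d_hat = Z_b.var(axis=1, ddof=1)
        g_bar = g_hat.mean()
        t2 = g_hat.var(ddof=1)
        # inverse-gamma moment estimators for the scale prior
        m_d = d_hat.mean()
        s2_d = d_hat.var(ddof=1)
        a = (2.0 * s2_d + m_d**2) / s2_d if s2_d > 0 else 1e6
        b = (m_d * s2_d + m_d**3) / s2_d if s2_d > 0 else m_d
        g_star, d_star = _eb_iterate(g_hat, d_hat, g_bar, t2, a, b, Z_b)
        bayes[:, sel] = (Z_b - g_star[:, None]) / np.sqrt(d_star)[:, None]

    adjusted = bayes * sd + stand_mean
    return MMatrix(
        values=pd.DataFrame(adjusted, index=m.values.index, columns=m.values.columns),
        epsilon=m.epsilon,
    )
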