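"""Epigenetic gestational age (EGA) from linear methylation clocks.

A clock is an intercept plus per-CpG weights applied to beta values; EGA
acceleration is the residual of EGA regressed on clinical GA (positive =
epigenetically older than the recorded GA).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import BetaMatrix, ClockModel, CovariateSpec
from .ewas import build_design
from .robust import huber_fit_matrix

log = logging.getLogger(__name__)


def predict_ega(
    beta: BetaMatrix, clock: ClockModel, missing_policy: str = "mean_impute"
) -> pd.Series:
    """Apply a linear clock: EGA = intercept + sum(coef_i * beta_i).

    At least half the clock CpGs must be present, else an error. Missing
    clock CpGs (e.g. removed by QC filtering) are handled per
    ``missing_policy``: ``"mean_impute"`` (default) lets each missing CpG
    contribute coef x the cohort grand-mean beta, so the prediction is not
    systematically shifted; ``"zero"`` drops the missing terms. The number
    of missing CpGs is logged.
    """
    coefs = clock.coefficients
    present = coefs.index.intersection(beta.cpg_ids)
    n_missing = len(coefs) - len(present)
    if len(present) < 0.5 * len(coefs):
        raise ValueError(
            f"only {len(present)}/{len(coefs)} clock CpGs present (<50%)"
        )
    if n_missing:
        log.info("predict_ega[%s]: %d clock CpGs missing", clock.name, n_missing)
    B = beta.values.loc[present].to_numpy(dtype=float)
    ega = clock.intercept + coefs.loc[present].to_numpy() @ B
    if n_missing and missing_policy == "mean_impute":
        grand_mean = float(beta.values.to_numpy(dtype=float).mean())
        missing = coefs.index.difference(beta.cpg_ids)
        ega = ega + float(coefs.loc[missing].sum()) * grand_mean
    elif n_missing and missing_policy != "zero":
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    return pd.Series(ega, index=beta.sample_ids, name=f"ega_{clock.name}")


def ega_acceleration(ega: pd.Series, ga: pd.Series | np.ndarray) -> pd.Series:
    """Residuals of OLS of EGA on clinical GA.

    Positive values mark samples epigenetically older than their recorded
    gestational age. Residuals average zero and are orthogonal to GA.
    """
    y = np.asarray(ega, dtype=float)
    g = np.asarray(ga, dtype=float)
    if len(y) != len(g) or len(y) < 3:
        raise ValueError("need >= 3 aligned samples")
    X = sm.add_constant(g)
    resid = sm.OLS(y, X).fit().resid
    index = ega.index if isinstance(ega, pd.Series) else None
    return pd.Series(resid, index=index, name="ega_acceleration")


@dataclass
class AccelerationAssociation:
    unadjusted_coef: float
    unadjusted_p: float
    adjusted_coef: float
    adjusted_p: float


def acceleration_association(
    acceleration: pd.Series,
    sample_sheet: pd.DataFrame,
    spec: CovariateSpec,
    composition=None,
    robust: bool = False,
) -> AccelerationAssociation:
    """Regress EGA acceleration on the phenotype, without and with covariates.

    Ordinary least squares by default; ``robust=True`` switches the
    adjusted model to the Huber estimator.
    """
    ss = sample_sheet.loc[acceleration.index]
    y = acceleration.to_numpy(dtype=float)
    pheno = ss[spec.phenotype].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        return AccelerationAssociation(0.0, 1.0, 0.0, 1.0)
    X0 = sm.add_constant(pheno)
    fit0 = sm.OLS(y, X0).fit()
    X, names = build_design(ss, spec, composition)
    j = names.index(spec.phenotype)
    if robust:
        fit = huber_fit_matrix(X, y)
        coef, p = float(fit.coef[j, 0]), float(fit.pvalues[j, 0])
    else:
        res = sm.OLS(y, X).fit()
        coef, p = float(res.params[j]), float(res.pvalues[j])
    return AccelerationAssociation(
        unadjusted_coef=float(fit0.params[1]),
        unadjusted_p=float(fit0.pvalues[1]),
        adjusted_coef=coef,
        adjusted_p=p,
    )
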