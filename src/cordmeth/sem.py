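"""Stochastic epigenetic mutations (SEMs) and epimutation load.

A SEM is a methylation value lying more than three interquartile ranges
above the third quartile or below the first quartile of that CpG's
cross-sample distribution. Quartiles use linear interpolation between
order statistics (type 7) over all samples jointly; the per-sample
epimutation load (EML) is the natural log of the SEM count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BetaMatrix, CovariateSpec, MMatrix, SemCatalog
from .ewas import build_design
from .preprocessing import beta_to_m
from .robust import huber_fit_matrix

log = logging.getLogger(__name__)

IQR_MULTIPLIER = 3.0


def detect_sems(
    beta: BetaMatrix, scale: str = "beta", iqr_mult: float = IQR_MULTIPLIER
) -> SemCatalog:
    """Flag per-CpG outliers beyond Q3 + 3*IQR or Q1 - 3*IQR.

    Computed on beta values by default (``scale="m"`` switches to
    M-values). Constant rows have IQR 0, so any deviation from the common
    value is flagged. Requires at least 8 samples for stable quartiles.
    """
    if beta.n_samples < 8:
        raise ValueError("SEM detection needs at least 8 samples")
    if scale == "beta":
        arr = beta.values.to_numpy(dtype=float)
    elif scale == "m":
        arr = beta_to_m(beta).values.to_numpy(dtype=float)
    else:
        raise ValueError("scale must be 'beta' or 'm'")
    q1 = np.quantile(arr, 0.25, axis=1, keepdims=True)
    q3 = np.quantile(arr, 0.75, axis=1, keepdims=True)
    iqr = q3 - q1
    hyper = arr > q3 + iqr_mult * iqr
    hypo = arr < q1 - iqr_mult * iqr
    mask = hyper | hypo
    mask_df = pd.DataFrame(mask, index=beta.cpg_ids, columns=beta.sample_ids)
    counts = pd.Series(mask.sum(axis=0), index=beta.sample_ids, name="sem_count")
    return SemCatalog(
        sem_mask=mask_df,
        per_sample_count=counts,
        eml=epimutation_load(counts),
        per_cpg_recurrence=pd.Series(
            mask.sum(axis=1), index=beta.cpg_ids, name="recurrence"
        ),
        hyper_count=pd.Series(hyper.sum(axis=0), index=beta.sample_ids),
        hypo_count=pd.Series(hypo.sum(axis=0), index=beta.sample_ids),
    )


def epimutation_load(counts: pd.Series | np.ndarray) -> pd.Series:
    """EML = ln(SEM count); a zero count maps to 0 (= ln 1) with a warning."""
    arr = np.asarray(counts, dtype=float)
    zeros = arr == 0
    if zeros.any():
        warnings.warn(
            f"{int(zeros.sum())} sample(s) with zero SEMs; EML set to 0",
            stacklevel=2,
        )
    eml = np.where(zeros, 0.0, np.log(np.where(zeros, 1.0, arr)))
    index = counts.index if isinstance(counts, pd.Series) else None
    return pd.Series(eml, index=index, name="eml")


def recurrent_sem_cpgs(catalog: SemCatalog, min_count: int = 3) -> list[str]:
    """CpGs flagged as a SEM in at least ``min_count`` samples."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    rec = catalog.per_cpg_recurrence
    return list(rec.index[rec >= min_count])


def bicor(x: np.ndarray, y: np.ndarray) -> float:
    """Biweight midcorrelation: a median/MAD-based robust correlation.

    u_i = (x_i - med(x)) / (9 MAD(x)); weights (1 - u^2)^2 on |u| < 1; the
    correlation of the weighted deviations. Falls back to Pearson with a
    warning when either MAD is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("bicor needs two aligned vectors of length >= 3")

    def _weighted_dev(v: np.ndarray) -> Optional[np.ndarray]:
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        if mad == 0:
            return None
        u = (v - med) / (9.0 * mad)
        w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
        return (v - med) * w

    a, b = _weighted_dev(x), _weighted_dev(y)
    if a is None or b is None:
        warnings.warn("zero MAD; falling back to Pearson correlation", stacklevel=2)
        return float(stats.pearsonr(x, y)[0])
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


def bicor_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """bicor with a Student-t approximate two-sided p-value."""
    r = bicor(x, y)
    n = len(np.asarray(x))
    r_ = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_ * np.sqrt((n - 2) / (1.0 - r_**2))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p)


@dataclass
class EmlAssociation:
    """EML-vs-phenotype association under three estimators.

    ``unadjusted_r``/``unadjusted_p`` from ordinary least squares of EML on
    the phenotype alone; ``bicor_r``/``bicor_p`` from the biweight
    midcorrelation; ``adjusted_coef``/``adjusted_p`` from Huber robust
    regression with the full covariate set. ``covariate_screen`` mirrors a
    univariate scan of EML against each covariate.
    """

    unadjusted_r: float
    unadjusted_p: float
    bicor_r: float
    bicor_p: float
    adjusted_coef: float
    adjusted_p: float
    covariate_screen: pd.DataFrame


def eml_association(
    eml: pd.Series,
    sample_sheet: pd.DataFrame,
    spec: CovariateSpec,
    composition=None,
) -> EmlAssociation:
    """Test whether epimutation load differs by phenotype.

    Reports (i) the unadjusted OLS correlation, (ii) the biweight
    midcorrelation, and (iii) the covariate-adjusted Huber regression
    coefficient, plus a univariate screen of EML against every covariate.
    """
    ss = sample_sheet.loc[eml.index]
    y = eml.to_numpy(dtype=float)
    pheno = ss[spec.phenotype].to_numpy(dtype=float)

    r, p_unadj = stats.pearsonr(pheno, y)
    with warnings.catch_warnings():
        # a binary phenotype always has zero MAD; the Pearson fallback is
        # the expected behaviour there, not worth a warning per call
        warnings.simplefilter("ignore", UserWarning)
        br, bp = bicor_test(pheno, y)

    X, names = build_design(ss, spec, composition)
    fit = huber_fit_matrix(X, y)
    j = names.index(spec.phenotype)

    rows = []
    screen_cols = list(spec.continuous) + list(spec.percentile)
    for c in screen_cols:
        v = ss[c].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            rows.append((c, np.nan, np.nan))
            continue
        rr, pp = stats.pearsonr(v, y)
        rows.append((c, rr, pp))
    if spec.cell_fraction_columns and composition is not None:
        for c in spec.cell_fraction_columns:
            v = composition.fractions.loc[eml.index, c].to_numpy(dtype=float)
            rr, pp = stats.pearsonr(v, y)
            rows.append((f"frac_{c}", rr, pp))
    screen = pd.DataFrame(rows, columns=["covariate", "r", "p"]).set_index(
        "covariate"
    )
    return EmlAssociation(
        unadjusted_r=float(r),
        unadjusted_p=float(p_unadj),
        bicor_r=br,
        bicor_p=bp,
        adjusted_coef=float(fit.coef[j, 0]),
        adjusted_p=float(fit.pvalues[j, 0]),
        covariate_screen=screen,
    )
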