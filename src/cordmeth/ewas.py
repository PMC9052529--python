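"""Epigenome-wide association scanning on M-values.

Per CpG, a Huber robust linear regression of the M-value on the phenotype
plus covariates (infant sex, gestational age, birth weight, ancestry,
smoking, hospital, percentile-transformed oxygen days, and the seven
estimated cell-type fractions in the full model). Multiple-testing control
by Bonferroni and Benjamini-Hochberg, group methylation summaries on the
beta (percentage) scale, and hypergeometric CpG-set overlap tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import BetaMatrix, CellComposition, CovariateSpec, MMatrix
from .robust import huber_fit_matrix, huber_rlm  # noqa: F401  (re-export)

log = logging.getLogger(__name__)

#: Minimum samples per categorical level before pooling into "other".
RARE_LEVEL_MIN = 3


def percentile_transform(x: np.ndarray | pd.Series) -> np.ndarray:
    """Empirical percentile transform: x_i -> fraction of values <= x_i.

    Ties share an output value; the maximum maps to 1. Output lies in
    (0, 1]. Used for heavily skewed covariates such as cumulative NICU
    oxygen days.
    """
    arr = np.asarray(x, dtype=float)
    finite = np.isfinite(arr)
    if not finite.any():
        raise ValueError("percentile_transform needs at least one finite value")
    vals = np.sort(arr[finite])
    out = np.full(arr.shape, np.nan)
    out[finite] = np.searchsorted(vals, arr[finite], side="right") / len(vals)
    return out


def build_design(
    sample_sheet: pd.DataFrame,
    spec: CovariateSpec,
    composition: Optional[CellComposition] = None,
) -> tuple[np.ndarray, list[str]]:
    """Assemble the regression design matrix (intercept, phenotype, covariates).

    Categorical covariates are one-hot encoded against a reference first
    level; levels carried by fewer than 3 samples are pooled into "other"
    to avoid separation. Covariates named in ``spec.percentile`` get the
    empirical percentile transform. Cell-fraction columns come from
    ``composition`` when given, else from same-named sample-sheet columns.
    """
    ss = sample_sheet
    cols: list[np.ndarray] = [np.ones(len(ss))]
    names = ["(Intercept)"]

    pheno = ss[spec.phenotype].to_numpy(dtype=float)
    if np.ptp(pheno[np.isfinite(pheno)]) == 0:
        raise ValueError(f"phenotype {spec.phenotype!r} is constant")
    cols.append(pheno)
    names.append(spec.phenotype)

    for c in spec.continuous:
        if c not in ss.columns:
            raise ValueError(f"covariate {c!r} missing from sample sheet")
        cols.append(ss[c].to_numpy(dtype=float))
        names.append(c)
    for c in spec.percentile:
        if c not in ss.columns:
            raise ValueError(f"covariate {c!r} missing from sample sheet")
        cols.append(percentile_transform(ss[c]))
        names.append(f"{c}_pctl")
    for c in spec.categorical:
        if c not in ss.columns:
            raise ValueError(f"covariate {c!r} missing from sample sheet")
        lab = ss[c].astype(str)
        counts = lab.value_counts()
        rare = counts.index[counts < RARE_LEVEL_MIN]
        if len(rare):
            lab = lab.where(~lab.isin(rare), "other")
        levels = sorted(lab.unique())
        for lv in levels[1:]:  # first level is the reference
            cols.append((lab == lv).to_numpy(dtype=float))
            names.append(f"{c}[{lv}]")
    if spec.cell_fraction_columns:
        if composition is not None:
            frac = composition.fractions.loc[ss.index]
        else:
            frac = ss
        for c in spec.cell_fraction_columns:
            cols.append(frac[c].to_numpy(dtype=float))
            names.append(f"frac_{c}")
    X = np.column_stack(cols)
    return X, names


def adjust_pvalues(p: np.ndarray, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment: 'bonferroni' or 'bh' (step-up FDR)."""
    p = np.asarray(p, dtype=float)
    if method == "bonferroni":
        return np.minimum(1.0, p * p.size)
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown method {method!r}")


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Genome-wide significance cutoff alpha / m."""
    if n_tests < 1:
        raise ValueError("n_tests must be positive")
    return alpha / n_tests


def group_mean_diff(
    beta: BetaMatrix | pd.DataFrame, groups: np.ndarray | pd.Series
) -> pd.DataFrame:
    """Per-CpG group methylation means (%) and their difference.

    ``groups`` is a binary indicator aligned to samples; output columns
    ``meth_group1_pct``/``meth_group0_pct`` are arithmetic beta means x100
    and ``dmeth_pct`` = group1 - group0, rounded to 2 decimals for
    reporting.
    """
    values = beta.values if isinstance(beta, BetaMatrix) else beta
    g = np.asarray(groups).astype(int)
    if (g == 1).sum() == 0 or (g == 0).sum() == 0:
        raise ValueError("both groups must be non-empty")
    arr = values.to_numpy(dtype=float)
    m1 = np.round(arr[:, g == 1].mean(axis=1) * 100.0, 2)
    m0 = np.round(arr[:, g == 0].mean(axis=1) * 100.0, 2)
    # dmeth is the difference of the *reported* means, so the printed
    # columns are exactly self-consistent
    out = pd.DataFrame(
        {
            "meth_group1_pct": m1,
            "meth_group0_pct": m0,
            "dmeth_pct": np.round(m1 - m0, 2),
        },
        index=values.index,
    )
    return out


def run_ewas(
    m: MMatrix,
    sample_sheet: pd.DataFrame,
    spec: CovariateSpec,
    beta: Optional[BetaMatrix] = None,
    annotation: Optional[pd.DataFrame] = None,
    composition: Optional[CellComposition] = None,
) -> pd.DataFrame:
    """Per-CpG robust regression of M-values on phenotype + covariates.

    Returns a per-CpG table with the phenotype coefficient (M-scale),
    robust SE, p, Bonferroni-adjusted p, BH q, group methylation means (%)
    when ``beta`` is supplied and the phenotype is binary, and annotation
    columns (chrom, pos, gene) when ``annotation`` is supplied.
    """
    ss = sample_sheet.loc[m.values.columns]
    X, names = build_design(ss, spec, composition)
    n = X.shape[0]
    if n < X.shape[1] + 5:
        raise ValueError("too few samples for the requested design")
    Y = m.values.to_numpy(dtype=float).T  # samples x cpgs
    fit = huber_fit_matrix(X, Y)
    if not fit.converged.all():
        log.warning(
            "EWAS: %d/%d CpG fits did not converge; last iterate reported",
            int((~fit.converged).sum()), len(fit.converged),
        )
    j = names.index(spec.phenotype)
    p = fit.pvalues[j]
    result = pd.DataFrame(
        {
            "coef": fit.coef[j],
            "se": fit.se[j],
            "p": p,
            "bonf_p": adjust_pvalues(p, "bonferroni"),
            "fdr_q": adjust_pvalues(p, "bh"),
            "converged": fit.converged,
        },
        index=m.values.index,
    )
    if beta is not None:
        pheno = ss[spec.phenotype].to_numpy(dtype=float)
        uniq = np.unique(pheno[np.isfinite(pheno)])
        if set(uniq) <= {0.0, 1.0}:
            gm = group_mean_diff(
                BetaMatrix(values=beta.values.loc[result.index, m.values.columns]),
                pheno,
            )
            result = result.join(gm)
    if annotation is not None:
        ann = annotation
        if "cpg_id" in ann.columns:
            ann = ann.set_index("cpg_id")
        keep = [c for c in ("chrom", "pos", "gene") if c in ann.columns]
        result = result.join(ann[keep], how="left")
    return result


def genomic_inflation(p: np.ndarray) -> float:
    """Genomic inflation factor: median chi-square ratio of the p-values."""
    p = np.asarray(p, dtype=float)
    p = p[np.isfinite(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


@dataclass
class OverlapResult:
    n_overlap: int
    fraction_of_a_pct: float
    p_value: float
    n_a: int
    n_b: int
    n_universe: int


def overlap_test(
    set_a: Sequence[str], set_b: Sequence[str], universe: Sequence[str]
) -> OverlapResult:
    """Hypergeometric enrichment of the overlap between two CpG sets.

    Reports the overlap count, the overlap as a percentage of ``set_b``
    (the reference set), and the one-sided upper-tail hypergeometric p for
    drawing |A| CpGs from the universe and hitting >= n_overlap of B.
    """
    A, Bs, U = set(set_a), set(set_b), set(universe)
    if not A <= U or not Bs <= U:
        raise ValueError("both sets must be subsets of the universe")
    k = len(A & Bs)
    N, K, n = len(U), len(Bs), len(A)
    p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
    frac = 100.0 * k / K if K else 0.0
    return OverlapResult(
        n_overlap=k, fraction_of_a_pct=frac, p_value=p, n_a=n, n_b=K, n_universe=N
    )


def prevalence_by_group(
    sample_sheet: pd.DataFrame,
    outcome: str = "bpd_status",
    group: Optional[str] = "sex",
) -> dict[str, float]:
    """Outcome prevalence (%) overall and within levels of a grouping column."""
    out: dict[str, float] = {
        "overall": 100.0 * sample_sheet[outcome].astype(int).mean()
    }
    if group is not None:
        for lv, sub in sample_sheet.groupby(group):
            out[str(lv)] = 100.0 * sub[outcome].astype(int).mean()
    return out
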