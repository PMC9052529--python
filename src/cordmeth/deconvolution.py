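"""Reference-based cell-type deconvolution of cord-blood methylation.

Cell fractions are estimated per sample by constrained projection: the
sample's beta values at the discriminating CpGs are regressed onto the
reference cell-type profiles under non-negativity, with no sum-to-one
constraint (the standard constrained-projection formulation). Cord blood
additionally carries nucleated red blood cells (NRBCs), whose genome-wide
hypomethylation shifts the bulk beta distribution; helpers here
characterise NRBC-associated CpGs and that density shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from .containers import BetaMatrix, CellComposition, MMatrix, ReferenceProfile
from .robust import huber_fit_matrix


def select_discriminating_cpgs(
    reference_samples: pd.DataFrame,
    sample_cell_types: pd.Series,
    per_type: int = 100,
) -> ReferenceProfile:
    """Pick the CpGs that separate each cell type from the rest.

    For every cell type a two-sample t statistic (that type's reference
    samples vs all others, pooled variance) ranks the CpGs; the top
    ``per_type/2`` hypermethylated and ``per_type/2`` hypomethylated CpGs
    are selected. The union over types defines the projection basis.

    Parameters
    ----------
    reference_samples : CpG-by-reference-sample beta DataFrame.
    sample_cell_types : cell-type label per reference sample (aligned to
        the columns).
    """
    labels = pd.Series(np.asarray(sample_cell_types), index=reference_samples.columns)
    types = list(pd.unique(labels))
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError("need at least 2 reference samples per cell type")
    X = reference_samples.to_numpy(dtype=float)
    disc: dict[str, list[str]] = {}
    means = {}
    for t in types:
        in_t = (labels == t).to_numpy()
        a, b = X[:, in_t], X[:, ~in_t]
        tstat, _ = stats.ttest_ind(a, b, axis=1, equal_var=True)
        tstat = np.where(np.isfinite(tstat), tstat, 0.0)
        order = np.argsort(tstat)
        half = per_type // 2
        hypo = order[:half]
        hyper = order[::-1][:half]
        chosen = pd.Index(reference_samples.index[np.concatenate([hyper, hypo])])
        disc[t] = list(chosen)
        means[t] = a.mean(axis=1)
    mean_df = pd.DataFrame(means, index=reference_samples.index)[types]
    return ReferenceProfile(means=mean_df.clip(0.0, 1.0), discriminating_cpgs=disc)


def estimate_composition(
    beta: BetaMatrix, reference: ReferenceProfile, renormalize: bool = False
) -> CellComposition:
    """Non-negative projection of each sample onto the reference profiles.

    Solves min_w ||y - R w||^2 subject to w >= 0 per sample over the
    discriminating-CpG basis; ``renormalize`` rescales each row to sum to 1
    for display (estimates are reported as-is by default, so row sums can
    mildly exceed 1).
    """
    basis = reference.basis_cpgs()
    if not basis:
        basis = list(reference.means.index)
    missing = [c for c in basis if c not in beta.values.index]
    if missing:
        raise ValueError(
            f"{len(missing)} discriminating CpGs absent from beta matrix "
            f"(first: {missing[0]})"
        )
    R = reference.means.loc[basis].to_numpy(dtype=float)
    if np.linalg.matrix_rank(R) < R.shape[1]:
        raise ValueError("reference profile matrix is rank-deficient")
    Y = beta.values.loc[basis].to_numpy(dtype=float)
    n_types = R.shape[1]
    W = np.empty((beta.n_samples, n_types))
    res = np.empty(beta.n_samples)
    for j in range(beta.n_samples):
        W[j], res[j] = nnls(R, Y[:, j])
    if renormalize:
        sums = W.sum(axis=1, keepdims=True)
        W = np.divide(W, sums, out=np.zeros_like(W), where=sums > 0)
    fractions = pd.DataFrame(W, index=beta.sample_ids, columns=reference.cell_types)
    return CellComposition(
        fractions=fractions,
        residual_norm=pd.Series(res, index=beta.sample_ids, name="residual_norm"),
    )


def nrbc_ewas(
    m: MMatrix,
    composition: CellComposition,
    sample_sheet: pd.DataFrame,
    exclude_bpd: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Scan for CpGs associated with the estimated NRBC fraction.

    Per CpG, robust (Huber) regression of the M-value on the estimated
    NRBC fraction, by default over non-BPD samples only so that disease
    effects cannot masquerade as NRBC effects. Returns a per-CpG table with
    a ``significant`` column marking Bonferroni significance at ``alpha``
    over the probes analysed.
    """
    samples = m.values.columns
    nrbc = composition.fractions.loc[samples, "NRBC"].to_numpy(dtype=float)
    keep = np.ones(len(samples), dtype=bool)
    if exclude_bpd:
        keep = sample_sheet.loc[samples, "bpd_status"].to_numpy(int) == 0
    if keep.sum() < 10:
        raise ValueError("need at least 10 samples for the NRBC scan")
    nrbc = nrbc[keep]
    Y = m.values.to_numpy(dtype=float)[:, keep]
    n_cpgs = Y.shape[0]
    if np.ptp(nrbc) == 0:
        # constant predictor: no testable variation
        return pd.DataFrame(
            {
                "coef": np.nan,
                "se": np.nan,
                "p": np.nan,
                "bonf_p": np.nan,
                "significant": False,
            },
            index=m.values.index,
        )
    X = np.column_stack([np.ones(keep.sum()), nrbc])
    fit = huber_fit_matrix(X, Y.T)
    p = fit.pvalues[1]
    bonf = np.minimum(1.0, p * n_cpgs)
    return pd.DataFrame(
        {
            "coef": fit.coef[1],
            "se": fit.se[1],
            "p": p,
            "bonf_p": bonf,
            "significant": bonf < alpha,
        },
        index=m.values.index,
    )


@dataclass
class DensitySummary:
    """Pooled beta-density comparison between high- and low-NRBC samples."""

    grid: np.ndarray
    density_high: np.ndarray
    density_low: np.ndarray
    frac_methylated_high: float  # fraction of pooled betas > threshold
    frac_methylated_low: float
    high_samples: list[str]
    low_samples: list[str]
    threshold: float = 0.7


def density_comparison(
    beta: BetaMatrix,
    composition: CellComposition,
    k: int = 10,
    threshold: float = 0.7,
    gridsize: int = 256,
) -> DensitySummary:
    """Contrast pooled beta distributions of extreme-NRBC sample groups.

    Takes the ``k`` highest- and ``k`` lowest-NRBC samples, pools their
    beta values, and returns Gaussian kernel density estimates on a common
    grid plus each group's fraction of values above ``threshold`` (the
    "fully methylated" mass whose loss marks NRBC hypomethylation).
    """
    if k > beta.n_samples // 2:
        raise ValueError("k must be at most half the number of samples")
    nrbc = composition.fractions.loc[beta.sample_ids, "NRBC"]
    order = nrbc.sort_values()
    low = list(order.index[:k])
    high = list(order.index[-k:])
    pooled_high = beta.values[high].to_numpy(dtype=float).ravel()
    pooled_low = beta.values[low].to_numpy(dtype=float).ravel()
    grid = np.linspace(0.0, 1.0, gridsize)
    dens_high = stats.gaussian_kde(pooled_high)(grid)
    dens_low = stats.gaussian_kde(pooled_low)(grid)
    return DensitySummary(
        grid=grid,
        density_high=dens_high,
        density_low=dens_low,
        frac_methylated_high=float((pooled_high > threshold).mean()),
        frac_methylated_low=float((pooled_low > threshold).mean()),
        high_samples=high,
        low_samples=low,
        threshold=threshold,
    )
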