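"""In-memory containers shared across the pipeline.

All matrices are pandas DataFrames with CpG identifiers on the rows and
sample identifiers on the columns (methylation matrices), or samples on the
rows (per-sample tables such as cell compositions). Beta values are
methylated proportions in [0, 1]; M-values are log2(beta / (1 - beta)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: The seven cord-blood cell types resolved by the reference profiles, in
#: canonical column order. NRBC = nucleated red blood cell.
CELL_TYPES = ("CD8T", "CD4T", "B", "NK", "Mono", "Gran", "NRBC")


@dataclass
class BetaMatrix:
    """CpG-by-sample matrix of methylation proportions.

    Parameters
    ----------
    values
        DataFrame of beta values in [0, 1], index = CpG ids, columns =
        sample ids.
    failure_mask
        Optional boolean DataFrame of the same shape; ``True`` marks a
        failed measurement.
    """

    values: pd.DataFrame
    failure_mask: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise ValueError("duplicate CpG ids in beta matrix")
        if v.columns.has_duplicates:
            raise ValueError("duplicate sample ids in beta matrix")
        arr = v.to_numpy(dtype=float, copy=False)
        if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 1):
            bad = np.argwhere((arr < 0) | (arr > 1))
            i, j = bad[0]
            raise ValueError(
                f"beta value out of [0,1] at CpG {v.index[i]!r}, "
                f"sample {v.columns[j]!r}: {arr[i, j]}"
            )
        if self.failure_mask is not None:
            if self.failure_mask.shape != v.shape:
                raise ValueError("failure mask shape does not match values")

    @property
    def cpg_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_cpgs(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class MMatrix:
    """CpG-by-sample matrix of M-values (log2 ratio of beta values)."""

    values: pd.DataFrame
    epsilon: float = 1e-3

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float, copy=False)
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValueError("M-value matrix contains non-finite entries")

    @property
    def cpg_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class ReferenceProfile:
    """Cell-type mean methylation profiles.

    ``means`` is CpG-by-cell-type; ``discriminating_cpgs`` maps each cell
    type to the CpGs that distinguish it from the other types and jointly
    define the deconvolution basis.
    """

    means: pd.DataFrame
    discriminating_cpgs: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.means.to_numpy(dtype=float, copy=False)
        if arr.size and (arr.min() < 0 or arr.max() > 1):
            raise ValueError("reference means must lie in [0, 1]")

    @property
    def cell_types(self) -> list[str]:
        return list(self.means.columns)

    def basis_cpgs(self) -> list[str]:
        """Union of the per-type discriminating CpGs, in matrix row order."""
        members = set()
        for cpgs in self.discriminating_cpgs.values():
            members.update(cpgs)
        return [c for c in self.means.index if c in members]


@dataclass
class CellComposition:
    """Estimated cell fractions per sample (rows) by cell type (columns)."""

    fractions: pd.DataFrame
    residual_norm: pd.Series

    def __post_init__(self) -> None:
        if (self.fractions.to_numpy() < -1e-12).any():
            raise ValueError("cell fractions must be non-negative")


@dataclass
class SemCatalog:
    """Stochastic epimutation calls.

    sem_mask is CpG-by-sample boolean; per_sample_count its column sums;
    eml the natural log of the per-sample count (ln 1 = 0 for zero counts);
    per_cpg_recurrence the row sums.
    """

    sem_mask: pd.DataFrame
    per_sample_count: pd.Series
    eml: pd.Series
    per_cpg_recurrence: pd.Series
    hyper_count: Optional[pd.Series] = None
    hypo_count: Optional[pd.Series] = None


@dataclass
class ClockModel:
    """Linear methylation clock: GA estimate = intercept + sum(coef * beta)."""

    intercept: float
    coefficients: pd.Series  # index = CpG id, values = weeks per beta unit
    name: str = "clock"

    def __post_init__(self) -> None:
        if self.coefficients.index.has_duplicates:
            raise ValueError("clock coefficient CpG ids must be unique")


@dataclass
class CovariateSpec:
    """Covariate roles for regression models.

    ``phenotype`` is the column tested; ``continuous`` and ``categorical``
    are adjustment columns from the sample sheet; columns listed in
    ``percentile`` are passed through the empirical percentile transform
    (used for cumulative NICU oxygen days); ``cell_fraction_columns`` names
    columns of an aligned cell-composition table appended to the design.
    """

    phenotype: str
    continuous: Sequence[str] = ()
    categorical: Sequence[str] = ()
    percentile: Sequence[str] = ()
    cell_fraction_columns: Sequence[str] = ()

    def __post_init__(self) -> None:
        covars = set(self.continuous) | set(self.categorical) | set(self.percentile)
        if self.phenotype in covars:
            raise ValueError("phenotype must not also be a covariate")
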