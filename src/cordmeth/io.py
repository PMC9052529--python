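"""Readers and writers for the pipeline's interchange formats.

Matrices travel as TSV (rows = CpG id, columns = sample id), per-sample
tables as CSV, ground truth as JSON, clocks as a two-column CSV whose
first row is ``(Intercept)``. Every file written here starts with a
``#``-prefixed header comment recording the package version, the seed,
and the stage parameters; readers skip such lines.
"""

from __future__ import annotations

import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .containers import BetaMatrix, CellComposition, ClockModel, ReferenceProfile

try:
    __version__ = version("cordmeth")
except PackageNotFoundError:  # pragma: no cover - editable edge case
    __version__ = "0.0.0"


def _header(stage: str, seed: Optional[int] = None, **params) -> str:
    bits = [f"cordmeth v{__version__}", f"stage={stage}"]
    if seed is not None:
        bits.append(f"seed={seed}")
    bits.extend(f"{k}={v}" for k, v in params.items())
    return "# " + " ".join(bits) + "\n"


def _write_frame(df: pd.DataFrame, path, sep: str, header: str,
                 index_label: str, float_format: str = "%.6f") -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        df.to_csv(fh, sep=sep, index_label=index_label,
                  float_format=float_format)


def write_beta(beta: BetaMatrix, path, seed: Optional[int] = None,
               **params) -> None:
    _write_frame(beta.values, path, "\t", _header("beta", seed, **params),
                 "cpg_id")


def read_beta(path) -> BetaMatrix:
    """Read a beta TSV; values outside [0,1] raise naming the cell."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty beta matrix file: {path}") from None
    if df.empty and df.columns.empty:
        raise ValueError(f"empty beta matrix file: {path}")
    arr = df.to_numpy(dtype=float)
    bad = np.argwhere((arr < 0) | (arr > 1))
    if len(bad):
        i, j = bad[0]
        raise ValueError(
            f"beta value out of [0,1] in {path.name} at CpG {df.index[i]!r}, "
            f"sample {df.columns[j]!r}: {arr[i, j]}"
        )
    return BetaMatrix(values=df)


def write_sample_sheet(sheet: pd.DataFrame, path, seed: Optional[int] = None,
                       **params) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header("sample_sheet", seed, **params))
        sheet.to_csv(fh, index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if "sample_id" not in df.columns:
        raise ValueError("sample sheet must carry a 'sample_id' column")
    return df.set_index("sample_id", drop=False)


def write_annotation(annotation: pd.DataFrame, path,
                     seed: Optional[int] = None, **params) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header("annotation", seed, **params))
        annotation.to_csv(fh, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"cpg_id", "chrom", "pos", "snp_flag", "crossreactive_flag"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    return df


def write_reference(reference: ReferenceProfile, path,
                    seed: Optional[int] = None, **params) -> None:
    _write_frame(reference.means, path, "\t",
                 _header("reference", seed, **params), "cpg_id")


def read_reference(path) -> ReferenceProfile:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return ReferenceProfile(means=df)


def write_composition(composition: CellComposition, path,
                      seed: Optional[int] = None, **params) -> None:
    df = composition.fractions.copy()
    df["residual_norm"] = composition.residual_norm
    _write_frame(df, path, ",", _header("composition", seed, **params),
                 "sample_id")


def read_composition(path) -> CellComposition:
    df = pd.read_csv(path, comment="#", index_col=0)
    res = df.pop("residual_norm")
    return CellComposition(fractions=df, residual_norm=res)


def write_clock(clock: ClockModel, path, seed: Optional[int] = None,
                **params) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header("clock", seed, name=clock.name, **params))
        fh.write(f"(Intercept),{clock.intercept!r}\n")
        for cpg, coef in clock.coefficients.items():
            fh.write(f"{cpg},{coef!r}\n")


def read_clock(path, name: Optional[str] = None) -> ClockModel:
    path = Path(path)
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, val = line.split(",", 1)
            rows.append((key, float(val)))
    if not rows or rows[0][0] != "(Intercept)":
        raise ValueError("clock CSV must start with an '(Intercept)' row")
    intercept = rows[0][1]
    coefs = pd.Series(dict(rows[1:]), name="coefficient", dtype=float)
    return ClockModel(intercept=intercept, coefficients=coefs,
                      name=name or path.stem)


def write_truth(truth, path, seed: Optional[int] = None) -> None:
    payload = {
        "_header": _header("truth", seed).strip("# \n"),
        "true_cell_fractions": {
            s: truth.true_cell_fractions.loc[s].to_dict()
            for s in truth.true_cell_fractions.index
        },
        "effect_cpg_ids": list(truth.effect_cpg_ids),
        "effect_signs": truth.effect_signs,
        "ga_cpg_ids": list(truth.ga_cpg_ids),
        "injected_sem_positions": [list(p) for p in truth.injected_sem_positions],
        "true_ga": truth.true_ga.to_dict(),
        "true_bw": truth.true_bw.to_dict(),
        "smoking_cpg_id": truth.smoking_cpg_id,
        "nrbc_hypo_cpg_ids": list(truth.nrbc_hypo_cpg_ids),
        "n_clipped": truth.n_clipped,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())
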