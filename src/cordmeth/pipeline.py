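"""End-to-end orchestration: simulate -> preprocess -> deconvolve ->
EWAS -> epimutations -> epigenetic age, with per-stage outputs and a JSON
summary."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .containers import CovariateSpec
from .deconvolution import estimate_composition, nrbc_ewas
from .ega import acceleration_association, ega_acceleration, predict_ega
from .ewas import overlap_test, run_ewas
from .preprocessing import (
    beta_to_m,
    combat_adjust,
    filter_probes,
    filter_samples,
    winsorize,
)
from .sem import detect_sems, eml_association, recurrent_sem_cpgs
from .synthetic import (
    CohortConfig,
    generate_annotation,
    generate_clock,
    generate_cohort,
    generate_reference_profiles,
)

log = logging.getLogger(__name__)

#: Full covariate adjustment used for the disease scan: sex, GA, birth
#: weight, smoking, ancestry, hospital, percentile-transformed oxygen
#: days, and the seven estimated cell-type fractions.
DEFAULT_SPEC = CovariateSpec(
    phenotype="bpd_status",
    continuous=("ga_weeks", "birth_weight_g", "smoking"),
    categorical=("sex", "ancestry", "hospital"),
    percentile=("o2_days",),
    cell_fraction_columns=("CD8T", "CD4T", "B", "NK", "Mono", "Gran", "NRBC"),
)


@dataclass
class RunConfig:
    """Parameters of a full pipeline run; unknown YAML keys are rejected."""

    out_dir: str = "cordmeth_out"
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    max_failed_fraction: float = 0.05
    m_epsilon: float = 1e-3
    winsorize_quantiles: Optional[tuple[float, float]] = None
    combat: bool = True
    run_ewas: bool = True
    run_sem: bool = True
    run_ega: bool = True
    run_ga_ewas: bool = False
    n_clock_cpgs: int = 100
    fdr_levels: tuple[float, float] = (0.01, 0.05)
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "cohort" in data and isinstance(data["cohort"], dict):
            ck = {f.name for f in dataclasses.fields(CohortConfig)}
            bad = set(data["cohort"]) - ck
            if bad:
                raise ValueError(f"unknown cohort config keys: {sorted(bad)}")
            data["cohort"] = CohortConfig(**data["cohort"])
        for key in ("winsorize_quantiles", "fdr_levels"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def run_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages, writing outputs under config.out_dir.

    Returns the summary dictionary (also written as ``summary.json``):
    significant-CpG counts at Bonferroni and the configured FDR levels,
    epimutation-load association statistics, epigenetic-age association
    statistics, and CpG-set overlap tables.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    cohort_cfg = dataclasses.replace(config.cohort, seed=seed)

    reference = generate_reference_profiles(
        cohort_cfg.n_cpgs, cohort_cfg.cell_types, seed=seed
    )
    beta, sheet, truth = generate_cohort(cohort_cfg, reference)
    protected = {c for v in reference.discriminating_cpgs.values() for c in v}
    protected |= set(truth.effect_cpg_ids)
    protected |= set(truth.ga_cpg_ids)
    if truth.smoking_cpg_id:
        protected.add(truth.smoking_cpg_id)
    annotation = generate_annotation(
        list(beta.cpg_ids), seed=seed + 1, protected_ids=protected
    )
    cio.write_beta(beta, out / "beta.tsv", seed=seed)
    cio.write_sample_sheet(sheet, out / "samples.csv", seed=seed)
    cio.write_annotation(annotation, out / "annotation.tsv", seed=seed)
    cio.write_reference(reference, out / "reference.tsv", seed=seed)
    cio.write_truth(truth, out / "truth.json", seed=seed)

    beta_f = filter_samples(beta, config.max_failed_fraction)
    beta_f, removal_counts = filter_probes(beta_f, annotation)
    m = beta_to_m(beta_f, epsilon=config.m_epsilon)
    if config.winsorize_quantiles is not None:
        lo, hi = config.winsorize_quantiles
        m = dataclasses.replace(m, values=winsorize(m.values, lo, hi))
    sheet_f = sheet.loc[m.values.columns]
    if config.combat and cohort_cfg.n_batches > 1:
        protected_design = np.column_stack([
            sheet_f["bpd_status"].to_numpy(float),
            sheet_f["ga_weeks"].to_numpy(float),
        ])
        m = combat_adjust(m, sheet_f["batch"], protected_design)

    composition = estimate_composition(beta_f, reference)
    cio.write_composition(composition, out / "composition.csv", seed=seed)

    summary: dict = {
        "seed": seed,
        "n_samples": int(beta_f.n_samples),
        "n_cpgs_analyzed": int(beta_f.n_cpgs),
        "probe_removal_counts": removal_counts,
    }
    universe = list(m.values.index)

    nrbc_table = None
    if config.run_ewas:
        spec = DEFAULT_SPEC
        result = run_ewas(
            m, sheet_f, spec, beta=beta_f, annotation=annotation,
            composition=composition,
        )
        result.to_csv(out / "ewas.tsv", sep="\t", index_label="cpg_id")
        f1, f2 = config.fdr_levels
        nrbc_table = nrbc_ewas(m, composition, sheet_f, exclude_bpd=True)
        summary["ewas"] = {
            "n_bonferroni": int((result["bonf_p"] < 0.05).sum()),
            f"n_fdr_{f1}": int((result["fdr_q"] < f1).sum()),
            f"n_fdr_{f2}": int((result["fdr_q"] < f2).sum()),
            "n_nrbc_associated": int(nrbc_table["significant"].sum()),
        }
        bpd_sets = {
            "bonferroni": set(result.index[result["bonf_p"] < 0.05]),
            f"fdr_{f1}": set(result.index[result["fdr_q"] < f1]),
        }
        if config.run_ga_ewas:
            ga_spec = CovariateSpec(
                phenotype="ga_weeks",
                continuous=("birth_weight_g", "smoking"),
                categorical=("sex", "ancestry", "hospital"),
                percentile=("o2_days",),
                cell_fraction_columns=spec.cell_fraction_columns,
            )
            nonbpd = sheet_f.index[sheet_f["bpd_status"] == 0]
            m_nb = dataclasses.replace(m, values=m.values[list(nonbpd)])
            ga_result = run_ewas(m_nb, sheet_f.loc[nonbpd], ga_spec,
                                 composition=composition)
            ga_result.to_csv(out / "ewas_ga.tsv", sep="\t", index_label="cpg_id")
            ga_set = set(ga_result.index[ga_result["bonf_p"] < 0.05])
            ov = overlap_test(sorted(bpd_sets[f"fdr_{f1}"]), sorted(ga_set),
                              universe) if ga_set else None
            summary["ewas"]["n_ga_bonferroni"] = len(ga_set)
            if ov is not None:
                summary["overlap_bpd_ga"] = {
                    "n_overlap": ov.n_overlap,
                    "pct_of_reference": round(ov.fraction_of_a_pct, 2),
                    "p": ov.p_value,
                }

    if config.run_sem:
        catalog = detect_sems(beta_f)
        per_sample = pd.DataFrame({
            "sem_count": catalog.per_sample_count,
            "eml": catalog.eml,
            "hyper_count": catalog.hyper_count,
            "hypo_count": catalog.hypo_count,
        })
        per_sample.to_csv(out / "sem_samples.csv", index_label="sample_id")
        catalog.per_cpg_recurrence.to_csv(
            out / "sem_recurrence.csv", index_label="cpg_id"
        )
        assoc = eml_association(catalog.eml, sheet_f, DEFAULT_SPEC, composition)
        summary["sem"] = {
            "count_min": int(catalog.per_sample_count.min()),
            "count_max": int(catalog.per_sample_count.max()),
            "eml_unadjusted_r": round(assoc.unadjusted_r, 6),
            "eml_unadjusted_p": assoc.unadjusted_p,
            "eml_bicor_r": round(assoc.bicor_r, 6),
            "eml_bicor_p": assoc.bicor_p,
            "eml_adjusted_coef": round(assoc.adjusted_coef, 6),
            "eml_adjusted_p": assoc.adjusted_p,
        }
        recurrent = recurrent_sem_cpgs(catalog, min_count=3)
        summary["sem"]["n_recurrent_cpgs"] = len(recurrent)
        if nrbc_table is not None:
            nrbc_set = sorted(nrbc_table.index[nrbc_table["significant"]])
            if nrbc_set and recurrent:
                ov = overlap_test(recurrent, nrbc_set, universe)
                summary["overlap_sem_nrbc"] = {
                    "n_overlap": ov.n_overlap,
                    "pct_of_reference": round(ov.fraction_of_a_pct, 2),
                    "p": ov.p_value,
                }

    if config.run_ega:
        clock = generate_clock(
            beta_f, sheet_f["ga_weeks"], n_clock_cpgs=config.n_clock_cpgs,
            seed=seed,
        )
        cio.write_clock(clock, out / "clock.csv", seed=seed)
        ega = predict_ega(beta_f, clock)
        accel = ega_acceleration(ega, sheet_f["ga_weeks"])
        pd.DataFrame({"ega_weeks": ega, "acceleration_weeks": accel}).to_csv(
            out / "ega.csv", index_label="sample_id"
        )
        assoc = acceleration_association(accel, sheet_f, DEFAULT_SPEC,
                                         composition)
        summary["ega"] = {
            "corr_ega_ga": round(
                float(np.corrcoef(ega, sheet_f["ga_weeks"])[0, 1]), 6
            ),
            "accel_unadjusted_coef": round(assoc.unadjusted_coef, 6),
            "accel_unadjusted_p": assoc.unadjusted_p,
            "accel_adjusted_coef": round(assoc.adjusted_coef, 6),
            "accel_adjusted_p": assoc.adjusted_p,
        }

    (out / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True)
    )
    return summary
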