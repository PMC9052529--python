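"""Synthetic preterm cord-blood cohorts with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume for a very-low-birth-weight preterm cohort (roughly: 107 infants,
14 of whom develop bronchopulmonary dysplasia):

* gestational age uniform on 24-35 weeks; birth weight linear in GA with
  noise scaled to a target population r^2 (0.38 by default);
* a nucleated-red-blood-cell (NRBC) fraction that is a logistic transform
  of a latent Gaussian decreasing in birth weight, moment-calibrated to a
  target mean/SD (29.9% / 24.1%) and BW correlation (r^2 = 0.16); the six
  leukocyte fractions split the remaining mass via a Dirichlet draw;
* beta values formed as reference-profile mixtures, with genome-wide NRBC
  hypomethylation inherited from the reference, a maternal-smoking
  biomarker CpG, injected disease-associated methylation differences,
  injected stochastic epimutations, plate batch effects on the M scale,
  and beta-distributed measurement noise.

Every stochastic choice flows from a single seed; identical configurations
yield bit-identical cohorts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, root
from scipy.special import expit, logit
from sklearn.linear_model import LinearRegression, Ridge

from .containers import CELL_TYPES, BetaMatrix, ClockModel, ReferenceProfile

log = logging.getLogger(__name__)

#: Relative Dirichlet weights for the six leukocyte fractions (typical
#: cord-blood proportions, granulocyte-dominated) and the concentration.
LEUKOCYTE_PROPS = {"CD8T": 0.06, "CD4T": 0.17, "B": 0.05, "NK": 0.03,
                   "Mono": 0.08, "Gran": 0.61}
DIRICHLET_CONCENTRATION = 40.0

ANCESTRY_LEVELS = ("EuropeanLatin", "Criollos", "EuropeanOther", "Jewish", "Other")
ANCESTRY_PROBS = (0.74, 0.13, 0.05, 0.04, 0.04)
HOSPITALS = ("H1", "H2", "H3", "H4")

BW_SLOPE_G_PER_WEEK = 60.0   # birth-weight gain per gestational week
BW_MEAN_G = 1150.0           # cohort mean (VLBW cohort) at the GA midpoint
BW_FLOOR_G = 350.0
MALE_FRACTION = 40 / 107
SMOKING_BASE_RATE = 0.30


@dataclass
class CohortConfig:
    """All tunable knobs of the cohort generator (defaults = study design)."""

    n_samples: int = 107
    n_cpgs: int = 20_000
    n_bpd: int = 14
    cell_types: Sequence[str] = CELL_TYPES
    ga_range: tuple[float, float] = (24.0, 35.0)
    bw_ga_r2: float = 0.38
    nrbc_mean: float = 0.299
    nrbc_sd: float = 0.241
    nrbc_bw_r2: float = 0.16
    n_effect_cpgs: int = 50
    effect_dmeth: float = 5.0          # percentage points, BPD minus non-BPD
    effect_hypo_fraction: float = 0.64  # share of effect CpGs lower in BPD
    smoking_effect_dmeth: float = 12.0  # biomarker-CpG drop per smoking unit
    n_ga_cpgs: int = 500               # CpGs tracking gestational age directly
    ga_effect_per_week: float = 0.01   # beta change per gestational week
    sem_rate: float = 200.0            # expected injected epimutations/sample
    sem_magnitude: float = 0.4         # beta offset of an injected epimutation
    sem_bpd_rate_ratio: float = 1.0    # multiplies sem_rate in BPD samples
    n_batches: int = 2
    batch_sd: float = 0.1              # M-scale location SD (scale SD = half)
    noise_precision: float = 1000.0    # beta-noise precision; inf = noiseless
    noise_model: str = "beta"          # or "logitnormal"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_bpd < self.n_samples:
            raise ValueError("need 0 < n_bpd < n_samples")
        if not 0 <= self.n_effect_cpgs < self.n_cpgs:
            raise ValueError("need n_effect_cpgs < n_cpgs")
        for name in ("nrbc_mean", "nrbc_sd", "bw_ga_r2", "nrbc_bw_r2",
                     "effect_hypo_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_model not in ("beta", "logitnormal"):
            raise ValueError("noise_model must be 'beta' or 'logitnormal'")


@dataclass
class CohortTruth:
    """Ground truth recorded alongside a generated cohort."""

    true_cell_fractions: pd.DataFrame  # sample-by-7, rows sum to 1
    effect_cpg_ids: list[str]
    effect_signs: dict[str, int]
    ga_cpg_ids: list[str]
    injected_sem_positions: list[tuple[str, str]]  # (cpg_id, sample_id)
    true_ga: pd.Series
    true_bw: pd.Series
    smoking_cpg_id: Optional[str] = None
    nrbc_hypo_cpg_ids: list[str] = field(default_factory=list)
    clock: Optional[ClockModel] = None
    n_clipped: int = 0


def generate_reference_profiles(
    n_cpgs: int,
    cell_types: Sequence[str] = CELL_TYPES,
    seed: int = 0,
    per_type: int = 100,
    nrbc_hypo_fraction: float = 0.3,
    nrbc_hypo_shift: float = 0.2,
) -> ReferenceProfile:
    """Construct cell-type mean methylation profiles with planted markers.

    Each cell type receives ``per_type`` discriminating CpGs (half
    hypermethylated in that type, half hypomethylated) whose mean beta
    differs from every other type's by at least 0.3. Away from markers the
    types share a bimodal baseline with small jitter. The NRBC profile
    additionally shifts ``nrbc_hypo_fraction`` of the highly methylated
    (beta > 0.7) non-marker CpGs down by ``nrbc_hypo_shift``, emulating
    the genome-wide demethylation of nucleated red blood cells.
    """
    n_types = len(cell_types)
    minimum = per_type * n_types
    if n_cpgs < minimum:
        raise ValueError(
            f"n_cpgs={n_cpgs} too small: need at least {minimum} "
            f"({per_type} discriminating CpGs x {n_types} cell types)"
        )
    rng = np.random.default_rng(seed)
    cpg_ids = [f"cg{i:08d}" for i in range(n_cpgs)]

    comp = rng.choice(3, size=n_cpgs, p=[0.35, 0.20, 0.45])
    base = np.empty(n_cpgs)
    base[comp == 0] = rng.beta(2, 18, size=(comp == 0).sum())     # unmethylated
    base[comp == 1] = rng.uniform(0.2, 0.8, size=(comp == 1).sum())
    base[comp == 2] = rng.beta(18, 2, size=(comp == 2).sum())     # methylated

    means = np.clip(
        base[:, None] + rng.normal(0.0, 0.01, size=(n_cpgs, n_types)),
        0.001, 0.999,
    )
    disc: dict[str, list[str]] = {}
    half = per_type // 2
    for t_idx, t in enumerate(cell_types):
        rows = np.arange(t_idx * per_type, (t_idx + 1) * per_type)
        hyper, hypo = rows[:half], rows[half:]
        others = [j for j in range(n_types) if j != t_idx]
        means[np.ix_(hyper, others)] = rng.uniform(0.05, 0.18, (half, n_types - 1))
        means[hyper, t_idx] = rng.uniform(0.82, 0.95, half)
        means[np.ix_(hypo, others)] = rng.uniform(0.82, 0.95, (half, n_types - 1))
        means[hypo, t_idx] = rng.uniform(0.05, 0.18, half)
        disc[t] = [cpg_ids[i] for i in rows]

    nrbc_idx = list(cell_types).index("NRBC") if "NRBC" in cell_types else None
    if nrbc_idx is not None and nrbc_hypo_fraction > 0:
        nondisc = np.arange(per_type * n_types, n_cpgs)
        candidates = nondisc[base[nondisc] > 0.7]
        n_shift = int(round(nrbc_hypo_fraction * len(candidates)))
        shifted = rng.choice(candidates, size=n_shift, replace=False)
        means[shifted, nrbc_idx] = np.clip(
            means[shifted, nrbc_idx] - nrbc_hypo_shift, 0.001, 0.999
        )
    return ReferenceProfile(
        means=pd.DataFrame(means, index=cpg_ids, columns=list(cell_types)),
        discriminating_cpgs=disc,
    )


def nrbc_hypomethylated_cpgs(
    reference: ReferenceProfile, min_gap: float = 0.15
) -> list[str]:
    """Non-marker CpGs where the NRBC profile sits well below the others."""
    means = reference.means
    others = [c for c in means.columns if c != "NRBC"]
    gap = means[others].mean(axis=1) - means["NRBC"]
    disc = {c for cpgs in reference.discriminating_cpgs.values() for c in cpgs}
    return [c for c in means.index[(gap > min_gap)] if c not in disc]


# ---------------------------------------------------------------------------
# latent-Gaussian calibration of the NRBC fraction (Gauss-Hermite quadrature)

def _gh_nodes(n: int = 80) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.hermite.hermgauss(n)
    return math.sqrt(2.0) * x, w / math.sqrt(math.pi)


@lru_cache(maxsize=32)
def _calibrate_latent(mean: float, sd: float) -> tuple[float, float]:
    """Find (mu, sigma) with expit(N(mu, sigma^2)) matching mean and SD."""
    z, w = _gh_nodes()

    def moments(mu: float, s: float) -> tuple[float, float]:
        p = expit(mu + s * z)
        m = w @ p
        v = w @ (p - m) ** 2
        return m, math.sqrt(max(v, 1e-300))

    def f(x):
        m, s_ = moments(x[0], math.exp(x[1]))
        return [m - mean, s_ - sd]

    sol = root(f, x0=[logit(mean), 0.0], tol=1e-12)
    if not sol.success:
        raise RuntimeError("NRBC latent moment calibration failed")
    return float(sol.x[0]), float(math.exp(sol.x[1]))


@lru_cache(maxsize=32)
def _calibrate_rho(mu: float, sigma: float, target_r2: float) -> float:
    """Latent correlation giving corr(expit(latent), driver)^2 = target."""
    if target_r2 == 0:
        return 0.0
    z, w = _gh_nodes(48)
    A, B = np.meshgrid(z, z, indexing="ij")
    W = np.outer(w, w)

    def observed_r2(rho: float) -> float:
        p = expit(mu + sigma * (rho * A + math.sqrt(1 - rho**2) * B))
        m = (W * p).sum()
        cov = (W * p * A).sum()  # driver is standard normal
        var_p = (W * (p - m) ** 2).sum()
        return cov**2 / var_p

    hi = observed_r2(0.999)
    if hi <= target_r2:
        return 0.999
    return float(brentq(lambda r: observed_r2(r) - target_r2, 1e-6, 0.999,
                        xtol=1e-10))


def _zscore(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def generate_cohort(
    config: CohortConfig, reference: ReferenceProfile
) -> tuple[BetaMatrix, pd.DataFrame, CohortTruth]:
    """Draw one cohort: beta matrix, sample sheet, and ground truth."""
    cfg = config
    if len(reference.means) < cfg.n_cpgs:
        raise ValueError("reference does not cover n_cpgs")
    ref = reference.means.iloc[: cfg.n_cpgs]
    cpg_ids = list(ref.index)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]

    # --- covariates -------------------------------------------------------
    ga = rng.uniform(*cfg.ga_range, size=n)
    sd_ga = (cfg.ga_range[1] - cfg.ga_range[0]) / math.sqrt(12.0)
    r2 = cfg.bw_ga_r2
    resid_sd = BW_SLOPE_G_PER_WEEK * sd_ga * math.sqrt((1 - r2) / r2)
    ga_mid = 0.5 * (cfg.ga_range[0] + cfg.ga_range[1])
    bw = BW_MEAN_G + BW_SLOPE_G_PER_WEEK * (ga - ga_mid) + rng.normal(0, resid_sd, n)
    bw = np.maximum(bw, BW_FLOOR_G)

    mu, sigma = _calibrate_latent(cfg.nrbc_mean, cfg.nrbc_sd)
    rho = _calibrate_rho(mu, sigma, cfg.nrbc_bw_r2)
    eps = rng.normal(size=n)
    latent = mu + sigma * (-rho * _zscore(bw) + math.sqrt(1 - rho**2) * eps)
    nrbc = expit(latent)

    leuko_types = [t for t in cfg.cell_types if t != "NRBC"]
    alpha = np.array([LEUKOCYTE_PROPS.get(t, 0.1) for t in leuko_types])
    alpha = alpha / alpha.sum() * DIRICHLET_CONCENTRATION
    leuko = rng.dirichlet(alpha, size=n) * (1.0 - nrbc)[:, None]
    fractions = pd.DataFrame(0.0, index=sample_ids, columns=list(cfg.cell_types))
    fractions.loc[:, leuko_types] = leuko
    if "NRBC" in fractions.columns:
        fractions["NRBC"] = nrbc
    fractions = fractions.div(fractions.sum(axis=1), axis=0)  # exact simplex

    risk = -_zscore(ga) - _zscore(bw) + rng.normal(0, 0.7, n)
    bpd = np.zeros(n, dtype=int)
    bpd[np.argsort(risk)[-cfg.n_bpd:]] = 1

    o2_latent = 8.0 - 2.2 * (ga - ga_mid) + 40.0 * bpd + rng.normal(0, 6.0, n)
    o2_days = np.maximum(np.round(o2_latent), 0.0).astype(int)

    sex = rng.choice(["M", "F"], size=n, p=[MALE_FRACTION, 1 - MALE_FRACTION])
    smoke_p = expit(logit(SMOKING_BASE_RATE) + 1.0 * _zscore(nrbc))
    smoking = (rng.uniform(size=n) < smoke_p).astype(int)
    ancestry = rng.choice(ANCESTRY_LEVELS, size=n, p=ANCESTRY_PROBS)
    hospital = rng.choice(HOSPITALS, size=n)
    batch = np.array([f"plate{b + 1}" for b in rng.integers(0, cfg.n_batches, n)])

    sheet = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "bpd_status": bpd,
            "ga_weeks": ga,
            "birth_weight_g": bw,
            "sex": sex,
            "smoking": smoking,
            "ancestry": ancestry,
            "hospital": hospital,
            "o2_days": o2_days,
            "batch": batch,
        }
    ).set_index("sample_id", drop=False)

    # --- methylation ------------------------------------------------------
    target = ref.to_numpy(dtype=float) @ fractions.to_numpy().T  # cpgs x n

    hypo_ids = nrbc_hypomethylated_cpgs(ReferenceProfile(
        means=ref, discriminating_cpgs=reference.discriminating_cpgs))
    smoking_cpg: Optional[str] = None
    if cfg.smoking_effect_dmeth != 0:
        pool = hypo_ids or [c for c in cpg_ids
                            if c not in set().union(
                                *reference.discriminating_cpgs.values())]
        smoking_cpg = pool[0]
        row = cpg_ids.index(smoking_cpg)
        target[row] = target[row] - cfg.smoking_effect_dmeth / 100.0 * smoking

    effect_ids: list[str] = []
    signs: dict[str, int] = {}
    if cfg.n_effect_cpgs > 0:
        disc = set().union(*reference.discriminating_cpgs.values()) \
            if reference.discriminating_cpgs else set()
        row_mean = target.mean(axis=1)
        eligible = [
            i for i, c in enumerate(cpg_ids)
            if c not in disc and c != smoking_cpg and 0.15 < row_mean[i] < 0.85
        ]
        chosen = rng.choice(eligible, size=cfg.n_effect_cpgs, replace=False)
        sgn = np.where(
            rng.uniform(size=cfg.n_effect_cpgs) < cfg.effect_hypo_fraction, -1, 1
        )
        is_bpd = bpd == 1
        for i, s in zip(chosen, sgn):
            target[i, is_bpd] += s * cfg.effect_dmeth / 100.0
            effect_ids.append(cpg_ids[i])
            signs[cpg_ids[i]] = int(s)

    ga_ids: list[str] = []
    if cfg.n_ga_cpgs > 0:
        # CpGs whose methylation tracks gestational age directly, the kind
        # of developmental signal gestational-age clocks are trained on
        disc = set().union(*reference.discriminating_cpgs.values()) \
            if reference.discriminating_cpgs else set()
        taken = disc | set(effect_ids) | {smoking_cpg}
        row_mean = target.mean(axis=1)
        eligible = [
            i for i, c in enumerate(cpg_ids)
            if c not in taken and 0.15 < row_mean[i] < 0.85
        ]
        chosen = rng.choice(eligible, size=min(cfg.n_ga_cpgs, len(eligible)),
                            replace=False)
        slopes = rng.choice([-1.0, 1.0], size=len(chosen)) * cfg.ga_effect_per_week
        ga_centered = ga - ga_mid
        for i, sl in zip(chosen, slopes):
            target[i] = target[i] + sl * ga_centered
            ga_ids.append(cpg_ids[i])

    target = np.clip(target, 1e-4, 1 - 1e-4)
    if np.isfinite(cfg.noise_precision):
        if cfg.noise_model == "beta":
            nu = cfg.noise_precision
            y = rng.beta(target * nu, (1.0 - target) * nu)
        else:  # logit-normal with matched delta-method variance
            s_logit = 1.0 / np.sqrt(
                (1.0 + cfg.noise_precision) * target * (1.0 - target)
            )
            y = expit(logit(target) + rng.normal(size=target.shape) * s_logit)
    else:
        y = target.copy()

    if cfg.batch_sd > 0 and cfg.n_batches > 1:
        eps_b = 1e-6
        yc = np.clip(y, eps_b, 1 - eps_b)
        M = np.log2(yc / (1 - yc))
        center = np.log2(target / (1 - target))
        loc = rng.normal(0.0, cfg.batch_sd, size=(cfg.n_cpgs, cfg.n_batches))
        scl = np.exp(rng.normal(0.0, cfg.batch_sd / 2.0,
                                size=(cfg.n_cpgs, cfg.n_batches)))
        levels = [f"plate{b + 1}" for b in range(cfg.n_batches)]
        for b, lv in enumerate(levels):
            sel = batch == lv
            M[:, sel] = (center[:, sel]
                         + scl[:, [b]] * (M[:, sel] - center[:, sel])
                         + loc[:, [b]])
        y = 2.0**M / (1.0 + 2.0**M)

    sem_positions: list[tuple[str, str]] = []
    if cfg.sem_rate > 0:
        rates = cfg.sem_rate * np.where(bpd == 1, cfg.sem_bpd_rate_ratio, 1.0)
        for j in range(n):
            k = rng.poisson(rates[j])
            k = min(k, cfg.n_cpgs)
            rows = rng.choice(cfg.n_cpgs, size=k, replace=False)
            shift = np.where(y[rows, j] < 0.5, cfg.sem_magnitude,
                             -cfg.sem_magnitude)
            y[rows, j] = y[rows, j] + shift
            sem_positions.extend((cpg_ids[i], sample_ids[j]) for i in rows)

    n_clipped = int(((y < 1e-6) | (y > 1 - 1e-6)).sum())
    if n_clipped:
        log.info("generate_cohort: clipped %d beta values into (0, 1)", n_clipped)
    y = np.clip(y, 1e-6, 1 - 1e-6)

    beta = BetaMatrix(values=pd.DataFrame(y, index=cpg_ids, columns=sample_ids))
    truth = CohortTruth(
        true_cell_fractions=fractions,
        effect_cpg_ids=effect_ids,
        effect_signs=signs,
        ga_cpg_ids=ga_ids,
        injected_sem_positions=sem_positions,
        true_ga=pd.Series(ga, index=sample_ids, name="ga_weeks"),
        true_bw=pd.Series(bw, index=sample_ids, name="birth_weight_g"),
        smoking_cpg_id=smoking_cpg,
        nrbc_hypo_cpg_ids=hypo_ids,
        n_clipped=n_clipped,
    )
    return beta, sheet, truth


def generate_clock(
    beta: BetaMatrix,
    ga: pd.Series | np.ndarray,
    n_clock_cpgs: int = 100,
    seed: int = 0,
    alpha: float = 1.0,
) -> ClockModel:
    """Fit a ridge-penalized linear gestational-age clock on a CpG subset.

    CpGs are ranked by absolute correlation with GA and the top
    ``n_clock_cpgs`` enter a ridge regression (``alpha=0`` gives plain
    least squares). The returned model follows the clock CSV schema:
    an intercept plus per-CpG coefficients.
    """
    g = np.asarray(ga, dtype=float)
    if beta.n_samples < 20:
        raise ValueError("need at least 20 samples to train a clock")
    if n_clock_cpgs > beta.n_cpgs:
        raise ValueError(
            f"requested {n_clock_cpgs} clock CpGs but only {beta.n_cpgs} available"
        )
    arr = beta.values.to_numpy(dtype=float)
    gc = g - g.mean()
    xc = arr - arr.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=1) * (gc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, (xc @ gc) / denom, 0.0)
    top = np.argsort(np.abs(corr))[::-1][:n_clock_cpgs]
    X = arr[top].T
    if alpha > 0:
        model = Ridge(alpha=alpha, random_state=seed)
    else:
        model = LinearRegression()
    model.fit(X, g)
    coefs = pd.Series(
        model.coef_, index=[beta.cpg_ids[i] for i in top], name="coefficient"
    )
    return ClockModel(
        intercept=float(model.intercept_), coefficients=coefs, name="synthetic"
    )


def generate_annotation(
    cpg_ids: Sequence[str],
    seed: int = 0,
    protected_ids: Sequence[str] = (),
    frac_sex_chrom: float = 0.02,
    frac_snp: float = 0.01,
    frac_crossreactive: float = 0.02,
) -> pd.DataFrame:
    """Synthetic probe annotation (chrom, 1-based pos, gene, QC flags).

    Probes named in ``protected_ids`` (planted markers, effect CpGs) stay
    autosomal and unflagged so QC filtering does not remove them.
    """
    rng = np.random.default_rng(seed)
    n = len(cpg_ids)
    chrom = np.array([f"chr{c}" for c in rng.integers(1, 23, size=n)], dtype=object)
    pos = rng.integers(1, 240_000_001, size=n)
    gene = np.array([f"GENE{i // 5}" for i in range(n)], dtype=object)
    snp = np.zeros(n, dtype=int)
    xr = np.zeros(n, dtype=int)
    protected = set(protected_ids)
    free = np.array([c not in protected for c in cpg_ids])
    free_idx = np.flatnonzero(free)
    rng.shuffle(free_idx)
    n_sex = int(frac_sex_chrom * n)
    n_snp = int(frac_snp * n)
    n_xr = int(frac_crossreactive * n)
    sex_idx = free_idx[:n_sex]
    snp_idx = free_idx[n_sex:n_sex + n_snp]
    xr_idx = free_idx[n_sex + n_snp:n_sex + n_snp + n_xr]
    chrom[sex_idx] = rng.choice(["chrX", "chrY"], size=len(sex_idx), p=[0.8, 0.2])
    snp[snp_idx] = 1
    xr[xr_idx] = 1
    return pd.DataFrame(
        {
            "cpg_id": list(cpg_ids),
            "chrom": chrom,
            "pos": pos,
            "gene": gene,
            "snp_flag": snp,
            "crossreactive_flag": xr,
        }
    )
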