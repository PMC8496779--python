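"""Synthetic matched case-control metabolomics cohorts and GWAS summary stats.

The generator emulates the data layout of a multi-cohort nested
case-control metabolomics study: correlated log-normal metabolite panels
with detection-limit censoring, 1:1 matched pairs whose case label follows
a conditional logistic model (so downstream fits are exactly
well-specified), and two-sample MR summary statistics with configurable
causal effect and pleiotropy.

Within each pair the case label is assigned by the softmax of the two
members' linear predictors eta = sum(logOR_m * z_m) + logOR_BMI * z_BMI,
which is precisely the 1:1 conditional likelihood — parameter-recovery
tests can therefore compare estimates against the configured truth
without approximation error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .qc import (
    FLAG_BELOW_LOD,
    FLAG_OK,
    METABOLITE_CLASSES,
    SEMIQUANT_CLASSES,
    MetaboliteMatrix,
    PanelSpec,
)

#: per-cohort pair shares mirroring a five-cohort consortium
_DEFAULT_COHORT_WEIGHTS = (0.486, 0.088, 0.195, 0.106, 0.125)


def _as_vector(x, n: int, name: str) -> np.ndarray:
    if x is None:
        return np.zeros(n)
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.size == 1:
        arr = np.full(n, float(arr[0]))
    if arr.size != n:
        raise ValueError(f"{name} must have length {n}, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class SimulationConfig:
    """Conditions for one simulated matched case-control metabolome.

    Defaults follow the design of a five-cohort consortium study: 1,305
    1:1 matched pairs, a 188-metabolite targeted panel, a latent-factor
    correlation structure, and a small below-LOD fraction.

    Parameters
    ----------
    n_pairs, n_metabolites, n_cohorts:
        Study size. Samples are ``2 * n_pairs``.
    n_factors:
        Latent factors driving metabolite correlation (0 = independent).
    true_logor:
        Per-metabolite log odds ratio of disease per SD of log
        concentration (scalar broadcasts; default all 0, the null).
    bmi_effect_on_metabolites:
        SD change in log metabolite per SD of BMI (the confounding path).
    bmi_logor:
        Log odds ratio of disease per SD of BMI.
    lod_quantile:
        Fraction of each metabolite's marginal distribution censored at
        the batch detection limit, in [0, 1).
    noise_sd, loading_sd:
        Residual SD of log concentrations and SD of factor loadings.
    platform:
        Panel label written into the PanelSpec ("targeted"/"untargeted").
    """

    n_pairs: int = 1305
    n_metabolites: int = 188
    n_cohorts: int = 5
    n_factors: int = 10
    true_logor: float | Sequence[float] | None = None
    bmi_effect_on_metabolites: float | Sequence[float] | None = None
    bmi_logor: float = 0.0
    lod_quantile: float = 0.05
    noise_sd: float = 1.0
    loading_sd: float = 0.5
    platform: str = "targeted"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1 or self.n_metabolites < 1:
            raise ValueError("n_pairs and n_metabolites must be >= 1")
        if self.n_cohorts < 1 or self.n_factors < 0:
            raise ValueError("n_cohorts must be >= 1 and n_factors >= 0")
        if not 0.0 <= self.lod_quantile < 1.0:
            raise ValueError("lod_quantile must lie in [0, 1)")
        for name in ("bmi_logor", "lod_quantile", "noise_sd", "loading_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        self.true_logor = _as_vector(self.true_logor, self.n_metabolites, "true_logor")
        self.bmi_effect_on_metabolites = _as_vector(
            self.bmi_effect_on_metabolites, self.n_metabolites,
            "bmi_effect_on_metabolites")


def _metabolite_names(n: int) -> list[str]:
    return [f"met_{i:04d}" for i in range(n)]


def _cohort_sizes(n_pairs: int, n_cohorts: int) -> np.ndarray:
    w = np.asarray(_DEFAULT_COHORT_WEIGHTS[:n_cohorts], dtype=float)
    if w.size < n_cohorts:
        w = np.concatenate([w, np.full(n_cohorts - w.size, w.min())])
    w = w / w.sum()
    sizes = np.floor(w * n_pairs).astype(int)
    sizes[0] += n_pairs - sizes.sum()
    sizes = np.maximum(sizes, 1)
    sizes[0] += n_pairs - sizes.sum()
    return sizes


def simulate_metabolome(config: SimulationConfig) -> tuple[MetaboliteMatrix, PanelSpec]:
    """Draw a correlated log-normal metabolite matrix with LOD censoring.

    Log concentrations follow a factor model: ``log c = mu_m + L f +
    b_m * z_BMI + noise`` with loadings drawn once per run. Values below
    the per-batch detection limit (the ``lod_quantile`` of the batch
    marginal) are flagged, not imputed — their latent values are retained
    so that downstream imputation is an explicit, testable step.

    The per-sample BMI z-score used for the confounding path is stored in
    ``sample_meta`` together with cohort and batch labels (one batch per
    cohort).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = 2 * cfg.n_pairs
    mets = _metabolite_names(cfg.n_metabolites)

    sizes = _cohort_sizes(cfg.n_pairs, cfg.n_cohorts)
    cohort = np.repeat([f"cohort_{i}" for i in range(cfg.n_cohorts)], sizes * 2)
    pair_id = np.repeat(np.arange(cfg.n_pairs), 2)

    bmi_z = rng.standard_normal(n)
    mu = rng.normal(0.0, 1.0, cfg.n_metabolites)
    if cfg.n_factors > 0:
        loadings = rng.normal(0.0, cfg.loading_sd, (cfg.n_metabolites, cfg.n_factors))
        factors = rng.standard_normal((n, cfg.n_factors))
        common = factors @ loadings.T
    else:
        common = 0.0
    log_conc = (mu + common + np.outer(bmi_z, cfg.bmi_effect_on_metabolites)
                + rng.normal(0.0, cfg.noise_sd, (n, cfg.n_metabolites)))
    values = pd.DataFrame(np.exp(log_conc), columns=mets)
    values.index = [f"s_{i:05d}" for i in range(n)]

    sample_meta = pd.DataFrame({
        "pair_id": pair_id,
        "cohort": cohort,
        "batch": cohort,  # one analytical batch per cohort
        "bmi_z": bmi_z,
    }, index=values.index)

    flags = pd.DataFrame(FLAG_OK, index=values.index, columns=mets, dtype=np.int8)
    limits = []
    for b in np.unique(cohort):
        in_batch = sample_meta["batch"].to_numpy() == b
        for m in mets:
            col = values.loc[in_batch, m]
            lod = float(np.quantile(col, cfg.lod_quantile)) if cfg.lod_quantile > 0 else 0.0
            limits.append({"metabolite": m, "batch": b, "lod": lod,
                           "lloq": lod, "uloq": np.nan})
            if cfg.lod_quantile > 0:
                below = in_batch & (values[m].to_numpy() < lod)
                flags.loc[below, m] = FLAG_BELOW_LOD

    classes = [METABOLITE_CLASSES[i % 6] for i in range(cfg.n_metabolites)]
    table = pd.DataFrame({
        "platform": cfg.platform,
        "metabolite_class": classes,
        "quantification": ["semiquantified" if c in SEMIQUANT_CLASSES else "quantified"
                           for c in classes],
        "unconfirmed": False,
    }, index=pd.Index(mets, name="metabolite"))
    panel = PanelSpec(table=table, limits=pd.DataFrame(limits))
    return MetaboliteMatrix(values, flags, sample_meta), panel


def simulate_matched_pairs(metabolome: MetaboliteMatrix,
                           config: SimulationConfig) -> pd.DataFrame:
    """Assign case/control labels and covariates to consecutive sample pairs.

    The two members of each pair share the matching variables (age, sex,
    blood-draw year, cohort). The case label is drawn with probability
    ``exp(eta_1) / (exp(eta_1) + exp(eta_2))`` from the pair members'
    linear predictors, making the 1:1 conditional logistic model exactly
    correct. Returns one row per sample: pair/case labels, matching
    variables and the risk-factor covariates used by adjusted models.
    """
    cfg = config
    n = len(metabolome.values)
    if n % 2:
        raise ValueError("sample count must be even (1:1 pairs)")
    if n < 2 * cfg.n_pairs:
        raise ValueError("metabolome has fewer than 2 * n_pairs samples")
    rng = np.random.default_rng(cfg.seed + 1)
    meta = metabolome.sample_meta
    if meta is None or "pair_id" not in meta.columns:
        raise ValueError("metabolome must carry pair ids in sample_meta")

    logc = np.log(metabolome.values.to_numpy())
    z = (logc - logc.mean(axis=0)) / logc.std(axis=0, ddof=1)
    eta = z @ np.asarray(cfg.true_logor) + cfg.bmi_logor * meta["bmi_z"].to_numpy()

    pair_ids = meta["pair_id"].to_numpy()
    case = np.zeros(n, dtype=int)
    first = np.arange(0, n, 2)
    second = first + 1
    if not np.all(pair_ids[first] == pair_ids[second]):
        raise ValueError("pair members must occupy consecutive rows")
    p_first = 1.0 / (1.0 + np.exp(-(eta[first] - eta[second])))
    first_is_case = rng.random(len(first)) < p_first
    case[first] = first_is_case
    case[second] = ~first_is_case

    n_pairs = n // 2
    age = np.repeat(rng.normal(57.6, 10.1, n_pairs), 2).round(1)
    sex = np.repeat(rng.choice(["male", "female"], n_pairs, p=[0.556, 0.444]), 2)
    draw_year = np.repeat(rng.integers(1994, 2010, n_pairs), 2)

    smoking = rng.choice(["never", "former", "current"], n, p=[0.44, 0.33, 0.23])
    pack_years = np.where(smoking == "never", 0.0,
                          rng.gamma(1.2, 14.0, n)).round(1)
    out = pd.DataFrame({
        "pair_id": pair_ids,
        "case": case,
        "cohort": meta["cohort"].to_numpy(),
        "age": age,
        "sex": sex,
        "blood_draw_year": draw_year,
        "bmi_z": meta["bmi_z"].to_numpy(),
        "bmi": (26.9 + 4.4 * meta["bmi_z"].to_numpy()).round(1),
        "smoking": smoking,
        "pack_years": pack_years,
        "alcohol_g_day": rng.gamma(0.9, 16.0, n).round(1),
        "hypertension": rng.choice(["ever", "never"], n, p=[0.29, 0.71]),
        "fasting": rng.choice(["<6h", ">=6h"], n, p=[0.6, 0.4]),
    }, index=metabolome.values.index)
    return out


def simulate_cohort(config: SimulationConfig
                    ) -> tuple[MetaboliteMatrix, PanelSpec, pd.DataFrame]:
    """Convenience wrapper: metabolome + panel + matched sample records."""
    matrix, panel = simulate_metabolome(config)
    records = simulate_matched_pairs(matrix, config)
    return matrix, panel, records


# ---------------------------------------------------------------------------
# GWAS summary statistics

_NONPALINDROMIC = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                   ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"))
_PALINDROMIC = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))


@dataclass
class GwasSimConfig:
    """Conditions for simulated two-sample MR summary statistics.

    ``causal_theta`` is the SD change in the (standardized) outcome trait
    per SD of exposure; per-SNP pleiotropic effects are drawn from
    ``Normal(pleiotropy_mean, pleiotropy_sd)``. Standard errors follow the
    standardized-trait approximation ``1 / sqrt(2 f (1-f) n)``.
    """

    n_snps: int = 549
    causal_theta: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    exposure_n: int = 700_000
    outcome_n: int = 14_296
    eaf_range: tuple[float, float] = (0.05, 0.95)
    beta_exposure_sd: float = 0.05
    palindromic_fraction: float = 0.1
    flip_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        lo, hi = self.eaf_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("eaf_range must lie strictly within (0, 1)")
        for name in ("causal_theta", "pleiotropy_mean", "pleiotropy_sd",
                     "beta_exposure_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not (0 <= self.palindromic_fraction <= 1 and 0 <= self.flip_fraction <= 1):
            raise ValueError("fractions must lie in [0, 1]")


def _se_standardized(eaf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy.stats import norm
    return np.clip(2.0 * norm.sf(np.abs(beta / se)), np.finfo(float).tiny, 1.0)


def _gwas_frame(snps, ea, oa, eaf, beta, se, n) -> pd.DataFrame:
    return pd.DataFrame({
        "snp": snps, "effect_allele": ea, "other_allele": oa,
        "eaf": eaf, "beta": beta, "se": se, "pval": _pvals(beta, se), "n": n,
    })


def _draw_instruments(cfg: GwasSimConfig, rng: np.random.Generator):
    """Shared instrument scaffold: ids, alleles, frequencies, true effects."""
    m = cfg.n_snps
    snps = [f"rs{1000 + i}" for i in range(m)]
    eaf = rng.uniform(*cfg.eaf_range, m)
    pal = rng.random(m) < cfg.palindromic_fraction
    pairs = np.empty((m, 2), dtype=object)
    if pal.any():
        pairs[pal] = [list(_PALINDROMIC[i]) for i in rng.integers(0, 4, pal.sum())]
    if (~pal).any():
        pairs[~pal] = [list(_NONPALINDROMIC[i]) for i in rng.integers(0, 8, (~pal).sum())]
    true_bx = rng.normal(0.0, cfg.beta_exposure_sd, m)
    return snps, pairs[:, 0], pairs[:, 1], eaf, true_bx


def _outcome_table(cfg, rng, snps, ea, oa, eaf, true_bx, theta) -> pd.DataFrame:
    m = cfg.n_snps
    se_y = _se_standardized(eaf, cfg.outcome_n)
    if cfg.pleiotropy_mean or cfg.pleiotropy_sd:
        # directional pleiotropy is defined relative to the exposure-raising
        # allele, so its sign follows the sign of the true exposure effect
        orient = np.where(true_bx >= 0, 1.0, -1.0)
        pleio = orient * rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, m)
    else:
        pleio = np.zeros(m)
    beta_y = theta * true_bx + pleio + rng.normal(0.0, se_y)
    tab = _gwas_frame(snps, ea, oa, eaf, beta_y, se_y, cfg.outcome_n)
    # re-express a fraction with the alleles swapped, to exercise harmonization
    flip = rng.random(m) < cfg.flip_fraction
    tab.loc[flip, ["effect_allele", "other_allele"]] = (
        tab.loc[flip, ["other_allele", "effect_allele"]].to_numpy())
    tab.loc[flip, "beta"] *= -1.0
    tab.loc[flip, "eaf"] = 1.0 - tab.loc[flip, "eaf"]
    return tab


def simulate_gwas_summary(gconfig: GwasSimConfig
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exposure and outcome summary-statistics tables for one trait pair.

    Observed exposure betas are the true per-SNP effects perturbed with
    sampling noise at the SE implied by allele frequency and sample size;
    outcome betas are ``causal_theta * true_beta + pleiotropy + noise``.
    A configurable fraction of outcome rows is emitted with swapped
    alleles (sign-flipped beta, complementary EAF) so harmonization has
    real work to do.
    """
    cfg = gconfig
    rng = np.random.default_rng(cfg.seed)
    snps, ea, oa, eaf, true_bx = _draw_instruments(cfg, rng)
    se_x = _se_standardized(eaf, cfg.exposure_n)
    beta_x = true_bx + rng.normal(0.0, se_x)
    exposure = _gwas_frame(snps, ea, oa, eaf, beta_x, se_x, cfg.exposure_n)
    outcome = _outcome_table(cfg, rng, snps, ea, oa, eaf, true_bx, cfg.causal_theta)
    return exposure, outcome


def simulate_gwas_panel(gconfig: GwasSimConfig,
                        thetas: Mapping[str, float]
                        ) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """One exposure table plus outcome tables for a panel of metabolites.

    All metabolites share the same instruments and true exposure effects;
    each gets its own causal effect ``thetas[name]``, pleiotropy draw and
    sampling noise.
    """
    cfg = gconfig
    rng = np.random.default_rng(cfg.seed)
    snps, ea, oa, eaf, true_bx = _draw_instruments(cfg, rng)
    se_x = _se_standardized(eaf, cfg.exposure_n)
    beta_x = true_bx + rng.normal(0.0, se_x)
    exposure = _gwas_frame(snps, ea, oa, eaf, beta_x, se_x, cfg.exposure_n)
    panel = {name: _outcome_table(cfg, rng, snps, ea, oa, eaf, true_bx, th)
             for name, th in thetas.items()}
    return exposure, panel


def simulate_null_exposure(gconfig: GwasSimConfig,
                           metabolites: Sequence[str]
                           ) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Instrument tables for a negative-control exposure.

    Identical machinery with ``causal_theta = 0`` against every
    metabolite: the exposure's instruments carry no signal into any
    outcome, so downstream MR scans should be null-calibrated.
    """
    return simulate_gwas_panel(gconfig, {m: 0.0 for m in metabolites})
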