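"""Two-sample mendelian randomisation from GWAS summary statistics.

Instruments are SNPs robustly associated with the exposure (p < 5e-8,
pairwise LD R^2 below threshold). After allele harmonization of the
exposure and outcome tables, three estimators of the causal effect
``theta`` (SD outcome per SD exposure) are fitted per outcome:

* IVW — inverse-variance weighted regression of outcome betas on
  exposure betas through the origin; equivalently the precision-weighted
  average of per-SNP Wald ratios. Standard errors use a multiplicative
  random-effects model: inflated by sqrt(Q / (J-1)) when the Cochran Q
  heterogeneity statistic exceeds its degrees of freedom.
* MR-Egger — the same weighted regression with a free intercept, fitted
  with all exposure betas oriented positive; the intercept estimates
  average directional pleiotropy and the slope remains a valid causal
  estimate under the InSIDE assumption.
* Weighted median — the ratio estimate at 50% of cumulative
  inverse-variance weight over ordered Wald ratios; consistent when at
  least half the weight comes from valid instruments. Its SE comes from
  a seeded parametric bootstrap.

All three are exposed as scikit-learn style estimators over arrays plus
thin functions over harmonized :class:`InstrumentSet` tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "GWAS_COLUMNS", "InstrumentSet", "MrEstimate",
    "select_instruments", "harmonize",
    "IVWEstimator", "EggerEstimator", "WeightedMedianEstimator",
    "ivw", "mr_egger", "weighted_median", "mr_scan",
]

GWAS_COLUMNS = ("snp", "effect_allele", "other_allele", "eaf", "beta", "se",
                "pval", "n")

_PALINDROMES = {frozenset(("A", "T")), frozenset(("C", "G"))}


class MrError(ValueError):
    pass


def _validate_gwas(df: pd.DataFrame, label: str) -> pd.DataFrame:
    missing = [c for c in GWAS_COLUMNS if c not in df.columns]
    if missing:
        raise MrError(f"{label} table lacks columns {missing}")
    if (df["se"] <= 0).any():
        raise MrError(f"{label} table has non-positive standard errors")
    if (df["effect_allele"] == df["other_allele"]).any():
        raise MrError(f"{label} table has identical effect/other alleles")
    return df


# ---------------------------------------------------------------------------
# instrument selection and harmonization

def select_instruments(exposure: pd.DataFrame, p_thresh: float = 5e-8,
                       r2_thresh: float = 0.01,
                       ld: pd.DataFrame | None = None) -> tuple[list[str], pd.DataFrame]:
    """Genome-wide significant, LD-independent instrument SNPs.

    Filters ``pval < p_thresh`` then greedily prunes: SNPs are visited in
    ascending p order and retained iff their R^2 with every
    already-retained SNP is below ``r2_thresh``. Without an LD matrix all
    p-passing SNPs are treated as independent (published instrument lists
    are normally pre-pruned); this is recorded in the drop log's attrs.

    Returns the retained SNP ids and a drop log (snp, reason).
    """
    _validate_gwas(exposure, "exposure")
    drops = []
    passing = exposure[exposure["pval"] < p_thresh].sort_values("pval")
    for snp in exposure.loc[~exposure["snp"].isin(passing["snp"]), "snp"]:
        drops.append({"snp": snp, "reason": f"p >= {p_thresh:g}"})
    retained: list[str] = []
    if ld is not None:
        for snp in passing["snp"]:
            r2s = [float(ld.loc[snp, k]) for k in retained
                   if snp in ld.index and k in ld.columns]
            if any(r2 >= r2_thresh for r2 in r2s):
                drops.append({"snp": snp, "reason": f"R2 >= {r2_thresh:g} with retained SNP"})
            else:
                retained.append(snp)
    else:
        retained = passing["snp"].tolist()
    if not retained:
        raise MrError("no instruments pass the selection thresholds")
    log = pd.DataFrame(drops, columns=["snp", "reason"])
    log.attrs["ld_supplied"] = ld is not None
    return retained, log


@dataclass
class InstrumentSet:
    """Harmonized exposure/outcome effect table for a set of instruments."""

    table: pd.DataFrame  # snp, beta_exposure, se_exposure, beta_outcome, se_outcome, eaf
    drops: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["snp", "reason"]))

    def __len__(self) -> int:
        return len(self.table)


def _is_palindromic(ea: str, oa: str) -> bool:
    return frozenset((str(ea).upper(), str(oa).upper())) in _PALINDROMES


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame,
              palindromic_window: tuple[float, float] = (0.42, 0.58)
              ) -> InstrumentSet:
    """Align outcome effects to the exposure's effect allele.

    Where the outcome's effect allele equals the exposure's other allele
    (and vice versa), the outcome beta is sign-flipped and its EAF
    complemented. Palindromic SNPs (A/T or C/G) whose EAF falls inside
    the ambiguity window on either side are dropped, as are SNPs with
    unresolvable allele mismatches; every drop is logged with its reason.
    """
    _validate_gwas(exposure, "exposure")
    _validate_gwas(outcome, "outcome")
    lo, hi = palindromic_window
    merged = exposure.merge(outcome, on="snp", suffixes=("_exp", "_out"))
    for snp in exposure.loc[~exposure["snp"].isin(merged["snp"]), "snp"]:
        merged.attrs.setdefault("absent", []).append(snp)
    rows, drops = [], []
    for _, r in merged.iterrows():
        ea_x, oa_x = str(r["effect_allele_exp"]).upper(), str(r["other_allele_exp"]).upper()
        ea_y, oa_y = str(r["effect_allele_out"]).upper(), str(r["other_allele_out"]).upper()
        if _is_palindromic(ea_x, oa_x) and (
                lo <= r["eaf_exp"] <= hi or lo <= r["eaf_out"] <= hi):
            drops.append({"snp": r["snp"], "reason": "palindromic, ambiguous eaf"})
            continue
        if (ea_x, oa_x) == (ea_y, oa_y):
            beta_y, eaf_y = r["beta_out"], r["eaf_out"]
        elif (ea_x, oa_x) == (oa_y, ea_y):
            beta_y, eaf_y = -r["beta_out"], 1.0 - r["eaf_out"]
        else:
            drops.append({"snp": r["snp"], "reason": "allele mismatch"})
            continue
        rows.append({
            "snp": r["snp"], "beta_exposure": r["beta_exp"],
            "se_exposure": r["se_exp"], "beta_outcome": beta_y,
            "se_outcome": r["se_out"], "eaf": r["eaf_exp"],
            "pval_exposure": r["pval_exp"],
        })
    if not rows:
        raise MrError("no SNPs survive harmonization")
    return InstrumentSet(pd.DataFrame(rows), pd.DataFrame(drops, columns=["snp", "reason"]))


# ---------------------------------------------------------------------------
# estimators

@dataclass
class MrEstimate:
    """One causal-effect estimate (SD outcome per SD exposure)."""

    method: str
    beta: float
    se: float
    p: float
    n_snps: int
    egger_intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    q: float | None = None
    q_df: int | None = None
    q_p: float | None = None
    note: str = ""

    def to_row(self) -> dict:
        return {
            "method": self.method, "beta": self.beta, "se": self.se, "p": self.p,
            "n_snps": self.n_snps, "egger_intercept": self.egger_intercept,
            "intercept_se": self.intercept_se, "intercept_p": self.intercept_p,
            "q": self.q, "q_df": self.q_df, "q_p": self.q_p, "note": self.note,
        }


def _col(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    return a.ravel()


class IVWEstimator(BaseEstimator):
    """Inverse-variance weighted regression through the origin.

    ``fit(X, y, se_outcome=...)`` with X the exposure betas (n_snps,) or
    (n_snps, 1) and y the aligned outcome betas. Weights are
    ``1 / se_outcome**2``. With a single SNP the estimate degrades to the
    Wald ratio with first-order delta-method SE (``note_`` flags this).
    """

    def __init__(self, random_effects: bool = True):
        self.random_effects = random_effects

    def fit(self, X, y, se_outcome=None, sample_weight=None):
        bx, by = _col(X), _col(y)
        if se_outcome is not None:
            w = 1.0 / _col(se_outcome) ** 2
        elif sample_weight is not None:
            w = _col(sample_weight)
        else:
            raise MrError("se_outcome (or sample_weight) is required")
        j = len(bx)
        if j < 1:
            raise MrError("IVW requires at least one SNP")
        if j == 1:
            self.beta_ = float(by[0] / bx[0])
            self.se_ = float((1.0 / np.sqrt(w[0])) / abs(bx[0]))
            self.q_, self.q_df_, self.q_p_ = 0.0, 0, np.nan
            self.note_ = "single-SNP Wald ratio"
        else:
            sxx = np.sum(w * bx * bx)
            self.beta_ = float(np.sum(w * bx * by) / sxx)
            se = float(np.sqrt(1.0 / sxx))
            q = float(np.sum(w * (by - self.beta_ * bx) ** 2))
            self.q_, self.q_df_ = q, j - 1
            self.q_p_ = float(stats.chi2.sf(q, j - 1))
            if self.random_effects and q > j - 1:
                se *= np.sqrt(q / (j - 1))
            self.se_ = se
            self.note_ = ""
        self.pvalue_ = float(2.0 * stats.norm.sf(abs(self.beta_ / self.se_)))
        self.n_snps_ = j
        return self


class EggerEstimator(BaseEstimator):
    """Weighted regression of outcome on exposure betas with an intercept.

    Exposure betas are oriented positive first (rows with negative
    exposure beta have both betas sign-flipped), as the method requires.
    The intercept estimates average directional pleiotropy. SEs carry the
    same multiplicative overdispersion as IVW, with phi = Q/(J-2);
    p-values use the t distribution on J-2 degrees of freedom.
    """

    def __init__(self, random_effects: bool = True):
        self.random_effects = random_effects

    def fit(self, X, y, se_outcome=None, sample_weight=None):
        bx, by = _col(X), _col(y)
        if se_outcome is not None:
            w = 1.0 / _col(se_outcome) ** 2
        elif sample_weight is not None:
            w = _col(sample_weight)
        else:
            raise MrError("se_outcome (or sample_weight) is required")
        j = len(bx)
        if j < 3:
            raise MrError("MR-Egger requires at least 3 SNPs")
        flip = np.sign(bx)
        flip[flip == 0] = 1.0
        bx, by = bx * flip, by * flip
        A = np.column_stack([np.ones(j), bx])
        aw = A * w[:, None]
        xtx = A.T @ aw
        coef = np.linalg.solve(xtx, aw.T @ by)
        resid = by - A @ coef
        q = float(np.sum(w * resid**2))
        phi = q / (j - 2)
        cov = np.linalg.inv(xtx)
        if self.random_effects and phi > 1.0:
            cov = cov * phi
        se = np.sqrt(np.diag(cov))
        self.intercept_, self.beta_ = float(coef[0]), float(coef[1])
        self.intercept_se_, self.se_ = float(se[0]), float(se[1])
        tdist = stats.t(j - 2)
        self.pvalue_ = float(2.0 * tdist.sf(abs(self.beta_ / self.se_)))
        self.intercept_pvalue_ = float(2.0 * tdist.sf(abs(self.intercept_ / self.intercept_se_)))
        self.q_, self.q_df_ = q, j - 2
        self.q_p_ = float(stats.chi2.sf(q, j - 2))
        self.n_snps_ = j
        return self


class WeightedMedianEstimator(BaseEstimator):
    """Weighted median of per-SNP Wald ratios.

    Ratio estimates theta_j = by_j / bx_j are ordered; weights are the
    first-order inverse variances bx_j^2 / se_y_j^2 normalized to sum 1.
    The estimate interpolates the ordered ratios at cumulative weight 0.5
    using midpoints s_k = cumsum(w)_k - w_k/2. The SE is the SD of the
    estimate over ``n_boot`` parametric bootstrap draws of (bx, by) from
    their stated SEs (bit-reproducible under ``random_state``).
    """

    def __init__(self, n_boot: int = 1000, random_state: int | None = 0):
        self.n_boot = n_boot
        self.random_state = random_state

    @staticmethod
    def _wm(bx, by, se_y):
        theta = by / bx
        w = bx**2 / se_y**2
        w = w / w.sum()
        order = np.argsort(theta)
        theta, w = theta[order], w[order]
        s = np.cumsum(w) - 0.5 * w
        return float(np.interp(0.5, s, theta))

    def fit(self, X, y, se_outcome=None, se_exposure=None):
        bx, by = _col(X), _col(y)
        if se_outcome is None:
            raise MrError("se_outcome is required")
        se_y = _col(se_outcome)
        se_x = _col(se_exposure) if se_exposure is not None else np.zeros_like(bx)
        keep = bx != 0
        if not keep.all():
            import warnings
            warnings.warn(f"dropping {np.sum(~keep)} SNP(s) with zero exposure beta")
            bx, by, se_y, se_x = bx[keep], by[keep], se_y[keep], se_x[keep]
        if len(bx) < 3:
            raise MrError("weighted median requires at least 3 usable SNPs")
        self.beta_ = self._wm(bx, by, se_y)
        rng = np.random.default_rng(self.random_state)
        boots = np.empty(self.n_boot)
        for b in range(self.n_boot):
            bx_b = bx + se_x * rng.standard_normal(len(bx))
            by_b = by + se_y * rng.standard_normal(len(by))
            ok = bx_b != 0
            boots[b] = self._wm(bx_b[ok], by_b[ok], se_y[ok])
        self.se_ = float(np.std(boots, ddof=1))
        self.pvalue_ = float(2.0 * stats.norm.sf(abs(self.beta_ / self.se_)))
        self.n_snps_ = len(bx)
        return self


# ---------------------------------------------------------------------------
# function layer over InstrumentSet

def _arrays(instruments) -> tuple[np.ndarray, ...]:
    t = instruments.table if isinstance(instruments, InstrumentSet) else instruments
    return (t["beta_exposure"].to_numpy(float), t["beta_outcome"].to_numpy(float),
            t["se_outcome"].to_numpy(float), t["se_exposure"].to_numpy(float))


def ivw(instruments) -> MrEstimate:
    """IVW causal estimate from a harmonized instrument table."""
    bx, by, se_y, _ = _arrays(instruments)
    est = IVWEstimator().fit(bx, by, se_outcome=se_y)
    return MrEstimate("IVW", est.beta_, est.se_, est.pvalue_, est.n_snps_,
                      q=est.q_, q_df=est.q_df_, q_p=est.q_p_, note=est.note_)


def mr_egger(instruments) -> MrEstimate:
    """MR-Egger slope + pleiotropy intercept from a harmonized table."""
    bx, by, se_y, _ = _arrays(instruments)
    est = EggerEstimator().fit(bx, by, se_outcome=se_y)
    return MrEstimate("Egger", est.beta_, est.se_, est.pvalue_, est.n_snps_,
                      egger_intercept=est.intercept_, intercept_se=est.intercept_se_,
                      intercept_p=est.intercept_pvalue_,
                      q=est.q_, q_df=est.q_df_, q_p=est.q_p_)


def weighted_median(instruments, n_boot: int = 1000, seed: int | None = 0) -> MrEstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE."""
    bx, by, se_y, se_x = _arrays(instruments)
    est = WeightedMedianEstimator(n_boot=n_boot, random_state=seed).fit(
        bx, by, se_outcome=se_y, se_exposure=se_x)
    return MrEstimate("weighted_median", est.beta_, est.se_, est.pvalue_, est.n_snps_)


def mr_scan(exposure: pd.DataFrame, outcome_panel: Mapping[str, pd.DataFrame],
            threshold: float | Mapping[str, float] = 0.05,
            p_thresh: float = 5e-8, r2_thresh: float = 0.01,
            ld: pd.DataFrame | None = None,
            n_boot: int = 1000, seed: int | None = 0) -> pd.DataFrame:
    """All three MR estimators against every metabolite's GWAS table.

    ``threshold`` is the per-platform significance level applied to the
    IVW p-value (a float, or a mapping metabolite -> threshold). Returns
    a tidy table with one row per metabolite x method; per-metabolite
    failures are recorded in ``error`` and the scan continues.
    """
    snps, _ = select_instruments(exposure, p_thresh, r2_thresh, ld)
    exp_sel = exposure[exposure["snp"].isin(snps)]
    rows = []
    for met, out_tab in outcome_panel.items():
        thr = threshold[met] if isinstance(threshold, Mapping) else threshold
        try:
            inst = harmonize(exp_sel, out_tab)
            ests = [ivw(inst), mr_egger(inst),
                    weighted_median(inst, n_boot=n_boot, seed=seed)]
        except (MrError, np.linalg.LinAlgError) as exc:
            rows.append({"metabolite": met, "method": "IVW", "beta": np.nan,
                         "se": np.nan, "p": np.nan, "n_snps": 0,
                         "significant": False, "error": str(exc)})
            continue
        flag = bool(ests[0].p <= thr)  # flagging keys on the primary (IVW) p
        for e in ests:
            rows.append({"metabolite": met, **e.to_row(), "significant": flag,
                         "error": ""})
    return pd.DataFrame(rows)
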