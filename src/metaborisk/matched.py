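"""Conditional logistic regression for 1:1 matched case-control sets.

For matched pairs the conditional likelihood reduces to an intercept-free
binary regression on within-pair covariate differences: with
``d_i = x_case - x_control`` for pair i,

    L(beta) = prod_i 1 / (1 + exp(-beta' d_i))

The estimator maximises this by Newton-Raphson with step-halving from
beta = 0; the likelihood is concave, so convergence failures indicate a
degenerate design (all differences zero) or complete separation. Wald
standard errors come from the observed information at the MLE and odds
ratios are reported per 1 SD of the (log-transformed, z-scored) exposure.

On top of the single fit sit the metabolome-wide scan (pooled and per
cohort) and stratified analyses with a Cochran-Q heterogeneity test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "ConditionalLogisticRegression",
    "RiskEstimate",
    "conditional_loglik",
    "pair_differences",
    "fit_conditional_logistic",
    "scan_metabolome",
    "stratified_analysis",
    "cochran_q",
]


class DegenerateDesignError(ValueError):
    """All within-pair differences vanish: the score is identically zero."""


def conditional_loglik(beta, diffs) -> float:
    """Analytic 1:1 conditional log-likelihood at ``beta``.

    ``diffs`` is the (n_pairs, p) matrix of case-minus-control covariate
    differences. Exposed so tests can compare the optimizer against a
    brute-force grid maximisation of the same function.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    D = np.asarray(diffs, dtype=float)
    if D.ndim == 1:
        D = D[:, None]
    eta = D @ beta
    # sum of log sigma(eta), computed stably
    return float(-np.logaddexp(0.0, -eta).sum())


def pair_differences(X, y, groups) -> np.ndarray:
    """Case-minus-control difference matrix from long-format data.

    Each group must contain exactly one case (y=1) and one control (y=0);
    rows with any missing covariate drop the whole pair (complete-case).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    groups = np.asarray(groups)
    diffs = []
    for g in pd.unique(groups):
        idx = np.flatnonzero(groups == g)
        if len(idx) != 2 or set(y[idx]) != {0, 1}:
            raise ValueError(
                f"matched set {g!r} must contain exactly one case and one control")
        case, ctrl = (idx[0], idx[1]) if y[idx[0]] == 1 else (idx[1], idx[0])
        d = X[case] - X[ctrl]
        if np.all(np.isfinite(d)):
            diffs.append(d)
    if not diffs:
        raise ValueError("no usable pairs after complete-case exclusion")
    return np.asarray(diffs)


class ConditionalLogisticRegression(BaseEstimator):
    """Maximum conditional-likelihood fit for 1:1 matched pairs.

    Parameters
    ----------
    tol:
        Convergence tolerance on the maximum absolute score.
    max_iter:
        Newton-Raphson iteration cap.

    Attributes
    ----------
    coef_:
        Log odds ratios per unit of each column of X.
    se_:
        Wald standard errors (observed information at the MLE).
    pvalues_, conf_int_:
        Two-sided Wald p-values and 95% confidence limits on the log scale.
    n_pairs_:
        Informative pairs used (complete-case).
    converged_:
        False under complete separation (the MLE diverges); coefficients
        then hold the last iterate and should not be interpreted.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 50):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, groups=None):
        """Fit from long-format samples (y = case indicator, groups = pair id)."""
        if groups is None:
            raise ValueError("groups (matched-set ids) are required")
        return self.fit_differences(pair_differences(X, y, groups))

    def fit_differences(self, diffs):
        """Fit directly from the case-minus-control difference matrix."""
        D = np.asarray(diffs, dtype=float)
        if D.ndim == 1:
            D = D[:, None]
        if not np.all(np.isfinite(D)):
            raise ValueError("difference matrix contains non-finite values")
        if D.shape[0] == 0:
            raise ValueError("zero usable pairs")
        if np.allclose(D, 0.0):
            raise DegenerateDesignError(
                "all within-pair differences are zero; beta is not identified")

        n, p = D.shape
        beta = np.zeros(p)
        ll = conditional_loglik(beta, D)
        converged = False
        message = ""
        for it in range(1, self.max_iter + 1):
            eta = D @ beta
            prob = 1.0 / (1.0 + np.exp(-eta))       # sigma(beta'd)
            score = D.T @ (1.0 - prob)
            if np.max(np.abs(score)) < self.tol:
                converged = True
                break
            w = prob * (1.0 - prob)
            info = (D * w[:, None]).T @ D
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError:
                message = "singular information matrix"
                break
            # step-halving to guarantee likelihood ascent
            new_ll = conditional_loglik(beta + step, D)
            halvings = 0
            while new_ll < ll and halvings < 30:
                step /= 2.0
                new_ll = conditional_loglik(beta + step, D)
                halvings += 1
            beta = beta + step
            ll = new_ll
        else:
            it = self.max_iter
        if converged and np.max(np.abs(beta)) > 15.0:
            # the likelihood is maximised at infinity; the score only falls
            # below tol because sigma saturates numerically
            converged = False
        if not converged and not message:
            message = ("non-converged: likely complete separation "
                       "(all differences of one sign along some direction)")

        eta = D @ beta
        prob = 1.0 / (1.0 + np.exp(-eta))
        w = prob * (1.0 - prob)
        info = (D * w[:, None]).T @ D
        try:
            cov = np.linalg.inv(info)
            se = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            cov = np.full((p, p), np.nan)
            se = np.full(p, np.nan)

        self.coef_ = beta
        self.cov_ = cov
        self.se_ = se
        with np.errstate(invalid="ignore", divide="ignore"):
            z = beta / se
        self.pvalues_ = 2.0 * stats.norm.sf(np.abs(z))
        self.conf_int_ = np.column_stack([beta - 1.959963984540054 * se,
                                          beta + 1.959963984540054 * se])
        self.loglik_ = ll
        self.n_pairs_ = n
        self.n_iter_ = it
        self.converged_ = converged
        self.message_ = message
        return self

    def predict_proba_pair(self, diffs):
        """P(first member of each pair is the case) at the fitted beta."""
        D = np.asarray(diffs, dtype=float)
        if D.ndim == 1:
            D = D[:, None]
        return 1.0 / (1.0 + np.exp(-(D @ self.coef_)))


@dataclass
class RiskEstimate:
    """Per-exposure conditional-logistic result (OR per 1 SD)."""

    exposure: str
    logor: float
    se: float
    p: float
    n_pairs: int
    model: str = "crude"
    cohort: str = "pooled"
    converged: bool = True
    error: str = ""

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.logor))

    @property
    def ci95(self) -> tuple[float, float]:
        h = 1.959963984540054 * self.se
        return float(np.exp(self.logor - h)), float(np.exp(self.logor + h))

    def to_row(self) -> dict:
        lo, hi = self.ci95
        return {
            "metabolite": self.exposure, "cohort": self.cohort, "model": self.model,
            "logor": self.logor, "se": self.se, "or": self.odds_ratio,
            "ci_low": lo, "ci_high": hi, "p": self.p, "n_pairs": self.n_pairs,
            "converged": self.converged, "error": self.error,
        }


def _design(z: pd.Series | np.ndarray, meta: pd.DataFrame,
            covariates: list[str] | None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assemble (X, y, groups) with dummy-coded categorical covariates."""
    cols = [np.asarray(z, dtype=float)]
    if covariates:
        for c in covariates:
            col = meta[c]
            if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
                dummies = pd.get_dummies(col, prefix=c, drop_first=True)
                cols.extend(dummies[k].to_numpy(dtype=float) for k in dummies)
            else:
                cols.append(col.to_numpy(dtype=float))
    X = np.column_stack(cols)
    return X, meta["case"].to_numpy(), meta["pair_id"].to_numpy()


def fit_conditional_logistic(exposure, meta: pd.DataFrame,
                             covariates: list[str] | None = None,
                             name: str = "exposure",
                             model: str = "crude",
                             cohort: str = "pooled") -> RiskEstimate:
    """Fit one exposure and return its :class:`RiskEstimate`.

    ``meta`` must carry ``case`` (0/1) and ``pair_id``; categorical
    covariates are dummy-coded. The reported estimate is the exposure's
    coefficient (first column).
    """
    X, y, groups = _design(exposure, meta, covariates)
    est = ConditionalLogisticRegression().fit(X, y, groups)
    return RiskEstimate(
        exposure=name, logor=float(est.coef_[0]), se=float(est.se_[0]),
        p=float(est.pvalues_[0]), n_pairs=est.n_pairs_, model=model,
        cohort=cohort, converged=est.converged_, error=est.message_)


def scan_metabolome(zmatrix: pd.DataFrame, meta: pd.DataFrame,
                    covariates: list[str] | None = None,
                    model: str = "crude",
                    per_cohort: bool = True) -> pd.DataFrame:
    """Conditional-logistic scan over every metabolite.

    Returns a tidy table with one row per metabolite x (pooled + cohort).
    Matching is within cohort, so the pooled fit simply concatenates the
    cohorts' pairs. Per-metabolite failures are recorded in the ``error``
    column and the scan continues. Adjusted models (non-empty
    ``covariates``) restrict to pairs with complete risk-factor data via
    complete-case handling inside the fit.
    """
    rows = []
    cohorts = sorted(meta["cohort"].unique()) if (per_cohort and "cohort" in meta) else []
    for met in zmatrix.columns:
        subsets = [("pooled", slice(None))]
        subsets += [(c, meta["cohort"] == c) for c in cohorts]
        for label, sel in subsets:
            sub_meta = meta.loc[sel] if label != "pooled" else meta
            sub_z = zmatrix[met].loc[sub_meta.index]
            try:
                est = fit_conditional_logistic(
                    sub_z, sub_meta, covariates, name=met, model=model, cohort=label)
            except (ValueError, np.linalg.LinAlgError) as exc:
                est = RiskEstimate(met, np.nan, np.nan, np.nan, 0, model, label,
                                   converged=False, error=str(exc))
            rows.append(est.to_row())
    return pd.DataFrame(rows)


def cochran_q(betas, ses) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity test on stratum log-ORs.

    Q = sum w_k (beta_k - beta_bar)^2 with w_k = 1/SE_k^2 and the
    inverse-variance-weighted mean beta_bar; p from chi-square(K-1).
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    ok = np.isfinite(b) & np.isfinite(s) & (s > 0)
    b, s = b[ok], s[ok]
    k = len(b)
    if k < 2:
        return np.nan, 0, np.nan
    w = 1.0 / s**2
    bbar = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - bbar) ** 2))
    return q, k - 1, float(stats.chi2.sf(q, k - 1))


def stratified_analysis(exposure: pd.Series, meta: pd.DataFrame,
                        stratifier: str,
                        n_bins: int = 2,
                        name: str = "exposure") -> tuple[pd.DataFrame, dict]:
    """Per-stratum conditional-logistic fits plus heterogeneity.

    The stratum of a pair is defined by the case's value of the
    stratifier (matching variables are shared within pairs; non-matching
    covariates are not, and the case's value is the conventional,
    documented choice). Continuous stratifiers are median-split (or cut
    into ``n_bins`` quantile bins). Strata with fewer than 2 informative
    pairs are excluded from Q with a warning.
    """
    cases = meta[meta["case"] == 1].set_index("pair_id")
    strat = cases[stratifier]
    if strat.dtype.kind in "fiu" and strat.nunique() > n_bins:
        strat = pd.qcut(strat, n_bins, duplicates="drop")
    pair_stratum = meta["pair_id"].map(strat)

    rows, betas, ses = [], [], []
    for level in pair_stratum.dropna().unique():
        sel = pair_stratum == level
        sub_meta = meta.loc[sel]
        try:
            est = fit_conditional_logistic(
                exposure.loc[sub_meta.index], sub_meta, name=name,
                model=f"stratified:{stratifier}", cohort=str(level))
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"stratum {level!r} excluded: {exc}")
            continue
        if est.n_pairs < 2:
            warnings.warn(f"stratum {level!r} has <2 informative pairs; excluded from Q")
        else:
            betas.append(est.logor)
            ses.append(est.se)
        row = est.to_row()
        row["stratum"] = str(level)
        rows.append(row)
    q, df, p = cochran_q(betas, ses)
    return pd.DataFrame(rows), {"Q": q, "df": df, "p_heterogeneity": p}
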