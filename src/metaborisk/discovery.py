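"""Multiple-testing correction via the effective number of tests.

Metabolite panels are strongly correlated, so a Bonferroni correction at
the raw panel size is too severe. The effective number of tests (ENT) is
estimated as the number of principal components explaining more than a
target fraction (default 95%) of the variance of the z-scored metabolite
matrix; the scan-wide significance threshold is then ``alpha / ENT``.
A metabolite is a "robust hit" when its pooled p-value is at or below
that threshold AND it is nominally significant (p <= 0.05) in at least
two cohorts independently.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = ["EffectiveTestCount", "effective_tests", "significance_threshold",
           "robust_hits"]


class EffectiveTestCount(BaseEstimator):
    """Count principal components explaining > ``variance_fraction`` of variance.

    Eigen-decomposes the metabolite correlation matrix on all pooled
    samples; ``n_effective_`` is the smallest k whose cumulative
    eigenvalue fraction strictly exceeds the target (the strict reading
    of "more than"). Invariant to column order and sign flips.
    """

    def __init__(self, variance_fraction: float = 0.95, alpha: float = 0.05):
        self.variance_fraction = variance_fraction
        self.alpha = alpha

    def fit(self, X, y=None):
        X = np.asarray(pd.DataFrame(X), dtype=float)
        if np.isnan(X).any():
            raise ValueError("matrix contains missing cells; impute before ENT")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance columns; drop before ENT")
        corr = np.corrcoef(X, rowvar=False)
        corr = np.atleast_2d(corr)
        eigvals = np.linalg.eigvalsh(corr)[::-1]
        eigvals = np.clip(eigvals, 0.0, None)
        frac = np.cumsum(eigvals) / eigvals.sum()
        self.eigenvalues_ = eigvals
        self.cumulative_fraction_ = frac
        self.n_effective_ = int(np.argmax(frac > self.variance_fraction) + 1)
        self.threshold_ = significance_threshold(self.n_effective_, self.alpha)
        return self


def effective_tests(zmatrix, variance_fraction: float = 0.95) -> int:
    """ENT of a complete z-scored matrix (see :class:`EffectiveTestCount`)."""
    return EffectiveTestCount(variance_fraction).fit(zmatrix).n_effective_


def significance_threshold(ent: int, alpha: float = 0.05) -> float:
    """Scan-wide threshold ``alpha / ENT`` (full precision)."""
    if ent < 1:
        raise ValueError("ENT must be >= 1")
    return alpha / float(ent)


def robust_hits(pooled_p: pd.Series, cohort_p: pd.DataFrame, threshold: float,
                nominal: float = 0.05, min_cohorts: int = 2) -> pd.DataFrame:
    """Apply the two-part replication rule, boundary inclusive.

    A metabolite is robust iff its pooled p-value is <= ``threshold`` and
    its per-cohort p-value is <= ``nominal`` in at least ``min_cohorts``
    cohorts. Cohorts with missing estimates count as non-significant.
    Output order follows ``pooled_p`` and is unaffected by cohort column
    order.
    """
    cohort_p = cohort_p.reindex(pooled_p.index)
    n_nominal = (cohort_p <= nominal).fillna(False).sum(axis=1)
    robust = (pooled_p <= threshold) & (n_nominal >= min_cohorts)
    return pd.DataFrame({
        "pooled_p": pooled_p,
        "n_cohorts_nominal": n_nominal.astype(int),
        "robust": robust.fillna(False).astype(bool),
    })
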