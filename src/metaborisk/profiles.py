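"""Comparison of metabolite effect-size profiles across analyses.

The observational risk scan and the exposure->metabolome MR scan each
yield one standardized effect (estimate / SE) per metabolite. Comparing
the two profiles by Spearman rank correlation — per platform, over the
metabolites common to both — quantifies how much of the risk signature an
exposure such as BMI could account for. A negative-control exposure run
through the same machinery should show a near-zero correlation and no MR
hits among the risk-robust metabolites.
"""

from __future__ import annotations

import warnings
from itertools import permutations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["standardized_profile", "profile_correlation",
           "negative_control_comparison"]


def standardized_profile(estimates: pd.DataFrame, source: str,
                         estimate_col: str = "logor",
                         se_col: str = "se") -> pd.Series:
    """Per-metabolite z = estimate / SE (log-OR scale for risk scans).

    ``estimates`` is indexed by metabolite (or has a ``metabolite``
    column). Rows with SE <= 0 or missing are dropped with a warning.
    The returned Series carries ``source`` in its attrs.
    """
    df = estimates
    if "metabolite" in df.columns:
        df = df.set_index("metabolite")
    est = df[estimate_col].astype(float)
    se = df[se_col].astype(float)
    bad = ~(se > 0) | est.isna()
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} row(s) with missing estimate "
                      "or non-positive SE")
    z = (est / se)[~bad]
    if z.index.has_duplicates:
        raise ValueError("duplicate metabolite ids in profile")
    z.name = "z"
    z.attrs["source"] = source
    return z


def _exact_permutation_p(a: np.ndarray, b: np.ndarray, rho: float) -> float:
    n = len(a)
    count, total = 0, 0
    for perm in permutations(range(n)):
        r = stats.spearmanr(a, b[list(perm)]).statistic
        total += 1
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    return count / total


def profile_correlation(profile_a: pd.Series, profile_b: pd.Series,
                        exact: bool = False) -> tuple[float, float, int]:
    """Spearman correlation of two standardized profiles.

    Metabolites are intersected by id; fewer than 3 in common is an
    error. Ties get average ranks and the two-sided p-value uses the t
    approximation; ``exact=True`` switches to the exact permutation
    p-value (only for n <= 10). Returns (rho, p, n_common).
    """
    common = profile_a.index.intersection(profile_b.index)
    n = len(common)
    if n < 3:
        raise ValueError(f"only {n} metabolites in common; need >= 3")
    a = profile_a.loc[common].to_numpy(float)
    b = profile_b.loc[common].to_numpy(float)
    res = stats.spearmanr(a, b)
    rho = float(res.statistic)
    if exact:
        if n > 10:
            raise ValueError("exact permutation p only supported for n <= 10")
        p = _exact_permutation_p(a, b, rho)
    else:
        p = float(res.pvalue)
    return rho, p, n


def negative_control_comparison(risk_profile: pd.Series,
                                null_scan: pd.DataFrame,
                                robust_metabolites,
                                threshold: float | Mapping[str, float]) -> dict:
    """Profile correlation against a null exposure, plus overlap audit.

    ``null_scan`` is an MR scan table (long format with ``metabolite``,
    ``method``, ``beta``, ``se``, ``p`` rows). The correlation uses the
    IVW rows' standardized effects; the overlap report counts how many
    risk-robust metabolites are IVW-significant under the null exposure
    (expected ~0 in a calibrated analysis).
    """
    ivw_rows = null_scan[null_scan["method"] == "IVW"]
    null_profile = standardized_profile(
        ivw_rows[["metabolite", "beta", "se"]], source="mr_negative_control",
        estimate_col="beta")
    rho, p, n = profile_correlation(risk_profile, null_profile)
    flagged = []
    for met in robust_metabolites:
        row = ivw_rows[ivw_rows["metabolite"] == met]
        if not len(row):
            continue
        thr = threshold[met] if isinstance(threshold, Mapping) else threshold
        if float(row["p"].iloc[0]) <= thr:
            flagged.append(met)
    return {
        "rho": rho, "p": p, "n_common": n,
        "n_robust": len(list(robust_metabolites)),
        "n_robust_mr_significant": len(flagged),
        "mr_significant_robust_metabolites": flagged,
    }
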