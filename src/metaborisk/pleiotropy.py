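"""Instrument-specificity screen via variance explained across a panel.

Before trusting a metabolite's SNPs as MR instruments, ask how much
variance those same SNPs explain in every *other* metabolite. Under
Hardy-Weinberg and a standardized trait, one SNP with effect-allele
frequency f and per-allele effect beta explains ``r^2 = 2 f (1-f) beta^2``
of the trait variance; an instrument set's cumulative R^2 in a metabolite
is the sum over its SNPs. If some non-candidate metabolite matches or
beats the candidate's own cumulative R^2 the instruments are not specific
and single-exposure MR assumptions are violated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["snp_r2", "cumulative_r2", "specificity_profile", "SpecificityProfile"]


def snp_r2(beta, eaf) -> np.ndarray | float:
    """Variance fraction explained by one SNP: ``2 f (1-f) beta^2``."""
    beta = np.asarray(beta, dtype=float)
    f = np.asarray(eaf, dtype=float)
    if np.any((f <= 0) | (f >= 1)):
        raise ValueError("eaf must lie strictly within (0, 1)")
    out = 2.0 * f * (1.0 - f) * beta**2
    return float(out) if out.ndim == 0 else out


def cumulative_r2(gwas: pd.DataFrame, snps) -> tuple[float, list[str]]:
    """Cumulative R^2 of an instrument set in one metabolite's GWAS.

    SNPs absent from the table contribute 0 and are returned for
    logging. Rows without a usable EAF fall back to ``r^2 = z^2 / n``
    with z = beta/se (the chi-square approximation).
    """
    sub = gwas[gwas["snp"].isin(list(snps))]
    missing = sorted(set(snps) - set(sub["snp"]))
    have_eaf = sub["eaf"].notna() & (sub["eaf"] > 0) & (sub["eaf"] < 1)
    total = 0.0
    if have_eaf.any():
        s = sub[have_eaf]
        total += float(np.sum(snp_r2(s["beta"].to_numpy(), s["eaf"].to_numpy())))
    if (~have_eaf).any():
        s = sub[~have_eaf]
        z = s["beta"].to_numpy(float) / s["se"].to_numpy(float)
        total += float(np.sum(z**2 / s["n"].to_numpy(float)))
    return total, missing


@dataclass
class SpecificityProfile:
    """Cumulative variance explained by one candidate's instruments."""

    candidate: str
    table: pd.DataFrame          # metabolite, r2, rank (1 = most variance)
    candidate_rank: int
    pleiotropic: bool
    specificity_ratio: float     # candidate R^2 / best non-candidate R^2
    missing_snps: dict[str, list[str]]


def specificity_profile(candidate: str, instrument_snps,
                        gwas_panel: dict[str, pd.DataFrame]) -> SpecificityProfile:
    """Rank the panel by cumulative R^2 from the candidate's instruments.

    The candidate is flagged pleiotropic unless it is *uniquely* rank 1:
    any non-candidate metabolite with cumulative R^2 >= the candidate's
    (ties included) trips the flag. ``specificity_ratio`` quantifies the
    verdict (values <= 1 mean some other metabolite is explained at least
    as well).
    """
    snps = list(instrument_snps)
    if not snps:
        raise ValueError("empty instrument set")
    if candidate not in gwas_panel:
        raise ValueError(f"candidate {candidate!r} absent from the GWAS panel")
    rows, missing = [], {}
    for met, tab in gwas_panel.items():
        r2, miss = cumulative_r2(tab, snps)
        rows.append({"metabolite": met, "r2": r2})
        if miss:
            missing[met] = miss
    table = pd.DataFrame(rows).sort_values("r2", ascending=False, kind="mergesort")
    table["rank"] = np.arange(1, len(table) + 1)
    cand_r2 = float(table.loc[table["metabolite"] == candidate, "r2"].iloc[0])
    cand_rank = int(table.loc[table["metabolite"] == candidate, "rank"].iloc[0])
    others = table[table["metabolite"] != candidate]["r2"]
    best_other = float(others.max()) if len(others) else 0.0
    pleiotropic = bool(len(others) and best_other >= cand_r2)
    ratio = cand_r2 / best_other if best_other > 0 else np.inf
    return SpecificityProfile(candidate, table.reset_index(drop=True),
                              cand_rank, pleiotropic, ratio, missing)
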