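"""Metabolomics panel quality control.

Implements the pre-analysis pipeline for targeted (Biocrates-style) and
untargeted (Metabolon-style) metabolite panels: limit-based imputation,
per-cohort sparsity exclusion, median rescaling of untargeted features,
derived sums/ratios, log-transform + z-scoring and replicate CVs.

Concentrations live in a :class:`MetaboliteMatrix` (samples x metabolites
with a per-cell quantification flag); assay metadata lives in a
:class:`PanelSpec`. Column-wise rescaling and standardisation are exposed
both as scikit-learn transformers (fit on one set of samples, apply to
another) and as thin one-shot functions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

# per-cell quantification flags
FLAG_OK = 0
FLAG_BELOW_LOD = 1
FLAG_BELOW_LLOQ = 2
FLAG_ABOVE_ULOQ = 3
FLAG_MISSING_IS = 4  # internal standard out of range: stays missing
FLAG_MISSING = 5

FLAG_NAMES = {
    FLAG_OK: "ok",
    FLAG_BELOW_LOD: "below_lod",
    FLAG_BELOW_LLOQ: "below_lloq",
    FLAG_ABOVE_ULOQ: "above_uloq",
    FLAG_MISSING_IS: "missing_internal_standard",
    FLAG_MISSING: "missing",
}

#: flags counted as "above LOD/LLOQ" for the sparsity exclusion rule
_ABOVE_LIMIT_FLAGS = (FLAG_OK, FLAG_ABOVE_ULOQ)

METABOLITE_CLASSES = (
    "acylcarnitine",
    "amino acid",
    "biogenic amine",
    "GPL",
    "sphingolipid",
    "hexose",
    "carbohydrate",
    "cofactor/vitamin",
    "energy",
    "lipid",
    "nucleotide",
    "peptide",
    "xenobiotic",
    "unknown",
)

#: classes reported semiquantified on the targeted assay (limit of detection
#: rather than limit of quantification governs low values)
SEMIQUANT_CLASSES = ("acylcarnitine", "GPL", "sphingolipid")


class QcError(ValueError):
    """A quality-control precondition was violated."""


@dataclass
class PanelSpec:
    """Per-metabolite assay metadata.

    Parameters
    ----------
    table:
        One row per metabolite (index = metabolite id) with columns
        ``platform`` ({"targeted", "untargeted"}), ``metabolite_class``,
        ``quantification`` ({"quantified", "semiquantified"}) and
        ``unconfirmed`` (bool; identity not confirmed against a standard).
    limits:
        Long-format quantification limits: columns ``metabolite``, ``batch``,
        ``lod``, ``lloq``, ``uloq`` (NaN where a limit is not defined).
    """

    table: pd.DataFrame
    limits: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["metabolite", "batch", "lod", "lloq", "uloq"]))

    def __post_init__(self) -> None:
        lim = self.limits
        if len(lim):
            bad = []
            for _, r in lim.iterrows():
                trio = [r.get("lod"), r.get("lloq"), r.get("uloq")]
                vals = [v for v in trio if v is not None and np.isfinite(v)]
                if len(vals) >= 2 and any(np.diff(vals) < 0):
                    bad.append((r["metabolite"], r["batch"]))
            if bad:
                raise QcError(f"limits must satisfy LOD <= LLOQ <= ULOQ; violated for {bad}")
        self._limit_index = (
            lim.set_index(["metabolite", "batch"]).sort_index() if len(lim) else None
        )

    def limit_for(self, metabolite: str, batch: str, kind: str) -> float:
        """Return the requested limit (NaN when absent)."""
        if self._limit_index is None:
            return np.nan
        for key in ((metabolite, batch), (metabolite, "all")):
            try:
                return float(self._limit_index.loc[key, kind])
            except KeyError:
                continue
        return np.nan

    def is_semiquantified(self, metabolite: str) -> bool:
        return str(self.table.loc[metabolite, "quantification"]) == "semiquantified"


@dataclass
class MetaboliteMatrix:
    """Samples x metabolites concentration table with quantification flags.

    ``values`` holds nonnegative concentrations (NaN = missing), ``flags``
    the per-cell codes above, and ``sample_meta`` optional per-sample
    columns (at least ``batch`` when limit imputation is batch-specific).
    """

    values: pd.DataFrame
    flags: pd.DataFrame | None = None
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.flags is None:
            self.flags = pd.DataFrame(
                np.where(self.values.isna(), FLAG_MISSING, FLAG_OK),
                index=self.values.index, columns=self.values.columns, dtype=np.int8)
        if self.flags.shape != self.values.shape:
            raise QcError("flags and values must have identical shape")
        if self.sample_meta is not None and len(self.sample_meta) != len(self.values):
            raise QcError("sample_meta must have one row per sample")

    @property
    def batches(self) -> pd.Series:
        if self.sample_meta is not None and "batch" in self.sample_meta.columns:
            return self.sample_meta["batch"]
        return pd.Series("all", index=self.values.index, name="batch")

    def copy(self) -> "MetaboliteMatrix":
        return MetaboliteMatrix(
            self.values.copy(), self.flags.copy(),
            None if self.sample_meta is None else self.sample_meta.copy())


# ---------------------------------------------------------------------------
# limit-based imputation

def impute_limits(matrix: MetaboliteMatrix, panel: PanelSpec) -> MetaboliteMatrix:
    """Impute out-of-range cells from the assay's quantification limits.

    Values flagged below the LLOQ (or below the batch LOD for
    semiquantified compounds) are set to half the relevant limit; values
    above the ULOQ are set to the ULOQ. Cells flagged as having an
    out-of-range internal standard stay missing. Idempotent.
    """
    out = matrix.copy()
    vals, flags = out.values, out.flags
    batches = out.batches
    missing_limits: dict[str, list[str]] = {}
    for met in vals.columns:
        if met not in panel.table.index:
            raise QcError(f"metabolite {met!r} absent from panel spec")
        col_flags = flags[met].to_numpy()
        if not np.isin(col_flags, (FLAG_BELOW_LOD, FLAG_BELOW_LLOQ, FLAG_ABOVE_ULOQ)).any():
            continue
        semi = panel.is_semiquantified(met)
        new = vals[met].to_numpy(dtype=float, copy=True)
        for i, f in enumerate(col_flags):
            if f in (FLAG_BELOW_LOD, FLAG_BELOW_LLOQ):
                kind = "lod" if (semi or f == FLAG_BELOW_LOD) else "lloq"
                lim = panel.limit_for(met, batches.iloc[i], kind)
                if not np.isfinite(lim):
                    # fall back to the other low limit before reporting
                    alt = "lloq" if kind == "lod" else "lod"
                    lim = panel.limit_for(met, batches.iloc[i], alt)
                if not np.isfinite(lim):
                    missing_limits.setdefault(met, []).append(str(batches.iloc[i]))
                    continue
                new[i] = lim / 2.0
            elif f == FLAG_ABOVE_ULOQ:
                lim = panel.limit_for(met, batches.iloc[i], "uloq")
                if not np.isfinite(lim):
                    missing_limits.setdefault(met, []).append(str(batches.iloc[i]))
                    continue
                new[i] = lim
        vals[met] = new
    if missing_limits:
        raise QcError(
            "flagged cells without a quantification limit: "
            + "; ".join(f"{m} (batches {sorted(set(b))})" for m, b in missing_limits.items()))
    return out


class LimitImputer(BaseEstimator, TransformerMixin):
    """Transformer wrapper around :func:`impute_limits`."""

    def __init__(self, panel: PanelSpec | None = None):
        self.panel = panel

    def fit(self, X: MetaboliteMatrix, y=None):
        if self.panel is None:
            raise QcError("LimitImputer requires a PanelSpec")
        self.n_features_in_ = X.values.shape[1]
        return self

    def transform(self, X: MetaboliteMatrix) -> MetaboliteMatrix:
        return impute_limits(X, self.panel)


# ---------------------------------------------------------------------------
# sparsity exclusion

def exclude_sparse(matrix: MetaboliteMatrix, cohorts: Sequence,
                   min_above: int = 100) -> tuple[MetaboliteMatrix, pd.DataFrame]:
    """Drop metabolites measured above LOD/LLOQ fewer than ``min_above``
    times in any single cohort.

    The rule is strict ("less than"): a metabolite with exactly
    ``min_above`` above-limit values in every cohort is retained. Returns
    the filtered matrix and a QC report (per-cohort above-limit counts and
    the retained flag, one row per metabolite).
    """
    cohorts = pd.Series(np.asarray(cohorts), index=matrix.values.index)
    if cohorts.isna().any():
        raise QcError("cohort labels must cover all samples")
    above = pd.DataFrame(
        np.isin(matrix.flags.to_numpy(), _ABOVE_LIMIT_FLAGS),
        index=matrix.values.index, columns=matrix.values.columns)
    counts = above.groupby(cohorts.to_numpy()).sum()  # cohorts x metabolites
    retained = (counts >= min_above).all(axis=0)
    report = counts.T.copy()
    report.columns = [f"n_above_limit_{c}" for c in report.columns]
    report["min_above_limit"] = counts.min(axis=0).to_numpy()
    report["retained"] = retained.to_numpy()
    report.index.name = "metabolite"
    keep = [m for m in matrix.values.columns if retained[m]]
    filtered = MetaboliteMatrix(
        matrix.values[keep].copy(), matrix.flags[keep].copy(),
        None if matrix.sample_meta is None else matrix.sample_meta.copy())
    return filtered, report


class SparsityFilter(BaseEstimator, TransformerMixin):
    """Column filter applying the per-cohort above-limit count rule."""

    def __init__(self, min_above: int = 100):
        self.min_above = min_above

    def fit(self, X: MetaboliteMatrix, y=None, cohorts: Sequence | None = None):
        if cohorts is None:
            if X.sample_meta is None or "cohort" not in X.sample_meta.columns:
                raise QcError("SparsityFilter needs cohort labels")
            cohorts = X.sample_meta["cohort"]
        _, report = exclude_sparse(X, cohorts, self.min_above)
        self.report_ = report
        self.retained_ = report.index[report["retained"]].tolist()
        return self

    def transform(self, X: MetaboliteMatrix) -> MetaboliteMatrix:
        keep = [m for m in X.values.columns if m in set(self.retained_)]
        return MetaboliteMatrix(
            X.values[keep].copy(), X.flags[keep].copy(),
            None if X.sample_meta is None else X.sample_meta.copy())


# ---------------------------------------------------------------------------
# untargeted rescaling

class MedianRescaler(BaseEstimator, TransformerMixin):
    """Per-feature median rescaling with minimum imputation.

    Each column is divided by the median of its observed values so the
    observed median becomes 1; missing cells are then filled with the
    (post-scaling) minimum observed value — the standard delivery format
    of untargeted metabolomics vendors.
    """

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        med = X.median(axis=0, skipna=True)
        empty = med.index[X.notna().sum(axis=0) == 0].tolist()
        if empty:
            raise QcError(f"all-missing metabolites cannot be rescaled: {empty}")
        self.median_ = med
        self.fill_min_ = (X / med).min(axis=0, skipna=True)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X) / self.median_
        return X.fillna(self.fill_min_)


def rescale_untargeted(values: pd.DataFrame) -> pd.DataFrame:
    """One-shot :class:`MedianRescaler` (fit and apply on the same samples)."""
    return MedianRescaler().fit_transform(values)


# ---------------------------------------------------------------------------
# derived sums and ratios

@dataclass(frozen=True)
class RatioDef:
    """A derived pseudo-metabolite: sum(numerator) / sum(denominator).

    With an empty denominator the feature is a plain sum. ``orientation``
    records clinical directionality (e.g. a low Fischer ratio signals
    liver dysfunction) as metadata only.
    """

    name: str
    numerator: tuple[str, ...]
    denominator: tuple[str, ...] = ()
    orientation: str = ""


FISCHER_RATIO = RatioDef(
    name="Fischer ratio",
    numerator=("Leu", "Ile", "Val"),
    denominator=("Phe", "Tyr"),
    orientation="lower values signal liver dysfunction",
)


def derive_ratios(values: pd.DataFrame,
                  ratios: Iterable[RatioDef]) -> pd.DataFrame:
    """Append derived sums/ratios as new columns.

    A sample with any missing constituent gets a missing derived value;
    a zero denominator yields missing, not infinity.
    """
    out = values.copy()
    for r in ratios:
        missing = [m for m in (*r.numerator, *r.denominator) if m not in values.columns]
        if missing:
            raise QcError(f"ratio {r.name!r}: constituents absent from matrix: {missing}")
        num = values[list(r.numerator)].sum(axis=1, skipna=False)
        if r.denominator:
            den = values[list(r.denominator)].sum(axis=1, skipna=False)
            col = num / den.where(den != 0)
        else:
            col = num
        out[r.name] = col.replace([np.inf, -np.inf], np.nan)
    return out


# ---------------------------------------------------------------------------
# log transform + z-scoring

class LogStandardizer(BaseEstimator, TransformerMixin):
    """Natural-log transform followed by per-column z-scoring.

    Parameters
    ----------
    on_constant:
        ``"raise"`` (default) errors on a zero-variance column after the
        log transform; ``"drop"`` removes it with a warning.
    """

    def __init__(self, on_constant: str = "raise"):
        self.on_constant = on_constant

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        if (X <= 0).any().any():
            bad = X.columns[(X <= 0).any(axis=0)].tolist()
            raise QcError(
                f"log transform requires strictly positive values (impute first): {bad}")
        logx = np.log(X)
        mean = logx.mean(axis=0, skipna=True)
        sd = logx.std(axis=0, ddof=1, skipna=True)
        const = sd.index[(sd == 0) | sd.isna()].tolist()
        if const:
            if self.on_constant == "drop":
                warnings.warn(f"dropping zero-variance metabolites: {const}")
            else:
                raise QcError(f"zero variance after log transform: {const}")
        self.columns_ = [c for c in X.columns if c not in set(const)]
        self.mean_ = mean[self.columns_]
        self.scale_ = sd[self.columns_]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)[self.columns_]
        if (X <= 0).any().any():
            raise QcError("log transform requires strictly positive values")
        return (np.log(X) - self.mean_) / self.scale_


def log_standardize(values: pd.DataFrame, cohorts: Sequence | None = None,
                    on_constant: str = "raise") -> pd.DataFrame:
    """Log-transform and z-score each metabolite.

    With ``cohorts`` given, standardisation is performed within each cohort
    before pooling (each cohort contributes mean-0, SD-1 columns); without,
    a single global scaling is used.
    """
    if cohorts is None:
        return LogStandardizer(on_constant=on_constant).fit_transform(values)
    cohorts = pd.Series(np.asarray(cohorts), index=values.index)
    parts = []
    common: set | None = None
    for _, idx in values.groupby(cohorts.to_numpy()).groups.items():
        z = LogStandardizer(on_constant=on_constant).fit_transform(values.loc[idx])
        parts.append(z)
        common = set(z.columns) if common is None else common & set(z.columns)
    cols = [c for c in values.columns if c in common]
    return pd.concat([p[cols] for p in parts]).loc[values.index]


# ---------------------------------------------------------------------------
# replicate coefficients of variation

def compute_cv(replicates: pd.DataFrame, batches: Sequence) -> pd.DataFrame:
    """Intra- and inter-batch CVs (%) from repeated QC-sample measurements.

    Per metabolite: intra-batch CV is the median over batches of
    100 * SD/mean within a batch (batches with fewer than 2 replicates
    yield a missing CV); inter-batch CV is 100 * SD/mean of the batch
    means (missing with fewer than 2 batches).
    """
    batches = pd.Series(np.asarray(batches), index=replicates.index)
    grouped = replicates.groupby(batches.to_numpy())
    per_batch_cv = grouped.agg(
        lambda s: 100.0 * s.std(ddof=1) / s.mean() if s.notna().sum() >= 2 else np.nan)
    batch_means = grouped.mean()
    intra = per_batch_cv.median(axis=0, skipna=True)
    if len(batch_means) >= 2:
        inter = 100.0 * batch_means.std(axis=0, ddof=1) / batch_means.mean(axis=0)
    else:
        inter = pd.Series(np.nan, index=replicates.columns)
    out = pd.DataFrame({"intra_batch_cv": intra, "inter_batch_cv": inter})
    out.index.name = "metabolite"
    return out


# ---------------------------------------------------------------------------
# cross-panel bookkeeping

def _canon(name: str) -> str:
    return " ".join(str(name).split()).casefold()


@dataclass
class PanelMerge:
    union: list[str]
    intersection: list[str]
    only_a: list[str]
    only_b: list[str]
    alias_map: dict[str, tuple[str, str]]

    @property
    def n_union(self) -> int:
        return len(self.union)

    @property
    def n_intersection(self) -> int:
        return len(self.intersection)


def merge_panels(ids_a: Iterable[str], ids_b: Iterable[str],
                 aliases: Mapping[str, str] | None = None) -> PanelMerge:
    """Union/intersection bookkeeping for two metabolite panels.

    Ids are canonicalized (case/whitespace) before comparison.
    ``aliases`` maps a panel-B name to its panel-A synonym; aliased pairs
    count as shared but both original columns are kept (cross-platform
    duplicates are reported separately, never averaged).
    """
    a = {_canon(x): str(x) for x in ids_a}
    b = {_canon(x): str(x) for x in ids_b}
    alias = {_canon(k): _canon(v) for k, v in (aliases or {}).items()}
    b_as_a = {alias.get(k, k): v for k, v in b.items()}
    shared = sorted(set(a) & set(b_as_a))
    union_keys = sorted(set(a) | set(b_as_a))
    alias_map = {k: (a[k], b_as_a[k]) for k in shared}
    return PanelMerge(
        union=[a.get(k, b_as_a.get(k)) for k in union_keys],
        intersection=[a[k] for k in shared],
        only_a=[a[k] for k in sorted(set(a) - set(b_as_a))],
        only_b=[b_as_a[k] for k in sorted(set(b_as_a) - set(a))],
        alias_map=alias_map,
    )
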