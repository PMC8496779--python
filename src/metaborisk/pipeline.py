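"""End-to-end orchestration: simulate -> qc -> risk -> discover -> mr ->
pleiotropy -> compare.

Each stage reads only the previous stages' file artifacts, writes its
outputs plus a JSON manifest (config echo, output checksums, seeds) and
is individually re-runnable. A stage failure raises :class:`StageError`
naming the stage; partial outputs are preserved.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import discovery, io, matched, mr, pleiotropy, profiles, qc, synthetic

STAGES = ("simulate", "qc", "risk", "discover", "mr", "pleiotropy", "compare")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sim_config(cfg: dict) -> synthetic.SimulationConfig:
    return synthetic.SimulationConfig(**cfg.get("simulate", {}))


def _gwas_config(cfg: dict, section: str, **overrides) -> synthetic.GwasSimConfig:
    params = dict(cfg.get(section, {}))
    params.update(overrides)
    return synthetic.GwasSimConfig(**params)


def stage_simulate(cfg: dict, out: Path) -> None:
    scfg = _sim_config(cfg)
    matrix, panel, records = synthetic.simulate_cohort(scfg)
    outputs = io.write_matrix(matrix, out / "raw")
    outputs += io.write_panel(panel, out / "raw")
    records.to_csv(out / "samples.tsv", sep="\t")
    outputs.append(out / "samples.tsv")
    io.write_manifest(out, "simulate", cfg.get("simulate", {}), outputs,
                      {"seed": scfg.seed})


def stage_qc(cfg: dict, out: Path) -> None:
    qcfg = cfg.get("qc", {})
    matrix = io.read_matrix(out / "raw")
    panel = io.read_panel(out / "raw")
    records = pd.read_csv(out / "samples.tsv", sep="\t", index_col=0)
    imputed = qc.impute_limits(matrix, panel)
    filtered, report = qc.exclude_sparse(
        imputed, records["cohort"], qcfg.get("min_above", 100))
    if filtered.values.shape[1] == 0:
        raise qc.QcError(
            "no metabolites survive the sparsity rule; lower qc.min_above "
            "for cohorts smaller than the default threshold")
    cohorts = records["cohort"] if qcfg.get("per_cohort_scaling", True) else None
    z = qc.log_standardize(filtered.values, cohorts=cohorts, on_constant="drop")
    outputs = [out / "qc_report.tsv", out / "zmatrix.tsv"]
    report.to_csv(outputs[0], sep="\t")
    z.to_csv(outputs[1], sep="\t")
    io.write_manifest(out, "qc", qcfg, outputs)


def stage_risk(cfg: dict, out: Path) -> None:
    rcfg = cfg.get("risk", {})
    z = pd.read_csv(out / "zmatrix.tsv", sep="\t", index_col=0)
    records = pd.read_csv(out / "samples.tsv", sep="\t", index_col=0)
    scan = matched.scan_metabolome(z, records, model="crude")
    outputs = [out / "risk_crude.tsv"]
    scan.to_csv(outputs[0], sep="\t", index=False)
    if rcfg.get("bmi_adjusted", True):
        adj = matched.scan_metabolome(z, records, covariates=["bmi_z"],
                                      model="bmi_adjusted", per_cohort=False)
        outputs.append(out / "risk_bmi_adjusted.tsv")
        adj.to_csv(outputs[-1], sep="\t", index=False)
    io.write_manifest(out, "risk", rcfg, outputs)


def stage_discover(cfg: dict, out: Path) -> None:
    dcfg = cfg.get("discover", {})
    z = pd.read_csv(out / "zmatrix.tsv", sep="\t", index_col=0)
    scan = pd.read_csv(out / "risk_crude.tsv", sep="\t")
    ent = discovery.effective_tests(z, dcfg.get("variance_fraction", 0.95))
    threshold = discovery.significance_threshold(ent, dcfg.get("alpha", 0.05))
    pooled = scan[scan["cohort"] == "pooled"].set_index("metabolite")["p"]
    cohort_p = (scan[scan["cohort"] != "pooled"]
                .pivot(index="metabolite", columns="cohort", values="p"))
    hits = discovery.robust_hits(pooled, cohort_p, threshold,
                                 dcfg.get("nominal", 0.05), dcfg.get("min_cohorts", 2))
    outputs = [out / "robust_hits.tsv", out / "discovery.json"]
    hits.to_csv(outputs[0], sep="\t")
    import json
    outputs[1].write_text(json.dumps(
        {"ent": ent, "threshold": threshold, "n_robust": int(hits["robust"].sum())},
        indent=2))
    io.write_manifest(out, "discover", dcfg, outputs)


def _risk_thetas(cfg: dict, metabolites) -> dict[str, float]:
    """BMI->metabolite causal effects for the simulated GWAS panel."""
    sim = cfg.get("simulate", {})
    effects = sim.get("bmi_effect_on_metabolites", 0.0)
    arr = np.atleast_1d(np.asarray(effects, dtype=float))
    if arr.size == 1:
        arr = np.full(len(metabolites), float(arr[0]))
    return dict(zip(metabolites, arr[: len(metabolites)]))


def stage_mr(cfg: dict, out: Path) -> None:
    mcfg = cfg.get("mr", {})
    z = pd.read_csv(out / "zmatrix.tsv", sep="\t", index_col=0)
    mets = list(z.columns)
    gcfg = _gwas_config(cfg, "gwas")
    exposure, panel = synthetic.simulate_gwas_panel(gcfg, _risk_thetas(cfg, mets))
    io.write_gwas(exposure, out / "gwas" / "exposure.tsv")
    scan = mr.mr_scan(exposure, panel,
                      threshold=mcfg.get("threshold", 0.05),
                      p_thresh=mcfg.get("p_thresh", 5e-8),
                      r2_thresh=mcfg.get("r2_thresh", 0.01),
                      n_boot=mcfg.get("n_boot", 200), seed=gcfg.seed)
    null_gcfg = _gwas_config(cfg, "gwas", seed=gcfg.seed + 7,
                             causal_theta=0.0)
    null_exposure, null_panel = synthetic.simulate_null_exposure(null_gcfg, mets)
    null_scan = mr.mr_scan(null_exposure, null_panel,
                           threshold=mcfg.get("threshold", 0.05),
                           n_boot=mcfg.get("n_boot", 200), seed=null_gcfg.seed)
    outputs = [out / "mr_bmi.tsv", out / "mr_negative_control.tsv"]
    scan.to_csv(outputs[0], sep="\t", index=False)
    null_scan.to_csv(outputs[1], sep="\t", index=False)
    io.write_manifest(out, "mr", mcfg, outputs, {"seed": gcfg.seed})


def stage_pleiotropy(cfg: dict, out: Path) -> None:
    pcfg = cfg.get("pleiotropy", {})
    z = pd.read_csv(out / "zmatrix.tsv", sep="\t", index_col=0)
    mets = list(z.columns)
    hits = pd.read_csv(out / "robust_hits.tsv", sep="\t", index_col=0)
    candidates = hits.index[hits["robust"]].tolist() or mets[:1]
    gcfg = _gwas_config(cfg, "metabolite_gwas", seed=_sim_config(cfg).seed + 13)
    thetas = {m: 0.3 if m in candidates else 0.0 for m in mets}
    exposure, panel = synthetic.simulate_gwas_panel(gcfg, thetas)
    rows = []
    for cand in candidates[: pcfg.get("max_candidates", 5)]:
        snps, _ = mr.select_instruments(panel[cand], pcfg.get("p_thresh", 5e-8))
        prof = pleiotropy.specificity_profile(cand, snps, panel)
        rows.append({"candidate": cand, "rank": prof.candidate_rank,
                     "pleiotropic": prof.pleiotropic,
                     "specificity_ratio": prof.specificity_ratio})
        prof.table.to_csv(out / f"pleiotropy_{cand}.tsv", sep="\t", index=False)
    outputs = [out / "pleiotropy_verdicts.tsv"]
    pd.DataFrame(rows).to_csv(outputs[0], sep="\t", index=False)
    io.write_manifest(out, "pleiotropy", pcfg, outputs)


def stage_compare(cfg: dict, out: Path) -> None:
    import json
    ccfg = cfg.get("compare", {})
    risk = pd.read_csv(out / "risk_crude.tsv", sep="\t")
    pooled = risk[risk["cohort"] == "pooled"]
    risk_profile = profiles.standardized_profile(
        pooled[["metabolite", "logor", "se"]], source="risk")
    bmi_scan = pd.read_csv(out / "mr_bmi.tsv", sep="\t")
    bmi_ivw = bmi_scan[bmi_scan["method"] == "IVW"]
    bmi_profile = profiles.standardized_profile(
        bmi_ivw[["metabolite", "beta", "se"]], source="mr_bmi",
        estimate_col="beta")
    rho, p, n = profiles.profile_correlation(risk_profile, bmi_profile)
    hits = pd.read_csv(out / "robust_hits.tsv", sep="\t", index_col=0)
    disc = json.loads((out / "discovery.json").read_text())
    null_scan = pd.read_csv(out / "mr_negative_control.tsv", sep="\t")
    nc = profiles.negative_control_comparison(
        risk_profile, null_scan, hits.index[hits["robust"]].tolist(),
        ccfg.get("threshold", disc["threshold"]))
    result = {"bmi": {"rho": rho, "p": p, "n_common": n}, "negative_control": nc}
    outputs = [out / "profile_comparison.json"]
    outputs[0].write_text(json.dumps(result, indent=2))
    scatter = pd.DataFrame({
        "risk_z": risk_profile,
        "mr_z": bmi_profile.reindex(risk_profile.index),
        "robust": hits["robust"].reindex(risk_profile.index).fillna(False),
    })
    scatter.to_csv(out / "profile_scatter.tsv", sep="\t")
    outputs.append(out / "profile_scatter.tsv")
    io.write_manifest(out, "compare", ccfg, outputs)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "risk": stage_risk,
    "discover": stage_discover,
    "mr": stage_mr,
    "pleiotropy": stage_pleiotropy,
    "compare": stage_compare,
}


def run_pipeline(config: dict, out_dir: str | Path,
                 stages=STAGES) -> Path:
    """Run the requested stages in canonical order.

    ``config`` is the nested mapping loaded from the YAML run config.
    Raises :class:`StageError` naming the first failing stage; outputs of
    completed stages are preserved under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ordered = [s for s in STAGES if s in set(stages)]
    for stage in ordered:
        try:
            _STAGE_FUNCS[stage](config, out)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(stage, exc) from exc
    return out
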