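# metaborisk

Metabolome-wide risk analysis for matched case–control studies, with
two-sample mendelian randomisation (MR) profiling of how a modifiable
exposure (such as BMI) shapes the blood metabolome.

## The problem

Prospective cohort studies nest matched case–control sets: each incident
case (for example, kidney cancer diagnosed years after blood draw) is
paired with a control matched on age, sex and date of blood collection.
Metabolomics assays then quantify hundreds to >1,000 circulating
metabolites per pre-diagnostic sample. Three questions follow:

1. **Which metabolites predict disease risk?** For 1:1 matched pairs the
   conditional logistic likelihood eliminates per-pair nuisance
   parameters; with within-pair difference `dᵢ = x_case − x_control`,

   `L(β) = ∏ᵢ 1 / (1 + exp(−βᵀdᵢ))`

   and `exp(β)` is the odds ratio per 1 SD of log metabolite
   concentration. Because metabolite panels are strongly correlated, the
   scan threshold uses the *effective number of tests* (ENT): the number
   of principal components explaining >95% of the panel's variance, with
   threshold `0.05 / ENT`. A "robust" hit must pass that threshold in
   the pooled analysis *and* be nominally significant (p ≤ 0.05) in at
   least two cohorts independently.

2. **Is an exposure causally shaping those metabolites?** Two-sample MR
   combines SNP–exposure and SNP–metabolite summary statistics over a
   set of LD-independent, genome-wide-significant instruments. The IVW
   estimate is the weighted regression of outcome betas on exposure
   betas through the origin (`wⱼ = 1/se²_Yⱼ`); MR–Egger adds an
   intercept estimating directional pleiotropy; the weighted median
   takes the Wald-ratio estimate at 50% of cumulative inverse-variance
   weight and is consistent when ≥50% of the weight is valid. Before any
   MR, a specificity screen sums `r² = 2f(1−f)β²` over a candidate's
   instruments in *every* panel metabolite — when another metabolite is
   explained as well as the candidate, single-exposure MR is off the
   table.

3. **Do the two profiles agree?** Effect estimates are standardised
   (estimate/SE) and the risk profile is compared with the exposure's MR
   profile by Spearman rank correlation, per platform. A
   negative-control exposure with no plausible effect on disease run
   through the same machinery should produce a near-zero correlation and
   no MR hits among the risk-robust metabolites — the calibration that
   makes the positive comparison interpretable.

The package implements the full pipeline — vendor-style QC
(detection-limit imputation, per-cohort sparsity exclusion, median
rescaling, derived ratios, log + z-scoring, CVs), the matched risk scan,
ENT discovery, the MR engine, the pleiotropy screen and the profile
comparison — plus a synthetic-data generator that reproduces the
statistical structure these analyses assume, so every stage is testable
without access to consortium data.

## Worked example

```python
import numpy as np
from metaborisk import (SimulationConfig, simulate_cohort, impute_limits,
                        log_standardize, scan_metabolome, effective_tests,
                        significance_threshold, robust_hits)

cfg = SimulationConfig(n_pairs=400, n_metabolites=30, n_cohorts=3, n_factors=3,
                       true_logor=np.r_[[np.log(1.39)], np.zeros(29)],
                       lod_quantile=0.02, seed=11)
matrix, panel, records = simulate_cohort(cfg)
z = log_standardize(impute_limits(matrix, panel).values)

scan = scan_metabolome(z, records)
pooled = scan[scan["cohort"] == "pooled"].set_index("metabolite")
ent = effective_tests(z)
print(f"ENT = {ent}, scan threshold = {significance_threshold(ent):.3g}")
cohort_p = (scan[scan["cohort"] != "pooled"]
            .pivot(index="metabolite", columns="cohort", values="p"))
hits = robust_hits(pooled["p"], cohort_p, significance_threshold(ent))
print(pooled.join(hits["robust"]).sort_values("p").head(3)
      [["or", "ci_low", "ci_high", "p", "robust"]].round(4))
```

prints

```
ENT = 26, scan threshold = 0.00192
                or  ci_low  ci_high       p  robust
metabolite
met_0000    1.4610  1.2542   1.7020  0.0000    True
met_0014    0.7732  0.6645   0.8997  0.0009    True
met_0023    0.8443  0.7293   0.9773  0.0234   False
```

The 30-metabolite panel collapses to 26 effective tests; the one
metabolite simulated with a true OR of 1.39 per SD is recovered at 1.46
(CI 1.25–1.70) and flagged robust, while a correlated null neighbour
that drifts below 0.05 pooled is *not* robust because it misses the
ENT-corrected threshold.

A command-line front end runs the stages from YAML configuration:
`metaborisk all --config run.yaml --out artifacts/` (subcommands
`simulate`, `qc`, `risk`, `discover`, `mr`, `pleiotropy`, `compare`
re-run any stage from its file inputs).

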