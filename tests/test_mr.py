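"""Two-sample MR: instrument selection, harmonization and estimators."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaborisk.mr import (EggerEstimator, IVWEstimator, MrError,
                           WeightedMedianEstimator, harmonize, ivw, mr_egger,
                           mr_scan, select_instruments, weighted_median)
from metaborisk.synthetic import GwasSimConfig, simulate_gwas_panel, simulate_gwas_summary


def gwas_table(snps, ea, oa, eaf, beta, se, n=10000):
    from scipy.stats import norm
    beta, se = np.asarray(beta, float), np.asarray(se, float)
    return pd.DataFrame({
        "snp": snps, "effect_allele": ea, "other_allele": oa, "eaf": eaf,
        "beta": beta, "se": se, "pval": 2 * norm.sf(np.abs(beta / se)), "n": n})


def instrument_frame(bx, by, se_y, se_x=None):
    bx = np.asarray(bx, float)
    return pd.DataFrame({
        "snp": [f"rs{i}" for i in range(len(bx))],
        "beta_exposure": bx,
        "se_exposure": np.zeros(len(bx)) if se_x is None else np.asarray(se_x, float),
        "beta_outcome": np.asarray(by, float),
        "se_outcome": np.asarray(se_y, float),
        "eaf": 0.3,
    })


class TestSelectInstruments:
    def test_correlated_pair_keeps_smaller_p(self):
        tab = gwas_table(["a", "b"], "A", "G", 0.3, [0.1, 0.09], [0.005, 0.005])
        ld = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]], index=["a", "b"],
                          columns=["a", "b"])
        snps, log = select_instruments(tab, ld=ld)
        assert snps == ["a"]
        assert "R2" in log["reason"].iloc[-1]

    def test_independent_snps_all_retained(self):
        tab = gwas_table(list("abc"), "A", "G", 0.3, [0.1] * 3, [0.005] * 3)
        ld = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        assert select_instruments(tab, ld=ld)[0] == ["a", "b", "c"]

    def test_block_ld_prune_satisfies_pairwise_constraint(self, rng):
        """Greedy retention leaves no retained pair with R^2 >= threshold
        (verified exhaustively) and drops nothing retainable first."""
        m = 20
        snps = [f"rs{i}" for i in range(m)]
        # block-diagonal LD: 4 blocks of 5 SNPs with high within-block R2
        ld = np.eye(m)
        for b in range(4):
            s = slice(5 * b, 5 * b + 5)
            ld[s, s] = 0.8
        np.fill_diagonal(ld, 1.0)
        ld = pd.DataFrame(ld, index=snps, columns=snps)
        beta = rng.uniform(0.05, 0.2, m)
        tab = gwas_table(snps, "A", "G", 0.3, beta, 0.005)
        kept, _ = select_instruments(tab, ld=ld)
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert ld.loc[a, b] < 0.01 or a == b

    def test_no_passing_snps_is_an_error(self):
        tab = gwas_table(["a"], "A", "G", 0.3, [0.001], [0.01])
        with pytest.raises(MrError, match="no instruments"):
            select_instruments(tab)


class TestHarmonize:
    def test_swapped_alleles_flip_beta_and_eaf(self):
        exp = gwas_table(["rs1"], "A", "G", 0.3, [0.1], [0.01])
        out = gwas_table(["rs1"], "G", "A", 0.7, [0.10], [0.02])
        inst = harmonize(exp, out)
        assert inst.table["beta_outcome"].iloc[0] == pytest.approx(-0.10)

    def test_ambiguous_palindromic_dropped(self):
        exp = gwas_table(["rs1"], "A", "T", 0.50, [0.1], [0.01])
        out = gwas_table(["rs2", "rs1"], ["A", "A"], ["G", "T"], 0.50,
                         [0.1, 0.05], [0.01, 0.01])
        with pytest.raises(MrError):
            harmonize(exp, out)  # sole shared SNP dropped
        exp2 = pd.concat([exp, gwas_table(["rs2"], "A", "G", 0.3, [0.2], [0.01])])
        inst = harmonize(exp2, out)
        assert inst.table["snp"].tolist() == ["rs2"]
        assert inst.drops["reason"].str.contains("palindromic").any()

    def test_aligned_table_passes_through(self):
        exp = gwas_table(["rs1", "rs2"], "A", "G", 0.3, [0.1, 0.2], [0.01, 0.01])
        out = gwas_table(["rs1", "rs2"], "A", "G", 0.3, [0.05, 0.1], [0.02, 0.02])
        inst = harmonize(exp, out)
        assert np.allclose(inst.table["beta_outcome"], [0.05, 0.1])
        assert len(inst.drops) == 0

    def test_mismatched_alleles_dropped_with_reason(self):
        exp = gwas_table(["rs1", "rs2"], ["A", "A"], ["G", "G"], 0.3,
                         [0.1, 0.2], [0.01, 0.01])
        out = gwas_table(["rs1", "rs2"], ["A", "C"], ["G", "T"], 0.3,
                         [0.1, 0.1], [0.01, 0.01])
        inst = harmonize(exp, out)
        assert inst.drops["reason"].tolist() == ["allele mismatch"]

    def test_generator_flips_are_recovered(self):
        """Harmonizing the generator's deliberately re-stranded outcome
        rows recovers Wald ratios tight around theta."""
        cfg = GwasSimConfig(n_snps=80, causal_theta=0.4, exposure_n=10**10,
                            outcome_n=10**10, palindromic_fraction=0.0,
                            flip_fraction=0.5, seed=21)
        exp, out = simulate_gwas_summary(cfg)
        inst = harmonize(exp, out)
        assert len(inst) == 80
        strong = inst.table[inst.table["beta_exposure"].abs() > 0.02]
        ratios = strong["beta_outcome"] / strong["beta_exposure"]
        assert np.allclose(ratios, 0.4, atol=1e-2)


class TestIvw:
    def test_single_snp_wald_ratio(self):
        est = ivw(instrument_frame([0.1], [0.05], [0.01]))
        assert est.beta == pytest.approx(0.5)
        assert est.note == "single-SNP Wald ratio"
        assert est.se == pytest.approx(0.01 / 0.1)

    def test_closed_form_weighted_least_squares(self):
        """Hand-computed WLS through the origin:
        sum(w bx by)/sum(w bx^2) = 107.5/525 = 0.20476..."""
        est = ivw(instrument_frame([0.1, 0.2, 0.1], [0.02, 0.04, 0.03],
                                   [0.01, 0.01, 0.02]))
        assert est.beta == pytest.approx(107.5 / 525, rel=1e-12)
        assert est.beta == pytest.approx(0.2048, abs=5e-5)

    def test_matches_statsmodels_wls_through_origin(self, rng):
        import statsmodels.api as sm
        bx = rng.uniform(0.02, 0.2, 40)
        by = 0.3 * bx + rng.normal(0, 0.01, 40)
        se_y = rng.uniform(0.005, 0.02, 40)
        mine = IVWEstimator(random_effects=False).fit(bx, by, se_outcome=se_y)
        ref = sm.WLS(by, bx[:, None], weights=1 / se_y**2).fit()
        assert mine.beta_ == pytest.approx(ref.params[0], rel=1e-10)

    def test_no_heterogeneity_keeps_fixed_effect_se(self):
        bx = np.array([0.1, 0.2, 0.15])
        se_y = np.array([0.01, 0.01, 0.01])
        est = IVWEstimator().fit(bx, 0.5 * bx, se_outcome=se_y)
        assert est.q_ == pytest.approx(0.0, abs=1e-20)
        assert est.se_ == pytest.approx(np.sqrt(1 / np.sum(bx**2 / se_y**2)))


class TestEgger:
    def test_exact_line_through_origin(self):
        bx = np.array([0.05, 0.1, 0.2, 0.3])
        est = mr_egger(instrument_frame(bx, 0.5 * bx, [0.01] * 4))
        assert est.beta == pytest.approx(0.5, abs=1e-12)
        assert est.egger_intercept == pytest.approx(0.0, abs=1e-12)

    def test_exact_affine_relation(self):
        bx = np.array([0.05, 0.1, 0.2, 0.3])
        est = mr_egger(instrument_frame(bx, 0.03 + 0.5 * bx, [0.01] * 4))
        assert est.beta == pytest.approx(0.5, abs=1e-10)
        assert est.egger_intercept == pytest.approx(0.03, abs=1e-10)

    def test_requires_three_snps(self):
        with pytest.raises(MrError, match="at least 3"):
            mr_egger(instrument_frame([0.1, 0.2], [0.05, 0.1], [0.01, 0.01]))

    def test_matches_statsmodels_wls_with_intercept(self, rng):
        import statsmodels.api as sm
        bx = rng.uniform(0.02, 0.2, 30)  # already positive: no orientation flip
        by = 0.02 + 0.4 * bx + rng.normal(0, 0.01, 30)
        se_y = rng.uniform(0.005, 0.02, 30)
        mine = EggerEstimator(random_effects=False).fit(bx, by, se_outcome=se_y)
        ref = sm.WLS(by, sm.add_constant(bx), weights=1 / se_y**2).fit()
        assert mine.beta_ == pytest.approx(ref.params[1], rel=1e-9)
        assert mine.intercept_ == pytest.approx(ref.params[0], rel=1e-9)

    def test_intercept_constrained_to_zero_equals_ivw(self, rng):
        """The through-origin weighted regression is exactly the IVW fit."""
        bx = rng.uniform(-0.2, 0.2, 25)
        by = 0.3 * bx + rng.normal(0, 0.02, 25)
        se_y = rng.uniform(0.005, 0.02, 25)
        w = 1 / se_y**2
        constrained = np.sum(w * bx * by) / np.sum(w * bx * bx)
        est = IVWEstimator().fit(bx, by, se_outcome=se_y)
        assert est.beta_ == pytest.approx(constrained, abs=1e-10)


class TestWeightedMedian:
    def test_middle_ratio_with_equal_weights(self):
        est = weighted_median(instrument_frame(
            [0.1, 0.1, 0.1], [0.02, 0.05, 0.09], [0.01] * 3), n_boot=50)
        assert est.beta == pytest.approx(0.5)

    def test_dominant_snp_returns_its_ratio(self):
        # first SNP holds >50% of total weight
        est = weighted_median(instrument_frame(
            [1.0, 0.05, 0.05], [0.3, 0.04, 0.05], [0.01] * 3), n_boot=50)
        assert est.beta == pytest.approx(0.3, abs=0.02)

    def test_zero_exposure_beta_dropped_with_warning(self):
        frame = instrument_frame([0.0, 0.1, 0.1, 0.1], [0.1, 0.02, 0.05, 0.09],
                                 [0.01] * 4)
        with pytest.warns(UserWarning, match="zero exposure"):
            est = weighted_median(frame, n_boot=50)
        assert est.n_snps == 3

    def test_bootstrap_se_reproducible_under_seed(self, rng):
        frame = instrument_frame(rng.uniform(0.05, 0.2, 10),
                                 rng.uniform(0.0, 0.1, 10),
                                 rng.uniform(0.005, 0.02, 10),
                                 se_x=rng.uniform(0.001, 0.005, 10))
        a = weighted_median(frame, n_boot=200, seed=42)
        b = weighted_median(frame, n_boot=200, seed=42)
        assert a.se == b.se

    def test_robust_to_forty_percent_invalid_instruments(self, rng):
        """60% valid instruments at theta = 0.3 plus 40% with large
        pleiotropy: the weighted median stays near 0.3 while IVW drifts."""
        wm_est, ivw_est = [], []
        for i in range(40):
            r = np.random.default_rng(1000 + i)
            bx = r.uniform(0.05, 0.15, 30)
            pleio = np.where(np.arange(30) < 12, 0.05, 0.0)
            se_y = np.full(30, 0.002)
            by = 0.3 * bx + pleio + r.normal(0, se_y)
            frame = instrument_frame(bx, by, se_y)
            wm_est.append(weighted_median(frame, n_boot=20, seed=i).beta)
            ivw_est.append(ivw(frame).beta)
        assert np.mean(wm_est) == pytest.approx(0.3, abs=0.05)
        assert np.mean(ivw_est) - 0.3 > 0.1  # visibly biased upward


class TestInvariantProperties:
    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 2**16))
    def test_weighted_median_within_ratio_range(self, seed):
        r = np.random.default_rng(seed)
        bx = r.uniform(0.05, 0.3, 8)
        by = r.normal(0, 0.1, 8)
        se_y = r.uniform(0.005, 0.05, 8)
        est = WeightedMedianEstimator(n_boot=10, random_state=0).fit(
            bx, by, se_outcome=se_y)
        ratios = by / bx
        assert ratios.min() - 1e-12 <= est.beta_ <= ratios.max() + 1e-12

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 2**16))
    def test_estimators_equivariant_under_outcome_negation(self, seed):
        r = np.random.default_rng(seed)
        frame = instrument_frame(r.uniform(0.05, 0.3, 10),
                                 r.normal(0, 0.1, 10),
                                 r.uniform(0.005, 0.05, 10))
        neg = frame.copy()
        neg["beta_outcome"] *= -1
        assert ivw(neg).beta == pytest.approx(-ivw(frame).beta, rel=1e-12)
        assert mr_egger(neg).beta == pytest.approx(-mr_egger(frame).beta, rel=1e-9)
        assert (weighted_median(neg, n_boot=10).beta
                == pytest.approx(-weighted_median(frame, n_boot=10).beta, rel=1e-9))


class TestScan:
    def test_panel_scan_flags_and_determinism(self):
        cfg = GwasSimConfig(n_snps=80, seed=31, palindromic_fraction=0.0,
                            outcome_n=200_000)
        exp, panel = simulate_gwas_panel(cfg, {"hit": -0.17, "null": 0.0})
        panel["null_copy"] = panel["null"].copy()
        scan = mr_scan(exp, panel, threshold=1e-3, n_boot=50, seed=1)
        assert set(scan["method"]) == {"IVW", "Egger", "weighted_median"}
        byname = scan[scan["method"] == "IVW"].set_index("metabolite")
        assert byname.loc["hit", "significant"]
        assert byname.loc["null_copy", "beta"] == byname.loc["null", "beta"]

    def test_failures_logged_not_raised(self):
        cfg = GwasSimConfig(n_snps=10, seed=32)
        exp, panel = simulate_gwas_panel(cfg, {"ok": 0.1})
        broken = panel["ok"].copy()
        broken["snp"] = [f"zz{i}" for i in range(len(broken))]  # no overlap
        panel["broken"] = broken
        scan = mr_scan(exp, panel, n_boot=20)
        errs = scan[scan["metabolite"] == "broken"]
        assert (errs["error"] != "").all()
        assert (scan[scan["metabolite"] == "ok"]["error"] == "").all()
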