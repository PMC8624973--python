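"""Single-study association engine and pre-meta variant QC."""
import numpy as np
import pandas as pd
import pytest

from steroidmr.assoc import TraitSpec, prepare_trait, run_association, variant_qc
from steroidmr.config import AnalysisConfig, ConfigError
from conftest import make_sumstats


def _cohort(n, rng, n_variants=1, eaf=0.3):
    df = pd.DataFrame({
        "ID": [str(i) for i in range(n)],
        "SEX": rng.choice(["male", "female"], n),
        "AGE": rng.normal(60, 8, n),
        "BMI": np.exp(rng.normal(np.log(28), 0.15, n)),
    })
    for j in range(n_variants):
        df[f"g{j}"] = rng.binomial(2, eaf, n).astype(float)
    return df


class TestPrepareTrait:
    def test_log_closed_forms(self):
        spec = TraitSpec("t")
        vals, mask = prepare_trait([1.0, np.e, np.e**2], spec)
        assert vals == pytest.approx([0.0, 1.0, 2.0])
        assert mask.all()

    def test_ratio_trait_from_study_median(self):
        # testosterone/estradiol ratio of 230.0 on the natural-log scale
        vals, _ = prepare_trait([230.0], TraitSpec("T/E2"))
        assert vals[0] == pytest.approx(5.438, abs=5e-4)

    def test_nonpositive_masked_with_warning(self):
        with pytest.warns(UserWarning, match="non-positive"):
            vals, mask = prepare_trait([2.0, 0.0, -1.0], TraitSpec("t"))
        assert list(mask) == [True, False, False]

    def test_none_transform_passthrough(self):
        vals, mask = prepare_trait([-3.0, 2.0], TraitSpec("t", transform="none"))
        assert list(vals) == [-3.0, 2.0] and mask.all()


class TestRunAssociation:
    def test_noiseless_fit_recovers_slope(self, rng):
        cohort = _cohort(200, rng)
        cohort["t"] = np.exp(0.5 * cohort["g0"])
        res = run_association(cohort, TraitSpec("t", covariates=()), ["g0"])
        assert res.loc[0, "BETA"] == pytest.approx(0.5, abs=1e-12)
        assert res.loc[0, "P"] < 1e-100

    def test_six_subject_fixture_matches_normal_equations(self):
        """beta/SE equal the hand-solved OLS normal equations."""
        g = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])
        age = np.array([50.0, 55.0, 60.0, 65.0, 70.0, 75.0])
        y = np.array([0.1, 0.5, 0.8, 0.2, 0.65, 1.1])
        cohort = pd.DataFrame({
            "ID": list("abcdef"), "SEX": ["male"] * 6, "AGE": age,
            "BMI": [25.0] * 6, "t": np.exp(y), "g0": g})
        res = run_association(cohort, TraitSpec("t", covariates=("age",)), ["g0"],
                              min_cases=6)
        # independent oracle: explicit normal equations
        X = np.column_stack([np.ones(6), g, age])
        coef = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ coef
        sigma2 = resid @ resid / (6 - 3)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert res.loc[0, "BETA"] == pytest.approx(coef[1], rel=1e-10)
        assert res.loc[0, "SE"] == pytest.approx(se, rel=1e-10)

    def test_statsmodels_oracle_agreement(self, rng):
        import statsmodels.api as sm

        cohort = _cohort(500, rng)
        cohort["t"] = np.exp(0.1 * cohort["g0"] + rng.normal(0, 1, 500))
        res = run_association(cohort, TraitSpec("t"), ["g0"], "combined")
        X = sm.add_constant(np.column_stack([
            cohort["g0"], cohort["AGE"], np.log(cohort["BMI"]),
            (cohort["SEX"] == "male").astype(float)]))
        fit = sm.OLS(np.log(cohort["t"]), X).fit()
        assert res.loc[0, "BETA"] == pytest.approx(fit.params[1], rel=1e-10)
        assert res.loc[0, "SE"] == pytest.approx(fit.bse[1], rel=1e-10)
        assert res.loc[0, "P"] == pytest.approx(fit.pvalues[1], rel=1e-8)

    def test_permutation_null_betas_small(self, rng):
        """Permuted traits are within 3 SE of zero in >= 99% of permutations."""
        cohort = _cohort(2000, rng)
        y = rng.normal(0, 1, 2000)
        g = cohort["g0"].to_numpy()
        X = np.column_stack([np.ones(2000), g])
        XtX_inv = np.linalg.inv(X.T @ X)
        hits = 0
        n_perm = 1000
        for _ in range(n_perm):
            yp = rng.permutation(y)
            coef = XtX_inv @ (X.T @ yp)
            resid = yp - X @ coef
            se = np.sqrt(resid @ resid / (2000 - 2) * XtX_inv[1, 1])
            hits += abs(coef[1]) < 3 * se
        assert hits / n_perm >= 0.99

    def test_frisch_waugh_residualization(self, rng):
        """Multivariate slope equals the slope after covariate residualization."""
        cohort = _cohort(800, rng)
        cohort["t"] = np.exp(0.2 * cohort["g0"] + 0.01 * cohort["AGE"]
                             + rng.normal(0, 0.5, 800))
        res = run_association(cohort, TraitSpec("t", covariates=("age", "log_bmi")),
                              ["g0"])
        C = np.column_stack([np.ones(800), cohort["AGE"], np.log(cohort["BMI"])])
        proj = C @ np.linalg.solve(C.T @ C, C.T)
        y_r = np.log(cohort["t"]) - proj @ np.log(cohort["t"])
        g_r = cohort["g0"] - proj @ cohort["g0"]
        slope = (g_r @ y_r) / (g_r @ g_r)
        assert res.loc[0, "BETA"] == pytest.approx(slope, abs=1e-10)

    def test_trait_scaling_scales_beta_and_se(self, rng):
        cohort = _cohort(300, rng)
        base = 0.2 * cohort["g0"] + rng.normal(0, 1, 300)
        cohort["t"] = base
        res1 = run_association(cohort, TraitSpec("t", "none", ()), ["g0"])
        cohort["t"] = 2.5 * base
        res2 = run_association(cohort, TraitSpec("t", "none", ()), ["g0"])
        assert res2.loc[0, "BETA"] == pytest.approx(2.5 * res1.loc[0, "BETA"], rel=1e-12)
        assert res2.loc[0, "SE"] == pytest.approx(2.5 * res1.loc[0, "SE"], rel=1e-12)

    def test_monomorphic_variant_skipped(self, rng):
        cohort = _cohort(100, rng)
        cohort["g0"] = 1.0
        cohort["t"] = rng.normal(5, 1, 100) + 10
        with pytest.warns(UserWarning, match="monomorphic"):
            res = run_association(cohort, TraitSpec("t", covariates=()), ["g0"])
        assert len(res) == 0

    def test_sex_never_covariate_when_stratified(self, rng):
        cohort = _cohort(400, rng)
        cohort["t"] = np.exp(rng.normal(0, 1, 400))
        res = run_association(cohort, TraitSpec("t"), ["g0"], "male")
        assert (res["N"] == (cohort["SEX"] == "male").sum()).all()

    def test_too_few_cases_raises(self, rng):
        cohort = _cohort(20, rng)
        cohort["t"] = np.exp(rng.normal(0, 1, 20))
        with pytest.raises(ConfigError, match="complete cases"):
            run_association(cohort, TraitSpec("t", covariates=()), ["g0"])

    def test_mac_from_expected_dosage(self, rng):
        cohort = _cohort(100, rng, eaf=0.2)
        cohort["t"] = rng.normal(1, 0.1, 100) + 5
        res = run_association(cohort, TraitSpec("t", "none", ()), ["g0"])
        dose = cohort["g0"].sum()
        assert res.loc[0, "MAC"] == round(min(dose, 200 - dose))


REFERENCE = pd.DataFrame({
    "SNP": [f"rs{i}" for i in range(1, 10)],
    "BP": [1000 + i for i in range(9)],
    "EA": ["A"] * 9, "OA": ["G"] * 9,
    "AF": [0.3, 0.3, 0.3, 0.3, 0.69, 0.3, 0.3, 0.69, 0.3],
})


class TestVariantQC:
    def test_seven_variant_fixture(self):
        """One clean survivor; five distinct reason codes across six exclusions."""
        df = make_sumstats([
            {},                                        # rs1 clean
            {"EAF": 0.005},                            # rs2 low MAF
            {"INFO": 0.4},                             # rs3 low info
            {"MAC": 6},                                # rs4 low MAC
            {"EAF": 0.95},                             # rs5 AF deviation vs ref 0.69
            {"EA": "C", "OA": "T"},                    # rs6 allele mismatch
            {"BP": 999999},                            # rs7 position mismatch
        ])
        kept, ledger = variant_qc(df, REFERENCE)
        assert list(kept["SNP"]) == ["rs1"]
        assert len(ledger) == 6
        assert set(ledger["REASON"]) == {"LOW_MAF", "LOW_INFO", "LOW_MAC",
                                         "AF_DEVIATION", "MISMATCH"}

    def test_af_deviation_boundary_is_strict(self):
        # deviation of exactly 0.19 <= 0.2 stays in
        df = make_sumstats([{"SNP": "rs5", "BP": 1004, "EAF": 0.50}])
        kept, ledger = variant_qc(df, REFERENCE)
        assert list(kept["SNP"]) == ["rs5"]
        df = make_sumstats([{"SNP": "rs5", "BP": 1004, "EAF": 0.40}])
        kept, ledger = variant_qc(df, REFERENCE)  # deviation 0.29 > 0.2
        assert list(ledger["REASON"]) == ["AF_DEVIATION"]

    def test_mac_boundary(self):
        kept, ledger = variant_qc(make_sumstats([{"MAC": 6}]), REFERENCE)
        assert list(ledger["REASON"]) == ["LOW_MAC"]
        kept, ledger = variant_qc(make_sumstats([{"MAC": 7}]), REFERENCE)
        assert len(kept) == 1 and len(ledger) == 0

    def test_reference_allele_swap_uses_flipped_frequency(self):
        ref = pd.DataFrame({"SNP": ["rs1"], "BP": [1000], "EA": ["G"], "OA": ["A"],
                            "AF": [0.7]})
        kept, ledger = variant_qc(make_sumstats([{"EAF": 0.3}]), ref)
        assert len(kept) == 1  # study EAF 0.3 vs flipped ref 0.3

    def test_order_independent_membership(self, rng):
        df = make_sumstats([
            {}, {"EAF": 0.005}, {"INFO": 0.4}, {"MAC": 6},
            {"EAF": 0.95}, {"EA": "C", "OA": "T"}, {"BP": 999999},
        ])
        kept1, _ = variant_qc(df, REFERENCE)
        shuffled = df.sample(frac=1, random_state=7).reset_index(drop=True)
        kept2, _ = variant_qc(shuffled, REFERENCE)
        assert set(kept1["SNP"]) == set(kept2["SNP"])
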