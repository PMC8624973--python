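"""Instrument selection, ratio/IVW estimation, OR conversion, MR FDR."""
import itertools

import numpy as np
import pandas as pd
import pytest

from steroidmr.config import AnalysisConfig, ConfigError
from steroidmr.interaction import hierarchical_fdr
from steroidmr.meta import fixed_effect_meta
from steroidmr.mr import (CausalEstimate, causal_interaction_test,
                          estimate_causal_effect, explained_variance, ivw_combine,
                          mr_fdr, or_to_beta, ratio_estimate, select_instruments)
from conftest import make_sumstats


class TestSelectInstruments:
    def _tables(self):
        exposure = make_sumstats([
            {"SNP": "rs1", "P": 1e-9, "BETA": 0.2},
            {"SNP": "rs2", "P": 1e-8, "BETA": 0.18},
            {"SNP": "rs3", "P": 1e-10, "BETA": 0.3, "CHR": "2"},
            {"SNP": "rs4", "P": 1e-3, "BETA": 0.05},
        ])
        outcome = make_sumstats([
            {"SNP": "rs1", "BETA": 0.02},
            {"SNP": "rs2", "BETA": 0.015},
            {"SNP": "rs3", "BETA": 0.04, "CHR": "2"},
            {"SNP": "rs4", "BETA": 0.01},
        ])
        loci = {"rs1": "L1", "rs2": "L1", "rs3": "L2", "rs4": "L3"}
        return exposure, outcome, loci

    def test_best_snp_per_locus(self):
        exposure, outcome, loci = self._tables()
        inst = select_instruments(exposure, outcome, loci)
        assert [i.variant_id for i in inst] == ["rs3", "rs1"]  # rs2 loses L1, rs4 fails p

    def test_next_best_when_outcome_missing(self):
        exposure, outcome, loci = self._tables()
        outcome = outcome[outcome["SNP"] != "rs1"]
        inst = select_instruments(exposure, outcome, loci)
        assert "rs2" in [i.variant_id for i in inst]
        assert "rs1" not in [i.variant_id for i in inst]

    def test_ld_pruning_chain_matches_exhaustive_search(self):
        exposure = make_sumstats([
            {"SNP": "rs1", "P": 1e-12, "BETA": 0.3},
            {"SNP": "rs2", "P": 1e-10, "BETA": 0.25},
            {"SNP": "rs3", "P": 1e-9, "BETA": 0.2},
        ])
        outcome = make_sumstats([{"SNP": f"rs{i}"} for i in (1, 2, 3)])
        loci = {"rs1": "L1", "rs2": "L2", "rs3": "L3"}
        ld = pd.DataFrame({"SNP_A": ["rs1", "rs2", "rs1"],
                           "SNP_B": ["rs2", "rs3", "rs3"],
                           "R2": [0.5, 0.5, 0.25]})
        inst = select_instruments(exposure, outcome, loci, ld_r2=ld)
        kept = {i.variant_id for i in inst}
        assert kept == {"rs1"}
        # exhaustive oracle: all pairwise-valid subsets, best p greedy choice
        r2 = {frozenset(("rs1", "rs2")): 0.5, frozenset(("rs2", "rs3")): 0.5,
              frozenset(("rs1", "rs3")): 0.25}
        valid = [set(sub) for k in range(1, 4)
                 for sub in itertools.combinations(["rs1", "rs2", "rs3"], k)
                 if all(r2[frozenset(p)] < 0.1
                        for p in itertools.combinations(sub, 2))]
        assert kept in valid
        assert max(len(s) for s in valid) == len(kept)  # kept set is maximal

    def test_plausible_gene_mode_restricts(self):
        exposure, outcome, loci = self._tables()
        genes = {"rs1": ("CYP21A2", 10.0), "rs3": ("FARGENE", 400.0)}
        inst = select_instruments(exposure, outcome, loci, mode="plausible-gene",
                                  plausible_genes=genes)
        assert [i.variant_id for i in inst] == ["rs1"]  # rs3 beyond 250 kb

    def test_strong_mode_requires_explained_variance(self):
        exposure, outcome, loci = self._tables()
        # rs1: 2*0.3*0.7*0.2^2 = 0.0168 passes; shrink its beta to fail
        exposure.loc[exposure["SNP"] == "rs1", "BETA"] = 0.01
        exposure.loc[exposure["SNP"] == "rs2", "BETA"] = 0.01
        inst = select_instruments(exposure, outcome, loci, mode="strong")
        assert [i.variant_id for i in inst] == ["rs3"]
        assert explained_variance(0.3, 0.01) < 0.001 < explained_variance(0.3, 0.2)

    def test_empty_set_when_nothing_significant(self):
        exposure, outcome, loci = self._tables()
        inst = select_instruments(exposure, outcome, loci, p_cutoff=1e-20)
        assert inst == []
        assert estimate_causal_effect(inst) is None


class TestRatioAndIVW:
    def test_identity_instrument(self):
        est, se = ratio_estimate(1.0, 0.1, 0.07, 0.02)
        assert est == 0.07 and se == 0.02

    def test_direct_arithmetic(self):
        est, se = ratio_estimate(0.1, 0.01, 0.05, 0.02)
        assert est == pytest.approx(0.5)
        assert se == pytest.approx(0.2)

    def test_allele_flip_invariance(self):
        est1, se1 = ratio_estimate(0.1, 0.01, 0.05, 0.02)
        est2, se2 = ratio_estimate(-0.1, 0.01, -0.05, 0.02)
        assert est1 == est2 and se1 == se2

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ConfigError, match="weak"):
            ratio_estimate(0.0, 0.1, 0.05, 0.02)

    def test_single_ratio_identity(self):
        est = ivw_combine([0.5], [0.2])
        assert est.method == "ratio"
        assert est.estimate == 0.5 and est.se == 0.2

    def test_two_identical_ratios(self):
        est = ivw_combine([0.5, 0.5], [0.2, 0.2])
        assert est.method == "ivw"
        assert est.estimate == pytest.approx(0.5)
        assert est.se == pytest.approx(0.2 / np.sqrt(2))

    def test_matches_fixed_effect_meta_exactly(self):
        ratios, ses = [0.4, 0.55, 0.38], [0.1, 0.2, 0.15]
        est = ivw_combine(ratios, ses)
        ref = fixed_effect_meta(ratios, ses)
        assert est.estimate == ref.beta and est.se == ref.se and est.p == ref.p

    def test_method_consistency_enforced(self):
        with pytest.raises(ConfigError, match="inconsistent"):
            CausalEstimate("e", "o", "combined", "ivw", 0.1, 0.05, 0.04, 1)


class TestOrConversion:
    def test_unit_or_gives_zero(self):
        beta, _ = or_to_beta(1.0, 0.9, 1.1)
        assert beta == 0.0

    def test_inverse_evaluation(self):
        beta, _ = or_to_beta(np.exp(1.81), np.exp(1.0), np.exp(2.6))
        assert beta == pytest.approx(1.0, abs=1e-12)

    def test_ci_width_to_se(self):
        _, se = or_to_beta(np.exp(1.81), np.exp(0.0), np.exp(3.62))
        assert se == pytest.approx(3.62 / (2 * 1.959964 * 1.81), abs=1e-6)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ConfigError):
            or_to_beta(0.0, 0.0, 1.0)
        with pytest.raises(ConfigError):
            or_to_beta(1.0, 1.2, 1.5)


class TestCausalInteraction:
    def _est(self, value, se, stratum):
        return CausalEstimate("DHEAS", "BMI", stratum, "ratio", value, se, 0.01, 1)

    def test_equal_estimates_p_one(self):
        p = causal_interaction_test(self._est(0.1, 0.05, "male"),
                                    self._est(0.1, 0.03, "female"))
        assert p == 1.0

    def test_inverse_normal_evaluation(self):
        # SEs chosen so the difference 0.055 sits at z = 2.02
        se = 0.055 / 2.02 / np.sqrt(2)
        p = causal_interaction_test(self._est(0.106, se, "male"),
                                    self._est(0.051, se, "female"))
        assert p == pytest.approx(0.043, abs=5e-4)

    def test_missing_stratum_untestable(self):
        assert causal_interaction_test(self._est(0.1, 0.05, "male"), None) is None


class TestMrFdr:
    def _estimates(self, p_by_exposure):
        out = []
        for exp, ps in p_by_exposure.items():
            for j, p in enumerate(ps):
                out.append(CausalEstimate(exp, f"out{j}", "combined",
                                          "ratio", 0.1, 0.05, p, 1))
        return out

    def test_single_pair_significant(self):
        res = mr_fdr(self._estimates({"17-OHP": [0.001]}))
        assert res.loc[0, "SIGNIFICANT"]

    def test_all_null_nothing_called(self):
        res = mr_fdr(self._estimates({"a": [0.9, 0.9], "b": [0.9]}))
        assert not res["SIGNIFICANT"].any()

    def test_nine_exposures_match_hierarchical_engine(self):
        rng = np.random.default_rng(3)
        p_by = {f"hormone{j}": list(rng.uniform(1e-6, 1, 3)) for j in range(9)}
        ests = self._estimates(p_by)
        res = mr_fdr(ests)
        ref = hierarchical_fdr([e.p for e in ests], [e.exposure for e in ests])
        assert list(res["SIGNIFICANT"]) == list(ref["SIGNIFICANT"])
        assert np.allclose(res["Q"], ref["Q"])
        assert all(e.q is not None for e in ests)


def test_end_to_end_allele_flip_invariance():
    """Consistently flipping both tables leaves the causal estimate unchanged."""
    exposure = make_sumstats([
        {"SNP": "rs1", "P": 1e-9, "BETA": 0.2, "EAF": 0.3},
        {"SNP": "rs2", "P": 1e-8, "BETA": 0.18, "EAF": 0.25, "CHR": "2"},
    ])
    outcome = make_sumstats([
        {"SNP": "rs1", "BETA": 0.02, "EAF": 0.3},
        {"SNP": "rs2", "BETA": 0.015, "EAF": 0.25, "CHR": "2"},
    ])
    loci = {"rs1": "L1", "rs2": "L2"}
    est = estimate_causal_effect(select_instruments(exposure, outcome, loci))

    def flip(df):
        out = df.copy()
        out["EA"], out["OA"] = df["OA"], df["EA"]
        out["BETA"] = -df["BETA"]
        out["EAF"] = 1 - df["EAF"]
        return out

    est_f = estimate_causal_effect(select_instruments(flip(exposure), flip(outcome),
                                                      loci))
    assert est_f.estimate == pytest.approx(est.estimate, abs=1e-12)
    assert est_f.se == pytest.approx(est.se, abs=1e-12)
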