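"""Instrument selection, harmonization, and the MR estimator stack."""

import numpy as np
import pandas as pd
import pytest

from pleiomap import mr, synthdata
from pleiomap.synthdata import SyntheticConfig


def _sumstats(snp_ids, chrom, pos, ea, oa, eaf, beta, se, n=10_000):
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    from scipy import stats

    return pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chrom,
            "pos": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "p": 2 * stats.norm.sf(np.abs(beta / se)),
            "n": n,
        }
    )


def _harmonized(beta_exp, beta_out, se_exp=0.01, se_out=0.01):
    beta_exp = np.asarray(beta_exp, float)
    beta_out = np.asarray(beta_out, float)
    k = beta_exp.size
    return mr.HarmonizedInstruments(
        table=pd.DataFrame(
            {
                "snp_id": [f"rs{i}" for i in range(k)],
                "beta_exp": beta_exp,
                "se_exp": np.full(k, se_exp),
                "beta_out": beta_out,
                "se_out": np.full(k, se_out),
                "eaf": np.full(k, 0.3),
                "n_exp": 10_000,
                "n_out": 100_000,
            }
        )
    )


class TestSelectInstruments:
    def test_clump_removes_linked_neighbor(self):
        ld = pd.DataFrame(
            [[1.0, 0.5], [0.5, 1.0]], index=["rs1", "rs2"], columns=["rs1", "rs2"]
        )
        tab = _sumstats(["rs1", "rs2"], [1, 1], [1_000_000, 6_000_000],
                        ["A", "C"], ["G", "T"], [0.3, 0.4],
                        [0.1, 0.09], [0.01, 0.01])
        tab["p"] = [1e-10, 1e-9]
        kept = mr.select_instruments(tab, clump_kb=10_000, clump_r2=0.001, ld=ld)
        assert list(kept["snp_id"]) == ["rs1"]

    def test_different_chromosomes_both_kept(self):
        tab = _sumstats(["rs1", "rs2"], [1, 2], [1_000_000, 1_000_000],
                        ["A", "C"], ["G", "T"], [0.3, 0.4],
                        [0.1, 0.09], [0.01, 0.01])
        kept = mr.select_instruments(tab)
        assert len(kept) == 2

    def test_planted_independent_hits_all_retained(self):
        cfg = SyntheticConfig(n_regions=4, n_genes=50, mr_n_instruments=12, seed=1)
        exp, _, _ = synthdata.gen_gwas_sumstats(cfg)
        kept = mr.select_instruments(exp)
        assert len(kept) == 12

    def test_nothing_significant_empty_result(self):
        tab = _sumstats(["rs1"], [1], [100], ["A"], ["G"], [0.3], [0.01], [0.01])
        assert mr.select_instruments(tab).empty


class TestRegionPowerFilter:
    def test_threshold_counts(self):
        eligible = mr.region_power_filter({"a": 4, "b": 5, "c": 6}, min_loci=5)
        assert sorted(eligible) == ["b", "c"]

    def test_all_zero_empty(self):
        assert mr.region_power_filter({"a": 0, "b": 0}) == []


class TestHarmonize:
    def test_swapped_alleles_flip_sign(self):
        exp = _sumstats(["rs1"], [1], [100], ["A"], ["G"], [0.3], [0.1], [0.01])
        out = _sumstats(["rs1"], [1], [100], ["G"], ["A"], [0.7], [0.2], [0.02])
        h = mr.harmonize(exp, out)
        assert h.table["beta_out"].iloc[0] == pytest.approx(-0.2)

    def test_strand_flip_resolved(self):
        exp = _sumstats(["rs1"], [1], [100], ["A"], ["G"], [0.3], [0.1], [0.01])
        out = _sumstats(["rs1"], [1], [100], ["T"], ["C"], [0.3], [0.2], [0.02])
        h = mr.harmonize(exp, out)
        assert h.table["beta_out"].iloc[0] == pytest.approx(0.2)

    def test_ambiguous_palindromic_dropped(self):
        exp = _sumstats(["rs1"], [1], [100], ["A"], ["T"], [0.5], [0.1], [0.01])
        out = _sumstats(["rs1"], [1], [100], ["A"], ["T"], [0.5], [0.2], [0.02])
        h = mr.harmonize(exp, out)
        assert h.n_snps == 0
        assert "palindromic" in h.exclusions["reason"].iloc[0]

    def test_matched_alleles_unchanged(self):
        exp = _sumstats(["rs1"], [1], [100], ["A"], ["G"], [0.3], [0.1], [0.01])
        out = _sumstats(["rs1"], [1], [100], ["A"], ["G"], [0.3], [0.2], [0.02])
        h = mr.harmonize(exp, out)
        assert h.table["beta_out"].iloc[0] == pytest.approx(0.2)

    def test_irreconcilable_alleles_logged_not_fatal(self):
        exp = _sumstats(["rs1", "rs2"], [1, 1], [100, 200], ["A", "A"],
                        ["G", "G"], [0.3, 0.3], [0.1, 0.1], [0.01, 0.01])
        out = _sumstats(["rs1", "rs2"], [1, 1], [100, 200], ["A", "A"],
                        ["C", "G"], [0.3, 0.3], [0.2, 0.2], [0.02, 0.02])
        h = mr.harmonize(exp, out)
        assert h.n_snps == 1
        assert len(h.exclusions) == 1


class TestIvw:
    def test_constant_ratio_toy_exact(self):
        h = _harmonized([0.1, 0.2, 0.3], [0.026, 0.052, 0.078], se_out=0.01)
        est = mr.ivw(h)
        assert est.beta == pytest.approx(0.26, abs=1e-12)
        assert est.Q == pytest.approx(0.0, abs=1e-20)

    def test_single_degree_of_freedom_equals_wald_ratio(self):
        h = _harmonized([0.1, 0.25], [0.03, 0.075])
        est = mr.ivw(h)
        assert est.beta == pytest.approx(0.3, abs=1e-12)

    def test_allele_flip_invariance(self):
        rng = np.random.default_rng(0)
        bx = rng.uniform(0.05, 0.1, size=20)
        by = 0.2 * bx + rng.normal(scale=0.01, size=20)
        est1 = mr.ivw(_harmonized(bx, by))
        flip = rng.random(20) < 0.5
        bx2, by2 = bx.copy(), by.copy()
        bx2[flip] *= -1
        by2[flip] *= -1
        est2 = mr.ivw(_harmonized(bx2, by2))
        assert est1.beta == pytest.approx(est2.beta, abs=1e-12)
        assert est1.Q == pytest.approx(est2.Q, abs=1e-10)

    def test_q_nonnegative_and_random_effects_inflation(self):
        rng = np.random.default_rng(5)
        bx = rng.uniform(0.05, 0.1, size=30)
        by = 0.2 * bx + rng.normal(scale=0.05, size=30)  # overdispersed
        est = mr.ivw(_harmonized(bx, by, se_out=0.01))
        assert est.Q > 29
        fixed_se = 1.0 / np.sqrt(np.sum(bx**2 / 0.01**2))
        assert est.se > fixed_se

    def test_too_few_instruments_rejected(self):
        with pytest.raises(ValueError):
            mr.ivw(_harmonized([0.1], [0.02]))


class TestEgger:
    def test_constant_ratios_slope_equals_ivw_intercept_zero(self):
        h = _harmonized([0.1, 0.2, 0.3, 0.15], np.array([0.1, 0.2, 0.3, 0.15]) * 0.4)
        e = mr.egger(h)
        assert e.beta == pytest.approx(0.4, abs=1e-10)
        assert e.egger_intercept == pytest.approx(0.0, abs=1e-12)

    def test_planted_directional_pleiotropy_detected(self):
        rng = np.random.default_rng(7)
        bx = rng.uniform(0.03, 0.1, size=200)
        by = 0.2 * bx + 0.05 + rng.normal(scale=0.005, size=200)
        e = mr.egger(_harmonized(bx, by, se_out=0.005))
        assert e.egger_intercept == pytest.approx(0.05, abs=0.01)
        assert e.egger_intercept_p < 0.001

    def test_orientation_invariance(self):
        rng = np.random.default_rng(8)
        bx = rng.uniform(0.05, 0.1, size=30)
        by = 0.3 * bx + rng.normal(scale=0.01, size=30)
        e1 = mr.egger(_harmonized(bx, by))
        flip = rng.random(30) < 0.5
        bx2, by2 = bx.copy(), by.copy()
        bx2[flip] *= -1
        by2[flip] *= -1
        e2 = mr.egger(_harmonized(bx2, by2))
        assert e1.beta == pytest.approx(e2.beta, abs=1e-12)


class TestWeightedMedian:
    def test_constant_ratio_exact(self):
        h = _harmonized([0.1, 0.2, 0.3], [0.05, 0.1, 0.15])
        est = mr.weighted_median(h, n_boot=200, seed=0)
        assert est.beta == pytest.approx(0.5, abs=1e-12)

    def test_robust_to_minority_contamination(self):
        rng = np.random.default_rng(9)
        bx = rng.uniform(0.05, 0.1, size=30)
        by = 0.25 * bx + rng.normal(scale=0.002, size=30)
        by[:10] += 0.08  # 1/3 of instruments biased upward
        h = _harmonized(bx, by, se_out=0.002)
        wm = mr.weighted_median(h, n_boot=200, seed=0)
        est_ivw = mr.ivw(h)
        assert abs(wm.beta - 0.25) < abs(est_ivw.beta - 0.25)
        assert wm.beta == pytest.approx(0.25, abs=0.05)

    def test_concentrated_weight_returns_that_ratio(self):
        h = _harmonized([0.1, 0.1, 0.1], [0.02, 0.05, 0.09])
        # essentially all ratio weight on rs1 (ratio 0.5)
        h.table.loc[1, "se_out"] = 1e-6
        h.table.loc[1, "se_exp"] = 1e-6
        est = mr.weighted_median(h, n_boot=200, seed=0)
        assert est.beta == pytest.approx(0.5, abs=0.01)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(10)
        bx = rng.uniform(0.05, 0.1, size=15)
        by = 0.2 * bx + rng.normal(scale=0.01, size=15)
        h = _harmonized(bx, by)
        e1 = mr.weighted_median(h, n_boot=300, seed=4)
        e2 = mr.weighted_median(h, n_boot=300, seed=4)
        assert e1.beta == e2.beta and e1.se == e2.se


class TestSteigerFilter:
    def test_forward_instrument_retained_reverse_dropped(self):
        h = _harmonized([0.10, 0.02], [0.02, 0.10])
        filtered = mr.steiger_filter(h, n_exp=10_000, n_out=10_000)
        assert list(filtered.table["snp_id"]) == ["rs0"]
        assert "Steiger" in filtered.exclusions["reason"].iloc[-1]

    def test_forward_causal_synthetic_mostly_retained(self):
        cfg = SyntheticConfig(n_regions=4, n_genes=50, mr_n_instruments=60, seed=12)
        exp, out, _ = synthdata.gen_gwas_sumstats(cfg)
        h = mr.harmonize(exp, out)
        filtered = mr.steiger_filter(h)
        assert filtered.n_snps >= 0.95 * h.n_snps

    def test_missing_sample_sizes_skips_with_warning(self):
        h = _harmonized([0.1, 0.2], [0.02, 0.04])
        h.table["n_exp"] = None
        with pytest.warns(UserWarning, match="Steiger"):
            out = mr.steiger_filter(h)
        assert out.n_snps == 2


class TestMrPanel:
    @staticmethod
    def _panel_inputs(n_null=8, seed=0):
        exposures = {}
        outcome = None
        causal_cfg = SyntheticConfig(n_regions=4, n_genes=50, mr_causal_beta=0.3,
                                     mr_n_instruments=30, seed=seed)
        exp, out, _ = synthdata.gen_gwas_sumstats(causal_cfg)
        exposures["causal"] = exp
        outcomes = {"causal": out}
        for i in range(n_null):
            cfg = SyntheticConfig(n_regions=4, n_genes=50, mr_causal_beta=0.0,
                                  mr_n_instruments=30, seed=seed + 100 + i)
            e, o, _ = synthdata.gen_gwas_sumstats(cfg)
            exposures[f"null{i}"] = e
            outcomes[f"null{i}"] = o
        return exposures, outcomes

    def test_planted_causal_region_flagged(self):
        exposures, outcomes = self._panel_inputs(seed=3)
        # per-region outcomes: run each region separately, collect panel rows
        rows = []
        for region, exp in exposures.items():
            panel = mr.mr_panel({region: exp}, outcomes[region], seed=0)
            rows.append(panel.iloc[0])
        panel = pd.DataFrame(rows).reset_index(drop=True)
        from pleiomap._utils import bh_fdr

        ok = panel["status"] == "ok"
        panel.loc[ok, "q_ivw"] = bh_fdr(panel.loc[ok, "p_ivw"].to_numpy())
        sig = panel.loc[panel["q_ivw"] < 0.05, "region_id"]
        assert "causal" in set(sig)
        assert len(sig) <= 2

    def test_underpowered_region_skipped(self):
        cfg = SyntheticConfig(n_regions=4, n_genes=50, mr_n_instruments=30, seed=5)
        exp, out, _ = synthdata.gen_gwas_sumstats(cfg)
        weak = exp.copy()
        weak["p"] = 0.5  # nothing genome-wide significant
        panel = mr.mr_panel({"weak": weak, "strong": exp}, out, seed=0)
        status = panel.set_index("region_id")["status"]
        assert status["weak"] == "underpowered"
        assert status["strong"] == "ok"

    def test_sensitivity_concordance_flag_present(self):
        cfg = SyntheticConfig(n_regions=4, n_genes=50, mr_causal_beta=0.3,
                              mr_n_instruments=40, seed=6)
        exp, out, _ = synthdata.gen_gwas_sumstats(cfg)
        panel = mr.mr_panel({"r": exp}, out, seed=0)
        assert bool(panel["sign_concordant"].iloc[0])
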