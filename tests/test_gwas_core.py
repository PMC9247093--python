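"""Association core: HWE, QC, scan, clumping, inflation, thresholds."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from depotgene import gwas_core as gc
from depotgene.errors import DataError
from depotgene.synthetic_data import simulate_clump_scenario


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def _hwe_enumeration_oracle(n_het, n_hom1, n_hom2):
    """Exact two-sided HWE p by full enumeration with rational arithmetic."""
    n = n_het + n_hom1 + n_hom2
    rare = 2 * min(n_hom1, n_hom2) + n_het
    if rare == 0:
        return 1.0
    f = math.factorial

    def prob(h):
        nr = (rare - h) // 2
        nc = n - h - nr
        if nr < 0 or nc < 0:
            return Fraction(0)
        return Fraction(
            f(n) * f(rare) * f(2 * n - rare) * 2**h, f(nr) * f(nc) * f(h) * f(2 * n)
        )

    probs = {h: prob(h) for h in range(rare % 2, rare + 1, 2)}
    p_obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestHweExact:
    @pytest.mark.parametrize(
        "het,hom1,hom2",
        [(0, 5, 5), (2, 4, 4), (10, 0, 0), (5, 10, 1), (1, 49, 0), (14, 20, 3)],
    )
    def test_matches_enumeration_oracle(self, het, hom1, hom2):
        assert gc.hwe_exact_pvalue(het, hom1, hom2) == pytest.approx(
            _hwe_enumeration_oracle(het, hom1, hom2), rel=1e-9
        )

    def test_monomorphic_is_one(self):
        assert gc.hwe_exact_pvalue(0, 100, 0) == 1.0


class TestVariantQc:
    def test_monomorphic_removed_by_maf_with_hwe_one(self):
        geno = pd.DataFrame({"rs1": np.zeros(200)})
        rep = gc.variant_qc_common(geno, mode="array")
        assert not rep["keep"].iloc[0]
        assert rep["drop_reason"].iloc[0] == "maf"
        assert rep["hwe_p"].iloc[0] == 1.0

    def test_low_call_rate_removed_in_array_mode(self):
        rng = np.random.default_rng(0)
        dos = rng.binomial(2, 0.3, 500).astype(float)
        dos[:10] = np.nan  # 2% missing
        rep = gc.variant_qc_common(pd.DataFrame({"rs1": dos}), mode="array")
        assert rep["drop_reason"].iloc[0] == "call_rate"

    def test_imputed_mode_filters_maf_and_info(self):
        rng = np.random.default_rng(1)
        geno = pd.DataFrame(
            {
                "common_good": rng.binomial(2, 0.3, 400).astype(float),
                "rare": rng.binomial(2, 0.001, 400).astype(float),
                "low_info": rng.binomial(2, 0.3, 400).astype(float),
            }
        )
        info = pd.Series({"common_good": 0.99, "rare": 0.99, "low_info": 0.1})
        rep = gc.variant_qc_common(geno, mode="imputed", info=info).set_index("SNP")
        assert rep.loc["common_good", "keep"]
        assert rep.loc["rare", "drop_reason"] == "maf"
        assert rep.loc["low_info", "drop_reason"] == "info"

    def test_out_of_range_dosage_rejected(self):
        with pytest.raises(DataError):
            gc.variant_qc_common(pd.DataFrame({"rs1": [0.0, 2.5, 1.0] * 10}))


# ---------------------------------------------------------------------------
# association scan
# ---------------------------------------------------------------------------


class TestAssociationScan:
    def test_exact_linear_trait_flagged_degenerate(self):
        rng = np.random.default_rng(2)
        dos = rng.binomial(2, 0.4, 100).astype(float)
        res = gc.association_scan(pd.DataFrame({"rs1": dos}), dos * 1.0)
        assert res["BETA"].iloc[0] == pytest.approx(1.0)
        assert res["SE"].iloc[0] < 1e-6
        assert res["degenerate"].iloc[0]

    def test_matches_closed_form_simple_regression(self):
        # tiny scan checked against hand normal equations (no covariates)
        dos = np.array([0.0, 1.0, 2.0, 1.0, 0.0] * 6)
        rng = np.random.default_rng(3)
        y = 0.5 * dos + rng.normal(0, 1, 30)
        res = gc.association_scan(pd.DataFrame({"rs1": dos}), y)
        xc = dos - dos.mean()
        yc = y - y.mean()
        beta = (xc @ yc) / (xc @ xc)
        resid = yc - beta * xc
        se = np.sqrt((resid @ resid) / (30 - 2) / (xc @ xc))
        assert res["BETA"].iloc[0] == pytest.approx(beta)
        assert res["SE"].iloc[0] == pytest.approx(se)
        t = beta / se
        assert res["P"].iloc[0] == pytest.approx(2 * stats.t.sf(abs(t), 28))

    def test_recovers_planted_effect(self):
        rng = np.random.default_rng(4)
        n = 10_000
        dos = rng.binomial(2, 0.3, n).astype(float)
        y = 0.1 * dos + rng.normal(0, 1, n)
        res = gc.association_scan(pd.DataFrame({"rs1": dos}), y)
        assert abs(res["BETA"].iloc[0] - 0.1) < 3 * res["SE"].iloc[0]

    def test_missing_dosages_mean_imputed(self):
        rng = np.random.default_rng(5)
        dos = rng.binomial(2, 0.4, 200).astype(float)
        y = rng.normal(0, 1, 200)
        dos_miss = dos.copy()
        dos_miss[:20] = np.nan
        imputed = dos.copy()
        imputed[:20] = dos_miss[20:].mean()
        res_a = gc.association_scan(pd.DataFrame({"rs1": dos_miss}), y)
        res_b = gc.association_scan(pd.DataFrame({"rs1": imputed}), y)
        assert res_a["BETA"].iloc[0] == pytest.approx(res_b["BETA"].iloc[0])

    def test_null_type_one_error_within_binomial_bounds(self):
        rng = np.random.default_rng(6)
        n, m = 300, 10_000
        geno = pd.DataFrame(rng.binomial(2, 0.3, (n, m)).astype(np.int8))
        geno.columns = [f"rs{j}" for j in range(m)]
        y = rng.normal(0, 1, n)
        res = gc.association_scan(geno, y)
        rate = (res["P"] < 0.05).mean()
        half = 1.96 * np.sqrt(0.05 * 0.95 / m)
        assert 0.05 - half < rate < 0.05 + half


# ---------------------------------------------------------------------------
# LD clumping
# ---------------------------------------------------------------------------


def _naive_clump(stats_df, ld_long, cfg):
    """Independent brute-force clumping reference."""
    r2 = {}
    for _, row in ld_long.iterrows():
        r2[(row["snp_a"], row["snp_b"])] = row["r2"]
        r2[(row["snp_b"], row["snp_a"])] = row["r2"]
    recs = sorted(
        stats_df.to_dict("records"), key=lambda r: (r["P"], r["CHR"], r["BP"])
    )
    unassigned = {r["SNP"] for r in recs}
    result = []
    while True:
        lead = next(
            (r for r in recs if r["SNP"] in unassigned and r["P"] < cfg.p1), None
        )
        if lead is None:
            break
        unassigned.discard(lead["SNP"])
        members = []
        for r in recs:
            if (
                r["SNP"] in unassigned
                and r["P"] < cfg.p2
                and r["CHR"] == lead["CHR"]
                and abs(r["BP"] - lead["BP"]) <= cfg.window_kb * 1000
                and r2.get((lead["SNP"], r["SNP"]), 0.0) > cfg.r2
            ):
                members.append(r["SNP"])
                unassigned.discard(r["SNP"])
        result.append((lead["SNP"], sorted(members)))
    return result


class TestLdClump:
    def test_single_significant_snp_is_lone_locus(self):
        stats_df = pd.DataFrame({"CHR": [1], "BP": [100], "SNP": ["rs1"], "P": [1e-9]})
        loci = gc.ld_clump(stats_df, gc.LdTable({}, {"rs1"}))
        assert len(loci) == 1 and loci[0].members == []

    def test_hand_traced_three_snp_case(self):
        stats_df = pd.DataFrame(
            {
                "CHR": [1, 1, 1],
                "BP": [100_000, 110_000, 500_000],
                "SNP": ["A", "B", "C"],
                "P": [1e-10, 1e-9, 1e-7],
            }
        )
        ld = gc.LdTable.from_long(
            pd.DataFrame([{"snp_a": "A", "snp_b": "B", "r2": 0.5}])
        )
        loci = gc.ld_clump(stats_df, ld)
        assert [l.lead["SNP"] for l in loci] == ["A"]
        assert loci[0].members == ["B"]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_naive_reference_on_block_ld(self, seed):
        stats_df, ld_long = simulate_clump_scenario(n_snps=200, seed=seed)
        loci = gc.ld_clump(stats_df, gc.LdTable.from_long(ld_long))
        got = [(l.lead["SNP"], sorted(l.members)) for l in loci]
        assert got == _naive_clump(stats_df, ld_long, gc.ClumpConfig())

    def test_every_significant_snp_assigned_and_leads_independent(self):
        stats_df, ld_long = simulate_clump_scenario(n_snps=200, seed=5)
        ld = gc.LdTable.from_long(ld_long)
        cfg = gc.ClumpConfig()
        loci = gc.ld_clump(stats_df, ld, cfg)
        assigned = {l.lead["SNP"] for l in loci} | {
            m for l in loci for m in l.members
        }
        sig = set(stats_df.loc[stats_df["P"] < cfg.p1, "SNP"])
        assert sig <= assigned
        pos = stats_df.set_index("SNP")["BP"]
        leads = [l.lead["SNP"] for l in loci]
        for i, a in enumerate(leads):
            for b in leads[i + 1 :]:
                assert ld.r2(a, b) <= cfg.r2 or abs(pos[a] - pos[b]) > cfg.window_kb * 1000

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            gc.ClumpConfig(p1=1e-5, p2=1e-8)


class TestNoveltyFlag:
    def setup_method(self):
        self.ld = gc.LdTable.from_long(
            pd.DataFrame(
                [
                    {"snp_a": "lead1", "snp_b": "cat1", "r2": 0.05},
                    {"snp_a": "lead2", "snp_b": "cat1", "r2": 0.10},
                ]
            )
        )

    def test_below_threshold_is_novel(self):
        rep = gc.flag_novel_loci(["lead1"], ["cat1"], self.ld)
        assert rep["status"].iloc[0] == "novel"

    def test_boundary_r2_is_known(self):
        rep = gc.flag_novel_loci(["lead2"], ["cat1"], self.ld)
        assert rep["status"].iloc[0] == "known"

    def test_empty_catalog_all_novel(self):
        rep = gc.flag_novel_loci(["lead1", "lead2"], [], self.ld)
        assert (rep["status"] == "novel").all()

    def test_unknown_lead_is_indeterminate(self):
        rep = gc.flag_novel_loci(["mystery"], ["cat1"], self.ld)
        assert rep["status"].iloc[0] == "indeterminate"


class TestGenomicInflation:
    def test_median_p_half_gives_unity(self):
        assert gc.genomic_inflation([0.5] * 200).lambda_gc == pytest.approx(1.0)

    def test_doubling_chi_square_doubles_lambda(self):
        rng = np.random.default_rng(7)
        chi2 = rng.chisquare(1, 5000)
        p1 = stats.chi2.sf(chi2, 1)
        p2 = stats.chi2.sf(2 * chi2, 1)
        l1 = gc.genomic_inflation(p1).lambda_gc
        l2 = gc.genomic_inflation(p2).lambda_gc
        assert l2 / l1 == pytest.approx(2.0, rel=1e-9)

    def test_too_few_pvalues_rejected(self):
        with pytest.raises(Exception):
            gc.genomic_inflation([0.5] * 50)


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,counts,display",
        [
            (0.05, [12_020], 4.2e-6),
            (0.05, [12_020, 27], 1.5e-7),
            (0.05, [220], 2.3e-4),
            (5e-9, [27], 1.9e-10),
        ],
    )
    def test_published_thresholds(self, alpha, counts, display):
        thr = gc.bonferroni_threshold(alpha, counts)
        assert thr.display == pytest.approx(display)
        assert thr.value == pytest.approx(alpha / np.prod(counts))

    def test_single_count_identity(self):
        assert gc.bonferroni_threshold(0.01, [1]).value == 0.01


class TestReplicationConcordance:
    @staticmethod
    def _pairs(n_concordant, n_total, rng_seed=0):
        rng = np.random.default_rng(rng_seed)
        b1 = rng.uniform(0.01, 0.2, n_total)
        b2 = b1.copy()
        b2[n_concordant:] *= -1
        return pd.DataFrame({"beta_this": b1, "beta_external": b2})

    def test_sixteen_of_seventeen(self):
        k, n, p = gc.replication_concordance(self._pairs(16, 17))
        assert (k, n) == (16, 17)
        assert float(f"{p:.1e}") == pytest.approx(2.7e-4)

    def test_even_split_is_one(self):
        assert gc.replication_concordance(self._pairs(5, 10))[2] == 1.0

    def test_total_discordance_exact_arithmetic(self):
        _, _, p = gc.replication_concordance(self._pairs(0, 10))
        assert p == pytest.approx(2 / 1024)

    def test_zero_betas_excluded(self):
        pairs = self._pairs(4, 4)
        pairs.loc[0, "beta_this"] = 0.0
        k, n, _ = gc.replication_concordance(pairs)
        assert (k, n) == (3, 3)
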