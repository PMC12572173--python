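"""MVMR direct effects, reclumping, covariance estimation, and the
difference/product mediation estimators with their filters."""

import numpy as np
import pandas as pd
import pytest

from metabomr import (InstrumentSet, MRResult, build_phenotypic_covariance,
                      clump, difference_method, ivw, mvmr_ivw,
                      overlap_iv_filter, product_method, reclump_union,
                      select_mediation_method, sign_consistency_filter)
from metabomr.harmonise import harmonise
from tests.conftest import make_sumstats


def iv_set(snp_ids):
    return InstrumentSet(index_snps=list(snp_ids), clump_audit={},
                         dropped=pd.DataFrame(columns=["snp_id", "reason"]))


def two_exposures(rng, n=12, theta=(0.3, 0.1), noise=0.0):
    """Two exposures with known direct effects on a constructed outcome."""
    b1 = rng.uniform(0.05, 0.3, n) * rng.choice([-1, 1], n)
    b2 = rng.uniform(0.05, 0.3, n) * rng.choice([-1, 1], n)
    se = np.full(n, 0.01)
    ids = [f"rs{i}" for i in range(n)]
    e1 = make_sumstats(b1, se, trait_id="e1", snp_ids=ids)
    e2 = make_sumstats(b2, se, trait_id="e2", snp_ids=ids)
    y = theta[0] * b1 + theta[1] * b2 + noise * rng.normal(0, 0.02, n)
    out = make_sumstats(y, np.full(n, 0.02), trait_id="y", snp_ids=ids)
    return e1, e2, out, ids


class TestMVMR:
    def test_exact_recovery(self):
        rng = np.random.default_rng(30)
        e1, e2, out, ids = two_exposures(rng)
        res = mvmr_ivw([e1, e2], out, iv_set(ids))
        got = dict(zip(res.effects["exposure"], res.effects["beta"]))
        assert got["e1"] == pytest.approx(0.3, abs=1e-12)
        assert got["e2"] == pytest.approx(0.1, abs=1e-12)
        assert not res.collinear

    def test_single_exposure_reduces_to_ivw_fixed(self):
        rng = np.random.default_rng(31)
        e1, _, out, ids = two_exposures(rng, noise=1.0)
        res = mvmr_ivw([e1], out, iv_set(ids))
        h = harmonise(e1, out)
        assert res.effects["beta"].iloc[0] == pytest.approx(
            ivw(h, "fixed").beta, rel=1e-10)

    def test_duplicated_exposure_collinear_and_weak(self):
        rng = np.random.default_rng(32)
        e1, _, out, ids = two_exposures(rng)
        e1b = make_sumstats(e1.df["beta"], e1.df["se"], trait_id="e1copy",
                            snp_ids=ids)
        res = mvmr_ivw([e1, e1b], out, iv_set(ids))
        assert res.collinear
        assert min(res.conditional_F.values()) < 1.0
        assert res.weak_flag

    def test_too_few_instruments(self):
        rng = np.random.default_rng(33)
        e1, e2, out, ids = two_exposures(rng, n=2)
        with pytest.raises(ValueError, match="instruments"):
            mvmr_ivw([e1, e2], out, iv_set(ids))

    def test_conditional_f_strong_design(self):
        rng = np.random.default_rng(34)
        e1, e2, out, ids = two_exposures(rng)
        res = mvmr_ivw([e1, e2], out, iv_set(ids))
        assert min(res.conditional_F.values()) > 10
        assert not res.weak_flag

    def test_planted_heterogeneity_flags_pleiotropy(self):
        rng = np.random.default_rng(35)
        e1, e2, out, ids = two_exposures(rng)
        out.df.loc[:4, "beta"] += np.array([0.3, -0.25, 0.3, -0.3, 0.25])
        res = mvmr_ivw([e1, e2], out, iv_set(ids))
        assert res.pleiotropy_flag


class TestReclumpUnion:
    def sig(self, panel, rows, pvals, trait):
        v = panel.variants.iloc[rows]
        from scipy import stats as st
        z = st.norm.isf(np.array(pvals) / 2)
        s = make_sumstats(z * 0.01, np.full(len(rows), 0.01),
                          trait_id=trait, snp_ids=v["snp_id"].tolist())
        s.df["chrom"] = v["chrom"].to_numpy()
        s.df["pos"] = v["pos"].to_numpy()
        return s

    def test_disjoint_independent_sets_union(self, panel_instr):
        a = self.sig(panel_instr, [0, 2, 4], [1e-10] * 3, "a")
        b = self.sig(panel_instr, [6, 8], [1e-9] * 2, "b")
        res = reclump_union([a, b], panel_instr)
        assert len(res.index_snps) == 5

    def test_shared_variant_ranked_by_min_pval(self, panel_ld):
        # two variants in one tight-LD block, each significant in one trait
        v = panel_ld.variants.loc[panel_ld.variants["block"] == 1]
        a = self.sig(panel_ld, [v.index[0], v.index[1]], [1e-9, 1e-20], "a")
        b = self.sig(panel_ld, [v.index[0], v.index[1]], [1e-12, 1e-9], "b")
        res = reclump_union([a, b], panel_ld)
        # min p: first variant 1e-12, second 1e-20 -> second wins the block
        assert res.index_snps == [v["snp_id"].iloc[1]]

    def test_matches_clump_on_pooled_best(self, panel_ld):
        rng = np.random.default_rng(36)
        rows = list(range(12))
        a = self.sig(panel_ld, rows, rng.uniform(1e-12, 1e-8, 12), "a")
        b = self.sig(panel_ld, rows, rng.uniform(1e-12, 1e-8, 12), "b")
        res = reclump_union([a, b], panel_ld)
        best = np.minimum(a.df["pval"].to_numpy(), b.df["pval"].to_numpy())
        merged = a.subset(np.ones(12, bool))
        merged.df["pval"] = best
        expected = clump(merged, panel_ld)
        assert res.index_snps == expected.index_snps

    def test_needs_two_traits(self, panel_instr):
        a = self.sig(panel_instr, [0], [1e-10], "a")
        with pytest.raises(ValueError):
            reclump_union([a], panel_instr)


class TestPhenotypicCovariance:
    def make_z_traits(self, rho, m=5000, seed=40):
        rng = np.random.default_rng(seed)
        z_shared = rng.standard_normal(m)
        z1 = rho * z_shared + np.sqrt(1 - rho ** 2) * rng.standard_normal(m)
        z2 = z_shared
        se = np.full(m, 0.01)
        a = make_sumstats(z1 * 0.01, se, trait_id="a",
                          snp_ids=[f"s{i}" for i in range(m)])
        b = make_sumstats(z2 * 0.01, se, trait_id="b",
                          snp_ids=[f"s{i}" for i in range(m)])
        return a, b

    def test_self_correlation_one(self):
        a, _ = self.make_z_traits(0.0, m=2000)
        c = build_phenotypic_covariance([a, a])
        assert c[0, 1] == pytest.approx(1.0)

    def test_independent_traits_near_zero(self):
        a, b = self.make_z_traits(0.0)
        c = build_phenotypic_covariance([a, b])
        assert abs(c[0, 1]) < 3 / np.sqrt(5000)

    def test_recovers_planted_correlation(self):
        a, b = self.make_z_traits(0.5)
        c = build_phenotypic_covariance([a, b])
        assert abs(c[0, 1] - 0.5) < 0.05

    def test_insufficient_overlap_identity(self):
        a, b = self.make_z_traits(0.5, m=50)
        with pytest.warns(UserWarning, match="identity"):
            c = build_phenotypic_covariance([a, b])
        assert np.allclose(c, np.eye(2))


def mr(beta, se, method="ivw_re", n=5):
    return MRResult(method=method, n_snp=n, beta=beta, se=se)


class TestMediationEstimators:
    def mvmr_stub(self, direct=0.3, se=0.02, weak=False, pleio=False):
        from metabomr.mediation import MVMRResult
        eff = pd.DataFrame({"exposure": ["bmi"], "beta": [direct],
                            "se": [se], "pval": [1e-4]})
        return MVMRResult(effects=eff,
                          conditional_F={"bmi": 5.0 if weak else 50.0},
                          modified_Q=20.0, Q_pval=0.01 if pleio else 0.5,
                          snp_ids=["rs0"] * 12)

    def test_difference_arithmetic(self):
        res = difference_method(mr(0.4, 0.02), self.mvmr_stub(0.3), "bmi")
        assert res.beta_indirect == pytest.approx(0.1)
        assert res.proportion_mediated == pytest.approx(0.25)
        assert res.se_indirect == pytest.approx(np.hypot(0.02, 0.02))
        assert res.usable

    def test_difference_direct_equals_total(self):
        res = difference_method(mr(0.4, 0.02), self.mvmr_stub(0.4), "bmi")
        assert res.beta_indirect == pytest.approx(0.0)
        assert res.proportion_mediated == pytest.approx(0.0)

    def test_difference_flags_unusable(self):
        res = difference_method(mr(0.4, 0.02), self.mvmr_stub(weak=True), "bmi")
        assert not res.usable and "weak" in res.notes
        res2 = difference_method(mr(0.4, 0.02), self.mvmr_stub(pleio=True),
                                 "bmi")
        assert not res2.usable and "pleiotropy" in res2.notes

    def test_zero_total_undefined(self):
        with pytest.raises(ZeroDivisionError):
            difference_method(mr(0.0, 0.02), self.mvmr_stub(), "bmi")

    def test_product_arithmetic(self):
        res = product_method(mr(0.5, 0.01), mr(0.2, 0.02), mr(0.4, 0.03))
        assert res.beta_indirect == pytest.approx(0.10)
        assert res.proportion_mediated == pytest.approx(0.25)
        assert res.se_indirect == pytest.approx(
            np.sqrt(0.5 ** 2 * 0.02 ** 2 + 0.2 ** 2 * 0.01 ** 2))

    def test_product_null_mediator_path(self):
        res = product_method(mr(0.5, 0.01), mr(0.0, 0.02), mr(0.4, 0.03))
        assert res.beta_indirect == 0.0
        assert res.proportion_mediated == 0.0

    def test_product_bilinear(self):
        a = product_method(mr(0.5, 0.01), mr(0.2, 0.02), mr(0.4, 0.03))
        b = product_method(mr(1.5, 0.01), mr(0.2, 0.02), mr(0.4, 0.03))
        assert b.beta_indirect == pytest.approx(3 * a.beta_indirect)

    @pytest.mark.parametrize("em,mo,total,expected", [
        (0.2, 0.3, 0.5, "keep"),
        (0.2, -0.3, 0.5, "exclude"),
        (-0.2, -0.3, 0.5, "keep"),
        (0.2, 0.3, -0.5, "exclude"),
        (0.0, 0.3, 0.5, "exclude:zero-effect"),
    ])
    def test_sign_filter(self, em, mo, total, expected):
        assert sign_consistency_filter(em, mo, total) == expected

    def test_sign_filter_nonfinite(self):
        with pytest.raises(ValueError):
            sign_consistency_filter(np.nan, 0.1, 0.1)

    def test_select_method(self):
        assert select_mediation_method(self.mvmr_stub()) == "difference"
        assert select_mediation_method(self.mvmr_stub(weak=True)) == "product"
        assert select_mediation_method(self.mvmr_stub(pleio=True)) == "product"


class TestOverlapFilter:
    def test_disjoint_chromosomes_untouched(self, panel_instr):
        v = panel_instr.variants
        chr1 = v.loc[v["chrom"] == "1", "snp_id"].tolist()[:2]
        chr3 = v.loc[v["chrom"] == "3", "snp_id"].tolist()[:2]
        e, m, audit = overlap_iv_filter(iv_set(chr1), iv_set(chr3),
                                        panel_instr, 100, 50)
        assert e.index_snps == chr1 and m.index_snps == chr3
        assert len(audit) == 0

    def test_shared_snp_removed_from_larger_n(self, panel_instr):
        s = panel_instr.variants["snp_id"].iloc[0]
        e, m, audit = overlap_iv_filter(iv_set([s]), iv_set([s]),
                                        panel_instr, n_exposure=1000,
                                        n_mediator=50)
        assert e.index_snps == [] and m.index_snps == [s]
        assert audit["removed_from"].tolist() == ["exposure"]
        # larger mediator sample: removal switches sides
        e2, m2, _ = overlap_iv_filter(iv_set([s]), iv_set([s]),
                                      panel_instr, n_exposure=50,
                                      n_mediator=1000)
        assert e2.index_snps == [s] and m2.index_snps == []

    def test_tie_removes_from_exposure(self, panel_instr):
        s = panel_instr.variants["snp_id"].iloc[0]
        e, m, _ = overlap_iv_filter(iv_set([s]), iv_set([s]), panel_instr,
                                    100, 100)
        assert e.index_snps == [] and m.index_snps == [s]

    def test_ld_pair_matches_bruteforce(self, panel_ld):
        v = panel_ld.variants.loc[panel_ld.variants["block"] == 2]
        a, b = v["snp_id"].iloc[0], v["snp_id"].iloc[3]
        assert panel_ld.r2(a, b) >= 0.01   # tight-LD block
        e, m, audit = overlap_iv_filter(iv_set([a]), iv_set([b]), panel_ld,
                                        10, 1000)
        assert len(audit) == 1
        assert m.index_snps == [] and e.index_snps == [a]
        # never removes from both sides for the same pair
        assert set(audit["removed_from"]) == {"mediator"}
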