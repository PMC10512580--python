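"""Wald ratio, IVW, MR-Egger, Bonferroni and replication."""

import math

import numpy as np
import pytest
from scipy import stats

from conftest import make_pair
from pqtlmr.mr import bonferroni, ivw, mr_egger, replicate, wald_ratio


class TestWaldRatio:
    def test_hand_computed_example(self):
        fit = wald_ratio(make_pair(0.5, -0.1, se_out=0.05))
        assert fit.beta_mr == pytest.approx(-0.2)
        assert fit.se_mr == pytest.approx(0.1)
        assert fit.or_point == pytest.approx(math.exp(-0.2), rel=1e-12)
        assert fit.or_point == pytest.approx(0.8187, abs=1e-4)

    def test_null_outcome(self):
        fit = wald_ratio(make_pair(0.5, 0.0))
        assert fit.beta_mr == 0.0 and fit.or_point == 1.0

    def test_scale_invariance(self):
        a = wald_ratio(make_pair(0.5, 0.2))
        b = wald_ratio(make_pair(1.0, 0.4))
        assert a.beta_mr == pytest.approx(b.beta_mr, rel=1e-12)

    def test_zero_exposure_beta_fatal(self):
        with pytest.raises(ZeroDivisionError, match="rs1"):
            wald_ratio(make_pair(0.0, 0.2))

    def test_ci_brackets_or(self, rng):
        for _ in range(20):
            fit = wald_ratio(make_pair(rng.uniform(0.1, 1), rng.normal(),
                                       se_out=rng.uniform(0.01, 0.5)))
            assert fit.ci_low < fit.or_point < fit.ci_high
            assert 0 < fit.pval <= 1


class TestIvw:
    def test_homogeneous_pair(self):
        pairs = [make_pair(1.0, 0.3, se_out=0.1, snp="rs1"),
                 make_pair(1.0, 0.3, se_out=0.1, snp="rs2")]
        fit = ivw(pairs)
        assert fit.beta_mr == pytest.approx(0.3)
        assert fit.se_mr == pytest.approx(0.1 / math.sqrt(2))
        assert fit.q_stat == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_two_ratios(self):
        """Ratios {0.1, 0.3} with equal ratio-SE 0.1: mean 0.2, Q = 2."""
        pairs = [make_pair(1.0, 0.1, se_out=0.1, snp="rs1"),
                 make_pair(1.0, 0.3, se_out=0.1, snp="rs2")]
        fit = ivw(pairs)
        assert fit.beta_mr == pytest.approx(0.2)
        assert fit.q_stat == pytest.approx(2.0)
        assert fit.q_pval == pytest.approx(stats.chi2.sf(2.0, 1), rel=1e-9)
        assert fit.q_pval == pytest.approx(0.1573, abs=1e-4)

    def test_equals_weighted_origin_regression(self, rng):
        """IVW == WLS of β_out on β_exp through the origin with weights 1/se_out²."""
        for _ in range(200):
            k = int(rng.integers(2, 8))
            pairs = [
                make_pair(
                    float(rng.uniform(0.05, 1.0) * rng.choice([-1, 1])),
                    float(rng.normal(0, 0.3)),
                    se_out=float(rng.uniform(0.01, 0.3)),
                    snp=f"rs{i}",
                )
                for i in range(k)
            ]
            fit = ivw(pairs)
            x = np.array([p.exposure.beta for p in pairs])
            y = np.array([p.outcome.beta for p in pairs])
            w = 1.0 / np.array([p.outcome.se for p in pairs]) ** 2
            slope = np.sum(w * x * y) / np.sum(w * x**2)
            se = 1.0 / math.sqrt(np.sum(w * x**2))
            assert fit.beta_mr == pytest.approx(slope, abs=1e-10)
            assert fit.se_mr == pytest.approx(se, abs=1e-10)

    def test_k1_degenerates_to_wald(self):
        pair = make_pair(0.4, 0.12, se_out=0.03)
        with pytest.raises(ValueError):
            ivw([pair])
        # the k=1 limit of the IVW formulas equals the Wald ratio
        wald = wald_ratio(pair)
        assert wald.beta_mr == pytest.approx(0.12 / 0.4)

    def test_random_effects_inflates_se_only_under_heterogeneity(self):
        hom = [make_pair(1.0, 0.3, se_out=0.1, snp=f"rs{i}") for i in range(3)]
        assert ivw(hom, random_effects=True).se_mr == pytest.approx(ivw(hom).se_mr)
        het = [make_pair(1.0, b, se_out=0.05, snp=f"rs{i}") for i, b in enumerate([0.0, 0.3, 0.6])]
        assert ivw(het, random_effects=True).se_mr > ivw(het).se_mr


class TestMrEgger:
    def test_perfectly_proportional_fit(self):
        theta = 0.25
        pairs = [make_pair(b, theta * b, se_out=0.05, snp=f"rs{i}")
                 for i, b in enumerate([0.2, 0.5, 0.9, 1.4])]
        fit = mr_egger(pairs)
        assert fit.beta_mr == pytest.approx(theta, abs=1e-10)
        assert fit.egger_intercept == pytest.approx(0.0, abs=1e-10)

    def test_orientation_invariance(self):
        pairs = [make_pair(b, 0.2 * b + i * 0.01, se_out=0.05, snp=f"rs{i}")
                 for i, b in enumerate([0.2, 0.5, 0.9, 1.4])]
        flipped = [make_pair(-p.exposure.beta, -p.outcome.beta, se_out=0.05, snp=p.snp_id)
                   for p in pairs[:2]] + pairs[2:]
        a, b = mr_egger(pairs), mr_egger(flipped)
        assert a.beta_mr == pytest.approx(b.beta_mr, rel=1e-10)
        assert a.egger_intercept == pytest.approx(b.egger_intercept, rel=1e-10)

    def test_zero_pleiotropy_intercept_small(self, rng):
        """Pleiotropy-free data: the intercept test rejects at 1% only rarely."""
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            k = 20
            bx = rng.uniform(0.2, 1.0, k)
            by = 0.3 * bx + rng.normal(0, 0.05, k)
            pairs = [make_pair(float(bx[i]), float(by[i]), se_out=0.05, snp=f"rs{i}")
                     for i in range(k)]
            fit = mr_egger(pairs)
            if fit.egger_intercept_p > 0.01:
                hits += 1
        assert hits >= 0.95 * n_rep

    def test_requires_three_instruments(self):
        with pytest.raises(ValueError, match="3"):
            mr_egger([make_pair(0.5, 0.1, snp="rs1"), make_pair(0.4, 0.1, snp="rs2")])


class TestBonferroni:
    def test_family_of_732(self):
        decision = bonferroni([], alpha=0.05, n_tests=732)
        assert decision.threshold == pytest.approx(0.05 / 732, rel=1e-15)
        assert decision.threshold == pytest.approx(6.83e-5, rel=5e-3)

    def test_single_test(self):
        assert bonferroni([], alpha=0.05, n_tests=1).threshold == 0.05

    def test_boundary_is_strict(self):
        fit = wald_ratio(make_pair(0.5, 0.1))
        fit.pval = 0.05 / 10
        fit.protein_id = "P_exact"
        decision = bonferroni([fit], alpha=0.05, n_tests=10)
        assert decision.significant_ids == []
        fit.pval = 0.05 / 10 - 1e-12
        assert bonferroni([fit], alpha=0.05, n_tests=10).significant_ids == ["P_exact"]


class TestReplicate:
    def _discovery(self):
        fit = wald_ratio(make_pair(0.5, 0.2, snp="rs_disc"))
        fit.protein_id = "P1"
        return fit

    def test_same_sign_significant_replicates(self):
        rep = [make_pair(0.4, 0.15, se_out=0.02, snp="rs_disc")]
        outcome = replicate(self._discovery(), rep, "same_variant")
        assert outcome.replicated and outcome.direction_consistent
        assert outcome.pval_rep < 0.01

    def test_opposite_sign_fails(self):
        rep = [make_pair(0.4, -0.15, se_out=0.02, snp="rs_disc")]
        outcome = replicate(self._discovery(), rep, "same_variant")
        assert not outcome.replicated and not outcome.direction_consistent

    def test_no_overlap_reason(self):
        rep = [make_pair(0.4, 0.15, snp="rs_other")]
        outcome = replicate(self._discovery(), rep, "same_variant")
        assert not outcome.replicated and outcome.reason == "no_overlap"

    def test_significant_variant_reselects(self):
        from conftest import make_record
        from pqtlmr.sumstats import HarmonizedPair

        def pair_with_p(snp, p_exp, beta_out, se_out):
            exp = make_record(snp=snp, beta=0.5, pval=p_exp)
            out = make_record(snp=snp, beta=beta_out, se=se_out,
                              trait_type="case_control", case_fraction=0.5)
            return HarmonizedPair(snp, exp, out, "none")

        weak = pair_with_p("rs_weak", 1e-4, 0.05, 0.2)
        strong = pair_with_p("rs_strong", 1e-12, 0.2, 0.02)
        outcome = replicate(self._discovery(), [weak, strong], "significant_variant")
        assert outcome.n_snps == 1 and outcome.replicated

    def test_replication_rate_with_true_effect(self, rng):
        """θ ≠ 0, large replication n: almost every run replicates."""
        from pqtlmr.simulate import ScenarioConfig, simulate_region
        from pqtlmr.sumstats import harmonize, kept_pairs

        hits = 0
        n_rep = 50
        for i in range(n_rep):
            cfg = ScenarioConfig(seed=9000 + i, n_disease_instruments=0, m_snps=30)
            region = simulate_region(cfg)
            pairs = kept_pairs(harmonize(region.exposure, region.outcome))
            causal = cfg.ci1
            disc = wald_ratio(pairs[causal], "P", "cancer")
            rep_cfg = ScenarioConfig(seed=50_000 + i, n_disease_instruments=0, m_snps=30,
                                     n_exposure=35_559)
            rep = simulate_region(rep_cfg)
            rep_pairs = kept_pairs(harmonize(rep.exposure, rep.outcome))
            if replicate(disc, rep_pairs, "same_variant").replicated:
                hits += 1
        assert hits / n_rep > 0.9
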