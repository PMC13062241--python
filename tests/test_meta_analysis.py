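import math
import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from sjoverlap.meta_analysis import (
    EffectEstimate,
    MetaAnalysisError,
    StudyCounts,
    begg_test,
    ci_from_effect,
    cohens_kappa,
    egger_test,
    estimates_for_pooling,
    forest_table,
    load_familial_fixture,
    load_poolings,
    pool_fixed,
    pool_random_dl,
    rr_from_counts,
    subgroup_pool,
)

from conftest import make_estimates


class TestRRFromCounts:
    def test_equal_rates_give_unit_rr(self):
        est = rr_from_counts(StudyCounts(a=5, c=95, b=10, d=190))
        assert est.rr == pytest.approx(1.0)
        assert est.log_rr == pytest.approx(0.0)

    def test_hand_evaluated_ratio(self):
        est = rr_from_counts(StudyCounts(a=10, c=90, b=5, d=195))
        assert est.rr == pytest.approx(4.0)
        assert est.se == pytest.approx(
            math.sqrt(1 / 10 - 1 / 100 + 1 / 5 - 1 / 200), rel=1e-12
        )

    def test_zero_cell_is_rejected_by_default(self):
        with pytest.raises(MetaAnalysisError, match="zero-cell"):
            rr_from_counts(StudyCounts(a=10, c=90, b=0, d=200))

    def test_zero_cell_continuity_correction_opt_in(self):
        est = rr_from_counts(
            StudyCounts(a=10, c=90, b=0, d=200), continuity_correction=True
        )
        assert np.isfinite(est.log_rr) and est.se > 0

    def test_empty_group_invalid(self):
        with pytest.raises(MetaAnalysisError):
            StudyCounts(a=0, c=0, b=5, d=95)


class TestConfidenceIntervals:
    @pytest.mark.parametrize(
        "log_rr,se,lo,hi",
        [
            (2.55, 0.31, 7.00, 23.30),  # concordant-SjD Danish registry row
            (1.08, 0.12, 2.33, 3.73),  # RA->SjD Taiwanese registry row
        ],
    )
    def test_published_ci_round_trip(self, log_rr, se, lo, hi):
        got_lo, got_hi = ci_from_effect(log_rr, se)
        assert got_lo == pytest.approx(lo, rel=0.02)
        assert got_hi == pytest.approx(hi, rel=0.02)

    def test_degenerate_small_se_collapses_to_point(self):
        lo, hi = ci_from_effect(0.0, 1e-12)
        assert lo == pytest.approx(1.0, abs=1e-9)
        assert hi == pytest.approx(1.0, abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(MetaAnalysisError):
            ci_from_effect(0.0, -1.0)
        with pytest.raises(MetaAnalysisError):
            ci_from_effect(0.0, 1.0, level=1.5)


class TestPooling:
    def test_identical_studies_pool_to_themselves(self):
        ests = make_estimates([(0.7, 0.2), (0.7, 0.2)])
        res = pool_fixed(ests)
        assert res.pooled_log_rr == pytest.approx(0.7)
        assert res.q == pytest.approx(0.0, abs=1e-12)
        assert res.i2 == 0.0

    def test_common_effect_concordant_trio(self, sjd_trio):
        # hand inverse-variance oracle: 9.645
        res = pool_fixed(sjd_trio)
        assert res.pooled_rr == pytest.approx(9.645, rel=1e-3)
        assert res.df == 2

    def test_ra_pair_heterogeneity_matches_hand_q(self, ra_pair):
        res = pool_fixed(ra_pair)
        assert res.q == pytest.approx(16.84, rel=1e-3)
        assert res.df == 1
        assert res.i2 == pytest.approx(94.06, rel=1e-3)

    def test_random_effects_concordant_trio_matches_published(self, sjd_trio):
        res = pool_random_dl(sjd_trio)
        assert res.pooled_rr == pytest.approx(10.54, rel=0.01)
        assert res.ci_low == pytest.approx(7.85, rel=0.01)
        assert res.ci_high == pytest.approx(14.16, rel=0.01)
        assert res.i2 == pytest.approx(69.1, rel=0.01)

    def test_random_effects_sle_trio_matches_published(self, sle_trio):
        res = pool_random_dl(sle_trio)
        assert res.pooled_rr == pytest.approx(4.49, rel=0.01)
        assert res.i2 == pytest.approx(80.2, rel=0.01)

    def test_no_heterogeneity_equals_common_effect(self):
        ests = make_estimates([(0.5, 0.2), (0.5, 0.3), (0.5, 0.1)])
        rand, fixed = pool_random_dl(ests), pool_fixed(ests)
        assert rand.tau2 == 0.0
        assert rand.pooled_log_rr == pytest.approx(fixed.pooled_log_rr)
        assert rand.pooled_se == pytest.approx(fixed.pooled_se)

    def test_single_study_rejected(self):
        with pytest.raises(MetaAnalysisError, match="insufficient"):
            pool_fixed(make_estimates([(0.5, 0.2)]))

    @given(
        hst.lists(
            hst.tuples(
                hst.floats(-2, 3), hst.floats(0.05, 1.0)
            ),
            min_size=2,
            max_size=8,
        )
    )
    @settings(deadline=None, max_examples=60)
    def test_pooled_estimate_within_study_range(self, pairs):
        ests = make_estimates(pairs)
        thetas = [e.log_rr for e in ests]
        for res in (pool_fixed(ests), pool_random_dl(ests)):
            assert min(thetas) - 1e-9 <= res.pooled_log_rr <= max(thetas) + 1e-9
            assert res.tau2 >= 0
            assert 0 <= res.i2 <= 100

    @given(
        hst.lists(
            hst.tuples(hst.floats(-2, 3), hst.floats(0.05, 1.0)),
            min_size=2,
            max_size=6,
        )
    )
    @settings(deadline=None, max_examples=40)
    def test_duplicating_the_pooled_value_never_raises_i2(self, pairs):
        ests = make_estimates(pairs)
        res = pool_fixed(ests)
        dup = ests + [
            EffectEstimate(study_label="dup", log_rr=res.pooled_log_rr, se=res.pooled_se)
        ]
        assert pool_fixed(dup).i2 <= res.i2 + 1e-9


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
class TestMetaforOracle:
    """Independent cross-check against R metafor's DerSimonian-Laird pooling."""

    def _metafor_dl(self, pairs):
        yi = ",".join(str(p[0]) for p in pairs)
        sei = ",".join(str(p[1]) for p in pairs)
        script = (
            "suppressMessages(library(metafor));"
            f"r <- rma(yi=c({yi}), sei=c({sei}), method='DL');"
            "cat(sprintf('%.10f %.10f %.10f', r$b[1], r$tau2, r$I2))"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        return [float(x) for x in out.stdout.split()]

    def test_concordant_trio_agrees_with_metafor(self, sjd_trio):
        pairs = [(e.log_rr, e.se) for e in sjd_trio]
        mu, tau2, i2 = self._metafor_dl(pairs)
        res = pool_random_dl(sjd_trio)
        assert res.pooled_log_rr == pytest.approx(mu, abs=1e-8)
        assert res.tau2 == pytest.approx(tau2, abs=1e-8)
        assert res.i2 == pytest.approx(i2, abs=1e-4)


class TestSubgroups:
    def test_single_group_equals_plain_pooling(self, sjd_trio):
        res = subgroup_pool(sjd_trio, ["all"] * 3)
        assert res.q_between == pytest.approx(0.0, abs=1e-12)
        assert res.groups["all"].pooled_log_rr == pytest.approx(
            pool_random_dl(sjd_trio).pooled_log_rr
        )

    def test_identical_groups_have_zero_between_q(self):
        ests = make_estimates([(0.5, 0.2), (0.5, 0.2), (0.5, 0.2), (0.5, 0.2)])
        res = subgroup_pool(ests, ["a", "a", "b", "b"])
        assert res.q_between == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_between_group_q(self):
        # group a: two identical studies pooling to (0, 0.5); group b: single (1, 0.5)
        s = 0.5 * math.sqrt(2)
        ests = make_estimates([(0.0, s), (0.0, s), (1.0, 0.5)])
        res = subgroup_pool(ests, ["a", "a", "b"])
        assert res.q_between == pytest.approx(2.0, rel=1e-9)
        assert res.df_between == 1

    def test_singleton_group_reported_unpooled(self):
        ests = make_estimates([(0.0, 0.5), (0.2, 0.5), (1.0, 0.5)])
        res = subgroup_pool(ests, ["a", "a", "b"])
        assert isinstance(res.groups["b"], EffectEstimate)


class TestBiasTests:
    def test_egger_detects_constructed_small_study_effect(self):
        se = np.linspace(0.1, 1.0, 8)
        ests = make_estimates([(3.0 * s, s) for s in se])
        res = egger_test(ests)
        assert abs(res.statistic) > 0.5
        assert res.p_value < 0.05

    def test_egger_null_when_effects_equal(self):
        se = np.linspace(0.1, 1.0, 8)
        ests = make_estimates([(0.7, s) for s in se])
        res = egger_test(ests)
        assert res.statistic == pytest.approx(0.0, abs=1e-8)

    def test_egger_matches_ols_oracle(self):
        rng = np.random.default_rng(3)
        se = rng.uniform(0.1, 0.8, 10)
        th = rng.normal(0.5, 0.3, 10)
        ests = make_estimates(list(zip(th, se)))
        res = egger_test(ests)
        slope, intercept = np.polyfit(1 / se, th / se, 1)
        assert res.statistic == pytest.approx(intercept, rel=1e-9)

    def test_too_few_studies(self):
        with pytest.raises(MetaAnalysisError, match="insufficient"):
            egger_test(make_estimates([(0.5, 0.2), (0.6, 0.3)]))
        with pytest.raises(MetaAnalysisError):
            begg_test(make_estimates([(0.5, 0.2), (0.6, 0.3)]))

    def test_begg_monotone_association_gives_tau_one(self):
        se = np.linspace(0.2, 1.0, 6)
        ests = make_estimates([(5.0 * s**2, s) for s in se])
        res = begg_test(ests)
        assert res.statistic > 0.8

    def test_begg_pvalues_uniform_under_permutation_null(self):
        """Monte-Carlo permutation oracle: when deviations are drawn
        independently of the precision ranks, the Kendall-tau p-values the
        test reports are ~uniform (KS at alpha=0.01, 2000 replicates)."""
        from scipy import stats

        rng = np.random.default_rng(11)
        var = rng.uniform(0.01, 1.0, 40)
        pvals = [stats.kendalltau(rng.standard_normal(40), var).pvalue for _ in range(2000)]
        d, p = stats.kstest(pvals, "uniform")
        assert p > 0.01

    def test_begg_full_null_is_not_anticonservative(self):
        """Simulated meta-analyses with no small-study effect: the rejection
        rate at alpha=0.05 stays at or below nominal (the shared pooled-mean
        standardization makes the test slightly conservative)."""
        rng = np.random.default_rng(11)
        se = rng.uniform(0.1, 1.0, 30)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            th = rng.normal(0.3, se)
            if begg_test(make_estimates(list(zip(th, se)))).p_value < 0.05:
                rejections += 1
        assert rejections / n_rep <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_rep)


class TestCohensKappa:
    def test_identical_sequences(self):
        assert cohens_kappa(list("abcabc"), list("abcabc")) == pytest.approx(1.0)

    def test_hand_evaluated_two_by_two(self):
        r1 = ["x"] * 50 + ["y"] * 50
        r2 = ["x"] * 40 + ["y"] * 10 + ["x"] * 10 + ["y"] * 40
        assert cohens_kappa(r1, r2) == pytest.approx(0.6)

    def test_constant_rater_vs_balanced_is_chance_level(self):
        r1 = ["x"] * 10
        r2 = ["x", "y"] * 5
        assert cohens_kappa(r1, r2) == pytest.approx(0.0)

    def test_both_raters_constant_and_equal(self):
        assert cohens_kappa(["x"] * 5, ["x"] * 5) == 1.0


class TestForestTable:
    def test_row_count_and_weight_normalization(self, sjd_trio):
        table = forest_table(sjd_trio, pool_fixed(sjd_trio), pool_random_dl(sjd_trio))
        assert len(table) == 5  # 3 studies + 2 pooled rows
        assert table.weight_common_pct.iloc[:3].sum() == pytest.approx(100.0)
        assert table.weight_random_pct.iloc[:3].sum() == pytest.approx(100.0)
        assert "i2" in table.attrs["heterogeneity"]

    def test_round_trip_preserves_rr(self, sjd_trio, tmp_path):
        table = forest_table(sjd_trio, pool_fixed(sjd_trio), pool_random_dl(sjd_trio))
        path = tmp_path / "forest.tsv"
        table.to_csv(path, sep="\t", index=False)
        import pandas as pd

        back = pd.read_csv(path, sep="\t")
        assert np.allclose(back.rr.iloc[:3], [e.rr for e in sjd_trio])


class TestFixture:
    def test_all_named_poolings_resolve(self):
        fixture = load_familial_fixture()
        for name, pooling in load_poolings().items():
            ests = estimates_for_pooling(fixture, pooling)
            assert len(ests) == len(pooling["studies"]), name

    def test_fixture_log_rr_consistent_with_rr(self):
        fixture = load_familial_fixture()
        assert np.allclose(np.log(fixture.rr), fixture.log_rr, atol=0.015)
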