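"""Association models, FDR, and summary-statistic group tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

from lipidscan.stats import (
    bh_fdr,
    chisq_independence,
    fit_cox,
    fit_logistic,
    scan_panel,
    two_group_anova_summary,
)


def _series(x):
    return pd.Series(np.asarray(x, dtype=float))


class TestLogistic:
    def test_balanced_null_zero_beta(self):
        y = _series([1] * 5 + [1] * 5 + [0] * 5 + [0] * 5)
        x = _series(([0] * 5 + [1] * 5) * 2)
        res = fit_logistic(y, x)
        assert res.beta == pytest.approx(0.0, abs=1e-8)

    def test_two_by_two_closed_form(self):
        # counts: (x=1,y=1)=20, (x=1,y=0)=10, (x=0,y=1)=10, (x=0,y=0)=20
        y = _series([1] * 20 + [0] * 10 + [1] * 10 + [0] * 20)
        x = _series([1] * 30 + [0] * 30)
        res = fit_logistic(y, x)
        assert res.beta == pytest.approx(np.log(4), rel=1e-6)
        assert res.se == pytest.approx(np.sqrt(1 / 20 + 1 / 10 + 1 / 10 + 1 / 20), rel=1e-6)
        assert res.n_cases == 30 and res.n_total == 60

    def test_separation_flagged_not_raised(self):
        y = _series([0] * 10 + [1] * 10)
        x = _series(np.arange(20.0))
        res = fit_logistic(y, x)
        assert res.flag == "separation"
        assert np.isnan(res.p)

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_logistic(_series([1, 1, 1]), _series([0.0, 1.0, 2.0]))

    def test_rank_deficiency_names_columns(self, rng):
        y = _series(rng.integers(0, 2, 40))
        x = _series(rng.standard_normal(40))
        covs = pd.DataFrame({"dup": x.to_numpy()})
        with pytest.raises(ValueError, match="rank deficient"):
            fit_logistic(y, x, covs)

    def test_lipid_rescale_scales_beta(self, rng):
        y = _series(rng.integers(0, 2, 200))
        x = _series(rng.standard_normal(200))
        b1 = fit_logistic(y, x).beta
        b2 = fit_logistic(y, 2.0 * x).beta
        assert b2 == pytest.approx(b1 / 2.0, rel=1e-6)


class TestCox:
    def test_three_subject_partial_likelihood_oracle(self):
        """Grid-maximised partial likelihood on three subjects gives ln sqrt(2)."""
        entry = _series([0.0, 0.0, 0.0])
        exit_ = _series([1.0, 2.0, 3.0])
        event = _series([1, 1, 1])
        x = _series([0.0, 1.0, 0.0])

        def neg_pl(beta):
            u = np.exp(beta)
            return -(np.log(1 / (2 + u)) + np.log(u / (1 + u)))

        grid = minimize_scalar(neg_pl, bounds=(-3, 3), method="bounded")
        assert grid.x == pytest.approx(np.log(np.sqrt(2)), abs=1e-5)
        res = fit_cox(entry, exit_, event, x)
        assert res.beta == pytest.approx(np.log(np.sqrt(2)), abs=5e-3)

    def test_constant_lipid_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            fit_cox(
                _series([0, 0, 0]), _series([1, 2, 3]), _series([1, 1, 0]),
                _series([1.0, 1.0, 1.0]),
            )

    def test_exit_before_entry_rejected(self):
        with pytest.raises(ValueError, match="exit age"):
            fit_cox(
                _series([5, 5]), _series([4, 6]), _series([1, 1]), _series([0.0, 1.0])
            )

    def test_lipid_rescale_scales_beta(self, prepared):
        o = prepared.incident.outcome
        x = prepared.incident.species.iloc[:, 0]
        b1 = fit_cox(o["entry_age"], o["exit_age"], o["event"], x).beta
        b2 = fit_cox(o["entry_age"], o["exit_age"], o["event"], 2.0 * x).beta
        assert b2 == pytest.approx(b1 / 2.0, rel=1e-5)


class TestBhFdr:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr(np.array([0.03])), [0.03])

    def test_step_up_example(self):
        np.testing.assert_allclose(
            bh_fdr(np.array([0.01, 0.02, 0.03, 0.04])), [0.04] * 4
        )

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_fdr(np.array([0.2, 0.2, 0.2])), [0.2] * 3)

    def test_matches_statsmodels_when_family_equals_length(self, rng):
        p = rng.uniform(0.001, 1, 50)
        np.testing.assert_allclose(
            bh_fdr(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    def test_family_size_larger_than_vector(self):
        # 2 tests surviving from a declared family of 4
        np.testing.assert_allclose(bh_fdr(np.array([0.01, 0.5]), 4), [0.04, 1.0])

    def test_invalid_p_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.2], [np.nan, 0.5]):
            with pytest.raises(ValueError):
                bh_fdr(np.array(bad))
        with pytest.raises(ValueError, match="family_size"):
            bh_fdr(np.array([0.1, 0.2]), 1)

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=30)
    )
    def test_monotone_in_ranks(self, ps):
        p = np.array(ps)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p - 1e-12) and np.all(q <= 1.0)


class TestAnovaSummary:
    def test_equal_means(self):
        F, p = two_group_anova_summary(10, 5.0, 1.0, 12, 5.0, 2.0)
        assert F == 0.0 and p == 1.0

    def test_matches_cohort_table_age_row(self):
        _, p = two_group_anova_summary(696, 75.27, 6.53, 268, 81.40, 7.91)
        # printed summary statistics reproduce the reported 2.96e-32 to
        # within their rounding
        assert np.log10(p) == pytest.approx(np.log10(2.96e-32), abs=0.15)

    def test_matches_cohort_table_triglyceride_row(self):
        _, p = two_group_anova_summary(696, 1.26, 0.63, 268, 1.50, 0.78)
        assert np.log10(p) == pytest.approx(np.log10(9.42e-7), abs=0.05)

    def test_equals_squared_pooled_t(self, rng):
        n1, n2 = 14, 23
        a, b = rng.normal(0, 1, n1), rng.normal(0.4, 1.3, n2)
        F, p = two_group_anova_summary(
            n1, a.mean(), a.std(ddof=1), n2, b.mean(), b.std(ddof=1)
        )
        from scipy.stats import ttest_ind

        t = ttest_ind(a, b, equal_var=True)
        assert F == pytest.approx(t.statistic**2, rel=1e-10)
        assert p == pytest.approx(t.pvalue, rel=1e-10)

    def test_degenerate_zero_variance(self):
        F, p = two_group_anova_summary(5, 1.0, 0.0, 5, 2.0, 0.0)
        assert p == 0.0 and np.isinf(F)


class TestChisq:
    def test_proportional_rows_null(self):
        chi2, df, p = chisq_independence([[10, 20], [20, 40]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_apoe_allele_tables(self):
        _, _, p1 = chisq_independence([[523, 99], [163, 131], [10, 38]])
        assert p1 == pytest.approx(7.31e-33, rel=0.01)
        _, _, p2 = chisq_independence([[257, 58], [118, 83], [22, 25]])
        assert p2 == pytest.approx(1.91e-10, rel=0.01)

    def test_permutation_invariance(self, rng):
        tab = rng.integers(1, 50, size=(3, 2))
        chi2, df, _ = chisq_independence(tab)
        chi2p, dfp, _ = chisq_independence(tab[[2, 0, 1]][:, [1, 0]])
        assert chi2p == pytest.approx(chi2, rel=1e-12)
        assert df == dfp == 2

    def test_df2_closed_form(self, rng):
        tab = rng.integers(5, 60, size=(3, 2))
        chi2, df, p = chisq_independence(tab)
        assert df == 2
        assert p == pytest.approx(np.exp(-chi2 / 2), rel=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chisq_independence([[0, 0], [5, 3]])


class TestScanPanel:
    def test_single_species_q_equals_p(self, prepared):
        aset = prepared.prevalent
        import dataclasses

        small = dataclasses.replace(
            aset, species=aset.species.iloc[:, :1], classes=aset.classes.iloc[:, :1]
        )
        tab = scan_panel(small)
        sp = tab[tab["level"] == "species"].iloc[0]
        assert sp["q"] == pytest.approx(sp["p"])

    def test_planted_species_detected(self, prepared):
        tab = scan_panel(prepared.prevalent)
        sp = tab[tab["level"] == "species"].set_index("lipid")
        assert sp.loc["PC(30:0)", "q"] < 0.05
        assert sp.loc["PC(30:0)", "beta"] > 0

    def test_families_adjusted_separately(self, prepared):
        tab = scan_panel(prepared.prevalent)
        for level, fam in [("species", 40), ("class", 4)]:
            sub = tab[(tab["level"] == level) & tab["p"].notna()]
            np.testing.assert_allclose(
                sub["q"].to_numpy(), bh_fdr(sub["p"].to_numpy(), fam), atol=1e-12
            )
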