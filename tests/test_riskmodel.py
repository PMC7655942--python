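"""Matching, stepwise selection, discrimination and reclassification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import toy_metadata
from lipidscan import riskmodel
from lipidscan.clusters import ClusterAssignment
from lipidscan.riskmodel import (
    c_statistic,
    cv_stepwise_select,
    finalize_features,
    match_discovery_subset,
    nri_continuous,
    replicate_evaluate,
)


def _brute_force_auc(scores, y):
    s = np.asarray(scores, float)
    y = np.asarray(y, bool)
    num = den = 0.0
    for i in np.flatnonzero(y):
        for j in np.flatnonzero(~y):
            den += 1
            if s[i] > s[j]:
                num += 1
            elif s[i] == s[j]:
                num += 0.5
    return num / den


def _brute_force_harrell(scores, entry, exit_, event):
    s, en, ex, ev = map(np.asarray, (scores, entry, exit_, event))
    num = den = 0.0
    n = len(s)
    for i in range(n):
        if not ev[i]:
            continue
        for j in range(n):
            if j == i:
                continue
            if ex[i] < ex[j] and ex[i] > en[j]:
                den += 1
                if s[i] > s[j]:
                    num += 1
                elif s[i] == s[j]:
                    num += 0.5
    return num / den


class TestCStatistic:
    def test_worked_example(self):
        assert c_statistic([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_perfect_and_uninformative(self):
        assert c_statistic([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0
        assert c_statistic([0.5] * 6, [0, 0, 0, 1, 1, 1]) == 0.5

    def test_monotone_transform_invariance(self, rng):
        s = rng.standard_normal(40)
        y = rng.integers(0, 2, 40)
        y[0], y[1] = 0, 1
        assert c_statistic(np.exp(s), y) == pytest.approx(c_statistic(s, y))

    def test_matches_brute_force_binary(self, rng):
        for _ in range(5):
            n = int(rng.integers(10, 200))
            s = rng.choice(np.linspace(0, 1, 17), n)  # many ties
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            assert c_statistic(s, y) == pytest.approx(_brute_force_auc(s, y))

    def test_matches_brute_force_survival(self, rng):
        n = 100
        entry = rng.uniform(60, 75, n)
        exit_ = entry + rng.uniform(0.5, 8, n)
        event = rng.integers(0, 2, n)
        event[:2] = 1
        s = rng.standard_normal(n)
        ours = c_statistic(s, entry=entry, exit=exit_, event=event)
        assert ours == pytest.approx(_brute_force_harrell(s, entry, exit_, event))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            c_statistic([0.1, 0.2], [1, 1])
        with pytest.raises(ValueError, match="comparable"):
            c_statistic([1.0, 2.0], entry=[0, 0], exit=[1, 2], event=[0, 0])


class TestNri:
    def test_no_change_zero(self):
        s = [0.1, 0.5, 0.9, 0.2]
        assert nri_continuous(s, s, [1, 1, 0, 0]) == (0.0, 0.0, 0.0)

    def test_maximal_reclassification(self):
        base = [0.5, 0.5, 0.5, 0.5]
        new = [0.9, 0.8, 0.1, 0.2]
        assert nri_continuous(base, new, [1, 1, 0, 0]) == (2.0, 1.0, 1.0)

    def test_direct_count_oracle(self):
        # events: one up, one down; nonevents: both down -> (1, 0, 1)
        base = [0.5, 0.5, 0.5, 0.5]
        new = [0.7, 0.3, 0.2, 0.4]
        assert nri_continuous(base, new, [1, 1, 0, 0]) == (1.0, 0.0, 1.0)

    @settings(deadline=None, max_examples=40)
    @given(st.integers(min_value=0, max_value=2**20))
    def test_identities(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        base, new = rng.standard_normal(n), rng.standard_normal(n)
        y = rng.integers(0, 2, n)
        y[0], y[1] = 0, 1
        total, ev, ne = nri_continuous(base, new, y)
        assert total == pytest.approx(ev + ne)
        # swapping labels swaps and negates the components
        t2, e2, n2 = nri_continuous(base, new, 1 - y)
        assert e2 == pytest.approx(-ne)
        assert n2 == pytest.approx(-ev)
        assert -1 <= ev <= 1 and -1 <= ne <= 1 and -2 <= total <= 2


class TestMatching:
    def test_exact_duplicates_matched(self):
        rows = []
        for i, (age, sex) in enumerate([(80, "F"), (74, "M"), (68, "F")]):
            rows.append({"sample_id": f"case{i}", "age": age, "sex": sex, "converted": True})
            for k in range(2):
                rows.append(
                    {"sample_id": f"dup{i}{k}", "age": age, "sex": sex, "converted": False}
                )
        rows.append({"sample_id": "far", "age": 95.0, "sex": "F", "converted": False})
        meta = toy_metadata(rows)
        matched = match_discovery_subset(meta, ratio=2)
        assert len(matched) == 9
        controls = matched[~matched["converted"]]
        cases = matched[matched["converted"]]
        assert sorted(controls["age"]) == sorted(np.repeat(sorted(cases["age"]), 2))

    def test_greedy_nearest_age_oracle(self):
        cases = [("c0", 82.0), ("c1", 75.0), ("c2", 70.0)]
        controls = [
            ("k0", 81.0), ("k1", 83.5), ("k2", 74.0), ("k3", 76.5),
            ("k4", 69.0), ("k5", 71.0), ("k6", 50.0), ("k7", 95.0),
            ("k8", 60.0), ("k9", 88.0),
        ]
        rows = [
            {"sample_id": c, "age": a, "sex": "F", "converted": True} for c, a in cases
        ] + [
            {"sample_id": k, "age": a, "sex": "F", "converted": False}
            for k, a in controls
        ]
        matched = match_discovery_subset(toy_metadata(rows), ratio=2)
        picked = set(matched.index) - {c for c, _ in cases}
        # greedy, cases descending age: c0 takes k0,k1; c1 takes k2,k3; c2 takes k4,k5
        assert picked == {"k0", "k1", "k2", "k3", "k4", "k5"}

    def test_ratio_two_gives_three_rows_per_case(self):
        rng = np.random.default_rng(4)
        rows = []
        for i in range(68):
            rows.append(
                {"sample_id": f"c{i}", "age": float(rng.uniform(70, 85)),
                 "sex": "F" if i % 2 else "M", "converted": True}
            )
        for i in range(400):
            rows.append(
                {"sample_id": f"k{i}", "age": float(rng.uniform(60, 90)),
                 "sex": "F" if i % 2 else "M", "converted": False}
            )
        matched = match_discovery_subset(toy_metadata(rows), ratio=2)
        assert len(matched) == 68 * 3  # 68 + 136

    def test_insufficient_pool_reports_shortfall(self):
        rows = [
            {"sample_id": "c0", "age": 80.0, "sex": "F", "converted": True},
            {"sample_id": "k0", "age": 79.0, "sex": "F", "converted": False},
        ]
        with pytest.raises(ValueError, match="shortfall"):
            match_discovery_subset(toy_metadata(rows), ratio=2)


class TestStepwise:
    def test_max_k_zero_returns_all_zero(self, prepared):
        aset = prepared.prevalent
        covs = aset.covariates[riskmodel.BASE_MODEL_COVARIATES]
        freq = cv_stepwise_select(
            aset.species, covs, aset.outcome[["ad"]], "logistic", max_k=0, seed=1
        )
        assert (freq == 0).all()

    def test_dominant_planted_lipid_always_selected(self, rng):
        """One strong planted lipid among noise is incorporated in 10/10 folds."""
        n = 500
        lip = pd.DataFrame(
            rng.standard_normal((n, 21)), columns=[f"L{i}" for i in range(21)]
        )
        eta = 1.0 * lip["L0"] - 0.3
        y = pd.DataFrame({"y": (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)})
        covs = pd.DataFrame({"age": rng.normal(75, 5, n)})
        freq = cv_stepwise_select(lip, covs, y, "logistic", max_k=3, n_repeats=1, seed=2)
        assert freq["L0"] == 10

    def test_null_panel_selects_fewer_than_cap(self, rng):
        """AIC stopping keeps the mean selected count below the cap under the null."""
        counts = []
        for s in range(6):
            r = np.random.default_rng(s)
            n = 250
            lip = pd.DataFrame(
                r.standard_normal((n, 15)), columns=[f"N{i}" for i in range(15)]
            )
            y = pd.DataFrame({"y": r.integers(0, 2, n)})
            covs = pd.DataFrame({"age": r.normal(70, 5, n)})
            freq = cv_stepwise_select(lip, covs, y, "logistic", max_k=5, n_repeats=1, seed=s)
            counts.append(freq.sum() / 10)  # mean lipids per fold
        assert np.mean(counts) < 5

    def test_unknown_family_rejected(self, prepared):
        with pytest.raises(ValueError, match="family"):
            cv_stepwise_select(
                prepared.prevalent.species,
                prepared.prevalent.covariates,
                prepared.prevalent.outcome,
                "poisson",
            )


class TestFinalize:
    def test_split_frequency_merged_into_one_representative(self):
        # two correlated lipids split incorporations 6/4 inside one cluster
        freq = pd.Series({"A": 6.0, "B": 4.0, "C": 3.0})
        asn = ClusterAssignment(
            pd.Series({"A": 1, "B": 1, "C": 0}, dtype=int), 1, 2, 1
        )
        sel = finalize_features(freq, asn, max_k=2)
        assert sel.features == ["A", "C"]
        assert sel.cluster_ranking.iloc[0]["frequency"] == 10.0

    def test_all_zero_frequencies_empty_features(self):
        freq = pd.Series({"A": 0.0, "B": 0.0})
        asn = ClusterAssignment(pd.Series({"A": 0, "B": 0}, dtype=int), 0, 2, 1)
        assert finalize_features(freq, asn, max_k=5).features == []

    def test_truncation_to_top_k(self):
        freq = pd.Series({f"S{i}": float(12 - i) for i in range(12)})
        asn = ClusterAssignment(
            pd.Series({f"S{i}": 0 for i in range(12)}, dtype=int), 0, 2, 1
        )
        sel = finalize_features(freq, asn, max_k=10)
        assert len(sel.features) == 10
        assert sel.features[0] == "S0"


class TestReplicate:
    @staticmethod
    def _selection(features, family="logistic"):
        return riskmodel.SelectionResult(
            analysis="diagnosis" if family == "logistic" else "incidence",
            family=family,
            base_covariates=list(riskmodel.BASE_MODEL_COVARIATES),
            frequencies=pd.Series(dtype=float),
            cluster_ranking=pd.DataFrame(),
            features=features,
            max_k=len(features),
            n_folds=10,
            n_repeats=10,
            n_fits=100,
            seed=0,
        )

    def test_single_repeat_ci_collapses(self, prepared):
        sel = self._selection(["PC(30:0)"])
        ev = replicate_evaluate(prepared.prevalent, sel, n_repeats=1, seed=3)
        assert ev.c_ci == (ev.c_statistic, ev.c_statistic)

    def test_missing_feature_named(self, prepared):
        sel = self._selection(["PC(99:9)"])
        with pytest.raises(KeyError, match=r"PC\(99:9\)"):
            replicate_evaluate(prepared.prevalent, sel, n_repeats=1)

    def test_informative_lipid_beats_base(self, prepared):
        sel = self._selection(["PC(30:0)"])
        ev = replicate_evaluate(prepared.prevalent, sel, n_repeats=30, seed=5)
        d = ev.per_repeat["c"] - ev.per_repeat["c_base"]
        assert np.percentile(d, 2.5) > 0

    def test_null_lipid_does_not_beat_base(self):
        """With no planted effects every lipid is null: base model not beaten."""
        from lipidscan.pipeline import prepare_cohort
        from lipidscan.simulate import SimulationConfig, generate_cohort

        cfg = SimulationConfig(
            n_participants=600, n_classes=2, species_per_class=5, seed=77
        )
        conc, meta, _ = generate_cohort(cfg)
        cd = prepare_cohort(conc, meta)
        sel = self._selection(["PC(30:0)"])
        ev = replicate_evaluate(cd.prevalent, sel, n_repeats=30, seed=5)
        # added lipid cannot improve discrimination beyond base-model CI
        assert ev.c_statistic <= ev.base_c_ci[1] + 0.01
        lo, hi = np.percentile(ev.per_repeat["nri_total"], [2.5, 97.5])
        assert lo <= 0 <= hi or abs(ev.nri_total) < 0.1

    def test_reproducible_with_seed(self, prepared):
        sel = self._selection(["PC(30:0)"])
        e1 = replicate_evaluate(prepared.prevalent, sel, n_repeats=5, seed=9)
        e2 = replicate_evaluate(prepared.prevalent, sel, n_repeats=5, seed=9)
        pd.testing.assert_frame_equal(e1.per_repeat, e2.per_repeat)
        assert e1.c_statistic == e2.c_statistic
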