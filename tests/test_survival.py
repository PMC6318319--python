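import itertools

import numpy as np
import pandas as pd
import pytest

from scprog import synthetic
from scprog.survival import (
    RiskGroups,
    collapse_probes,
    hazard_ratio,
    km_estimate,
    kmeans_dichotomize,
    logrank_test,
    standardize,
)


def records_df(times, events, ids=None):
    ids = ids or [f"s{i}" for i in range(len(times))]
    return pd.DataFrame({"sample_id": ids, "time_days": times, "event": events})


def group_series(labels, ids=None):
    ids = ids or [f"s{i}" for i in range(len(labels))]
    return pd.Series(labels, index=ids)


class TestCollapseProbes:
    def test_single_probe_unchanged(self):
        m = pd.DataFrame({"p1": [1.0, 2.0]}, index=["s1", "s2"])
        out = collapse_probes(m, {"p1": "GENE"})
        assert list(out.columns) == ["GENE"]
        assert np.allclose(out["GENE"], [1.0, 2.0])

    def test_two_probes_averaged(self):
        m = pd.DataFrame({"p1": [4.0], "p2": [6.0]}, index=["s1"])
        out = collapse_probes(m, {"p1": "G", "p2": "G"})
        assert out.loc["s1", "G"] == pytest.approx(5.0)

    def test_unmapped_probes_warned_and_dropped(self):
        m = pd.DataFrame({"p1": [1.0], "p2": [9.0]}, index=["s1"])
        with pytest.warns(UserWarning, match="unmapped"):
            out = collapse_probes(m, {"p1": "G"})
        assert list(out.columns) == ["G"]

    def test_matches_groupby_oracle(self, rng):
        probes = [f"p{i}" for i in range(12)]
        genes = rng.choice(["A", "B", "C"], size=12)
        m = pd.DataFrame(
            rng.normal(size=(6, 12)), columns=probes,
            index=[f"s{i}" for i in range(6)],
        )
        pmap = dict(zip(probes, genes))
        out = collapse_probes(m, pmap)
        for gene in "ABC":
            cols = [p for p in probes if pmap[p] == gene]
            assert np.allclose(out[gene], m[cols].mean(axis=1))


class TestStandardize:
    def test_toy_column(self):
        m = pd.DataFrame({"g": [1.0, 3.0, 5.0]})
        out = standardize(m)
        assert np.allclose(out["g"], [-1.0, 0.0, 1.0])

    def test_idempotent(self, rng):
        m = pd.DataFrame(rng.normal(size=(20, 4)))
        once = standardize(m)
        twice = standardize(once)
        assert np.allclose(once.values, twice.values, atol=1e-10)

    def test_constant_column_zeroed_with_warning(self):
        m = pd.DataFrame({"g": [2.0, 2.0, 2.0], "h": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            out = standardize(m)
        assert (out["g"] == 0).all()

    def test_moments(self, rng):
        m = pd.DataFrame(rng.normal(5, 3, size=(50, 6)))
        out = standardize(m)
        assert np.allclose(out.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(out.std(axis=0, ddof=1), 1.0, atol=1e-10)


class TestKMeansDichotomize:
    def test_separated_blobs_split_perfectly(self, rng):
        X = pd.DataFrame(
            np.concatenate([rng.normal(-5, 0.3, (10, 3)), rng.normal(5, 0.3, (12, 3))]),
            index=[f"s{i}" for i in range(22)],
        )
        risk = kmeans_dichotomize(X, seed=0)
        assert set(risk.label_of_sample.iloc[:10]) == {"low"}
        assert set(risk.label_of_sample.iloc[10:]) == {"high"}

    def test_high_has_larger_mean(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 4)))
        risk = kmeans_dichotomize(X, seed=3)
        high = X.loc[risk.label_of_sample == "high"].values.mean()
        low = X.loc[risk.label_of_sample == "low"].values.mean()
        assert high > low
        assert risk.cluster_means["high"] > risk.cluster_means["low"]

    def test_duplicated_samples_same_partition(self, rng):
        X = pd.DataFrame(
            np.concatenate([rng.normal(-2, 0.5, (6, 2)), rng.normal(2, 0.5, (6, 2))]),
            index=[f"s{i}" for i in range(12)],
        )
        dup = pd.concat([X, X.set_axis([f"d{i}" for i in range(12)])])
        risk = kmeans_dichotomize(dup, seed=1)
        labels = risk.label_of_sample
        for i in range(12):
            assert labels[f"s{i}"] == labels[f"d{i}"]

    def test_matches_bruteforce_partition(self, rng):
        X = pd.DataFrame(rng.normal(size=(6, 2)), index=[f"s{i}" for i in range(6)])
        risk = kmeans_dichotomize(X, n_restarts=50, seed=0)

        def wcss(mask):
            total = 0.0
            for m in (mask, ~mask):
                if m.sum() == 0:
                    return np.inf
                sub = X.values[m]
                total += ((sub - sub.mean(axis=0)) ** 2).sum()
            return total

        best = min(
            (np.array([i in combo for i in range(6)]) for r in range(1, 6)
             for combo in itertools.combinations(range(6), r)),
            key=wcss,
        )
        ours = (risk.label_of_sample == "high").values
        assert wcss(ours) == pytest.approx(wcss(best), rel=1e-9)

    def test_k_exceeding_samples_rejected(self):
        X = pd.DataFrame([[1.0]], index=["s0"])
        with pytest.raises(ValueError):
            kmeans_dichotomize(X, seed=0)

    def test_seed_determinism(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 5)))
        a = kmeans_dichotomize(X, seed=7)
        b = kmeans_dichotomize(X, seed=7)
        assert (a.label_of_sample == b.label_of_sample).all()


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        rec = records_df([5, 6, 7], [0, 0, 0])
        curves = km_estimate(rec, group_series(["g"] * 3))
        assert (curves["g"]["survival"] == 1.0).all()

    def test_hand_computed_toy(self):
        # times (1, 2+, 3), events at 1 and 3: S = 2/3 after t=1, 0 after t=3
        rec = records_df([1, 2, 3], [1, 0, 1])
        curve = km_estimate(rec, group_series(["g"] * 3))["g"]
        s = dict(zip(curve["time"], curve["survival"]))
        assert s[1.0] == pytest.approx(2 / 3)
        assert s[2.0] == pytest.approx(2 / 3)
        assert s[3.0] == pytest.approx(0.0)

    def test_no_censoring_matches_ecdf(self, rng):
        times = rng.exponential(10, size=40).round(2)
        rec = records_df(times, [1] * 40)
        curve = km_estimate(rec, group_series(["g"] * 40))["g"]
        for t, s in zip(curve["time"][1:], curve["survival"][1:]):
            assert s == pytest.approx((times > t).mean(), abs=1e-12)

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        times = rng.exponential(10, size=60).round(1)
        events = rng.integers(0, 2, size=60)
        rec = records_df(times, events)
        curve = km_estimate(rec, group_series(["g"] * 60))["g"]
        kmf = KaplanMeierFitter().fit(times, events)
        for t, s in zip(curve["time"], curve["survival"]):
            assert s == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-10
            )

    def test_negative_times_rejected(self):
        rec = records_df([-1, 2], [1, 1])
        with pytest.raises(ValueError, match="negative"):
            km_estimate(rec, group_series(["g", "g"]))

    def test_curves_nonincreasing_start_at_one(self, rng):
        times = rng.exponential(5, size=50)
        events = rng.integers(0, 2, size=50)
        labels = rng.choice(["a", "b"], size=50)
        curves = km_estimate(records_df(times, events), group_series(list(labels)))
        for curve in curves.values():
            assert curve["survival"].iloc[0] == 1.0
            assert (np.diff(curve["survival"]) <= 1e-12).all()


class TestLogRank:
    def test_identical_groups_null(self):
        times = [1, 2, 3, 4, 5]
        events = [1, 1, 0, 1, 1]
        rec = records_df(times * 2, events * 2, ids=[f"s{i}" for i in range(10)])
        labels = group_series(["a"] * 5 + ["b"] * 5, ids=[f"s{i}" for i in range(10)])
        result = logrank_test(rec, labels)
        assert result.chi_square == pytest.approx(0.0, abs=1e-12)
        assert result.p == pytest.approx(1.0)

    def test_textbook_toy_matches_oracle(self):
        # two groups, hand-tabulated O/E/V over the risk table
        rec = records_df([1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 1, 0])
        labels = group_series(["a", "b", "a", "b", "a", "b"])
        result = logrank_test(rec, labels)
        o1 = e1 = v = 0.0
        times = np.array([1, 2, 3, 4, 5, 6])
        events = np.array([1, 1, 1, 1, 1, 0])
        in_a = np.array([True, False, True, False, True, False])
        for t in [1, 2, 3, 4, 5]:
            at = times >= t
            n, n1 = at.sum(), (at & in_a).sum()
            d = int(((times == t) & (events == 1)).sum())
            d1 = int(((times == t) & (events == 1) & in_a).sum())
            o1 += d1
            e1 += d * n1 / n
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        assert result.chi_square == pytest.approx((o1 - e1) ** 2 / v, abs=1e-12)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        times = rng.exponential(10, size=80)
        events = rng.integers(0, 2, size=80)
        labels = rng.choice(["a", "b"], size=80)
        rec = records_df(times, events)
        result = logrank_test(rec, group_series(list(labels)))
        ll = ll_logrank(
            times[labels == "a"], times[labels == "b"],
            events[labels == "a"], events[labels == "b"],
        )
        assert result.chi_square == pytest.approx(ll.test_statistic, rel=1e-9)
        assert result.p == pytest.approx(ll.p_value, rel=1e-9)

    def test_label_swap_invariant(self, rng):
        times = rng.exponential(10, size=40)
        events = rng.integers(0, 2, size=40)
        labels = list(rng.choice(["a", "b"], size=40))
        swapped = ["b" if l == "a" else "a" for l in labels]
        rec = records_df(times, events)
        r1 = logrank_test(rec, group_series(labels))
        r2 = logrank_test(rec, group_series(swapped))
        assert r1.chi_square == pytest.approx(r2.chi_square, abs=1e-10)

    def test_time_rescaling_invariant(self, rng):
        times = rng.exponential(10, size=40)
        events = rng.integers(0, 2, size=40)
        labels = list(rng.choice(["a", "b"], size=40))
        r1 = logrank_test(records_df(times, events), group_series(labels))
        r2 = logrank_test(records_df(times * 365, events), group_series(labels))
        assert r1.p == pytest.approx(r2.p, abs=1e-12)

    def test_single_group_rejected(self):
        rec = records_df([1, 2], [1, 1])
        with pytest.raises(ValueError, match="2 non-empty groups"):
            logrank_test(rec, group_series(["a", "a"]))


class TestHazardRatio:
    def test_identical_groups_hr_one(self):
        times = [1, 2, 3, 4, 5, 6, 7, 8]
        events = [1, 1, 1, 0, 1, 1, 1, 0]
        rec = records_df(times * 2, events * 2, ids=[f"s{i}" for i in range(16)])
        labels = group_series(
            ["high"] * 8 + ["low"] * 8, ids=[f"s{i}" for i in range(16)]
        )
        result = hazard_ratio(rec, labels)
        assert result.hr == pytest.approx(1.0, abs=1e-6)
        assert result.ci_low <= 1.0 <= result.ci_high

    def test_label_swap_inverts_hr(self, rng):
        times = np.concatenate([rng.exponential(5, 30), rng.exponential(10, 30)])
        rec = records_df(times, [1] * 60)
        labels = ["high"] * 30 + ["low"] * 30
        ids = [f"s{i}" for i in range(60)]
        r1 = hazard_ratio(records_df(times, [1] * 60, ids), group_series(labels, ids))
        r2 = hazard_ratio(
            records_df(times, [1] * 60, ids),
            group_series(["low" if l == "high" else "high" for l in labels], ids),
        )
        assert r1.hr == pytest.approx(1 / r2.hr, rel=1e-6)

    def test_no_events_in_group_rejected(self):
        rec = records_df([1, 2, 3, 4], [1, 1, 0, 0])
        labels = group_series(["high", "high", "low", "low"])
        with pytest.raises(ValueError, match="no events"):
            hazard_ratio(rec, labels)

    def test_mantel_haenszel_close_to_cox(self, rng):
        times = np.concatenate([rng.exponential(5, 60), rng.exponential(10, 60)])
        ids = [f"s{i}" for i in range(120)]
        rec = records_df(times, [1] * 120, ids)
        labels = group_series(["high"] * 60 + ["low"] * 60, ids)
        result = hazard_ratio(rec, labels)
        assert result.hr == pytest.approx(result.hr_mantel_haenszel, rel=0.25)

    def test_planted_hazard_direction(self):
        cfg = synthetic.SurvivalSimConfig(n_samples=300, true_hr=2.5, seed=5)
        _, surv = synthetic.simulate_survival_cohort(cfg)
        labels = pd.Series(
            np.where(surv["true_high"], "high", "low").tolist(),
            index=surv["sample_id"],
        )
        result = hazard_ratio(surv, labels)
        assert result.hr > 1.5
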