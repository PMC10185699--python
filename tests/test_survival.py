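"""Survival analysis: KM/log-rank behavior, Cox estimation and guards,
maximally selected cutpoints vs brute force, tertiles, Kruskal-Wallis."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from petclust.survival import (
    categorize_by_cutpoints,
    cluster_param_stats,
    find_cutpoints,
    fit_cox,
    fit_km_logrank,
    tertile_bins,
    univariate_cox_coefficients,
)


def _two_arm(rng, n=300, hr=3.0, censor=0.1):
    arm = rng.integers(0, 2, n)
    t = rng.exponential(1 / (0.01 * hr ** arm))
    e = rng.random(n) > censor
    return arm, t, e


class TestUnivariateCoxCoefficients:
    def test_matches_lifelines_per_column(self, rng):
        n = 100
        X = rng.normal(size=(n, 4))
        t = rng.exponential(np.exp(-X[:, 0] * 0.8) / 0.01)
        e = rng.random(n) < 0.8
        betas = univariate_cox_coefficients(X, t, e)
        for j in range(4):
            df = pd.DataFrame({"x": X[:, j], "t": t, "e": e})
            expected = CoxPHFitter().fit(df, "t", "e").params_["x"]
            assert betas[j] == pytest.approx(expected, abs=1e-4)

    def test_constant_column_zero(self, rng):
        X = np.column_stack([np.ones(50), rng.normal(size=50)])
        t = rng.exponential(100, 50)
        e = np.ones(50, dtype=bool)
        betas, se = univariate_cox_coefficients(X, t, e, return_se=True)
        assert betas[0] == 0.0
        assert np.isinf(se[0])

    def test_no_events_rejected(self, rng):
        with pytest.raises(ValueError, match="event"):
            univariate_cox_coefficients(rng.normal(size=(10, 2)),
                                        rng.random(10), np.zeros(10, dtype=bool))


class TestKMLogrank:
    def test_identical_groups_give_p_one(self):
        t = np.array([5.0, 10.0, 15.0, 20.0] * 2)
        e = np.array([True, True, False, True] * 2)
        g = np.array(["a"] * 4 + ["b"] * 4)
        res = fit_km_logrank(g, t, e)
        assert res.overall_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.overall_p == pytest.approx(1.0)

    def test_curves_start_at_one_and_decrease(self, rng):
        arm, t, e = _two_arm(rng)
        res = fit_km_logrank(arm, t, e)
        for sf in res.curves.values():
            surv = sf["survival"].to_numpy()
            assert surv[0] == 1.0
            assert (np.diff(surv) <= 1e-12).all()
            assert ((0 <= surv) & (surv <= 1)).all()

    def test_planted_hazard_ratio_detected(self, rng):
        arm, t, e = _two_arm(rng, n=300, hr=3.0)
        res = fit_km_logrank(arm, t, e)
        assert res.overall_p < 0.001

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            fit_km_logrank(np.zeros(10), np.arange(1.0, 11.0), np.ones(10, bool))

    def test_asct_style_subgroup_rerun(self, rng):
        """Stratified reruns: the same call works on a covariate subset."""
        arm, t, e = _two_arm(rng, n=200)
        strat = rng.integers(0, 2, 200).astype(bool)
        sub = fit_km_logrank(arm[strat], t[strat], e[strat])
        assert set(sub.group_sizes) == {"0", "1"}


class TestFitCox:
    def test_two_arm_recovery_within_three_se(self, rng):
        arm, t, e = _two_arm(rng, n=500, hr=2.0, censor=0.0)
        df = pd.DataFrame({"arm": arm.astype(float), "pfs_days": t, "event": e})
        fit = fit_cox(df, "arm")
        hr = fit.summary.iloc[0]["hr"]
        assert 1.7 <= hr <= 2.35

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame({"x": np.ones(20), "pfs_days": np.arange(1.0, 21.0),
                           "event": [True] * 20})
        with pytest.raises(ValueError, match="constant"):
            fit_cox(df, "x")

    def test_multivariate_rejects_two_imaging_variables(self, rng):
        n = 60
        df = pd.DataFrame(
            {
                "mtv_group": rng.choice(["low", "high"], n),
                "unsupervised_cluster": rng.choice(["A", "B"], n),
                "pfs_days": rng.exponential(100, n),
                "event": rng.random(n) < 0.8,
            }
        )
        with pytest.raises(ValueError, match="at most one"):
            fit_cox(df, ["mtv_group", "unsupervised_cluster"], mode="multivariate")

    def test_categorical_reference_level(self, rng):
        n = 200
        grp = rng.choice(["low", "moderate", "high"], n)
        df = pd.DataFrame({"mtv_group": grp, "pfs_days": rng.exponential(100, n),
                           "event": rng.random(n) < 0.8})
        fit = fit_cox(df, "mtv_group", references={"mtv_group": "low"})
        assert fit.references["mtv_group"] == "low"
        assert set(fit.summary["category"]) == {"moderate", "high"}

    def test_ci_contains_hr(self, rng):
        arm, t, e = _two_arm(rng, n=200)
        df = pd.DataFrame({"arm": arm.astype(float), "pfs_days": t, "event": e})
        s = fit_cox(df, "arm").summary.iloc[0]
        assert s["ci_low"] <= s["hr"] <= s["ci_high"]


def _slow_logrank_z(high, time, event):
    """Independent textbook implementation of the standardized log-rank
    statistic, used as the oracle for the cutpoint search."""
    U = V = 0.0
    for t in sorted(set(time[event])):
        at = time >= t
        n, n1 = at.sum(), (at & high).sum()
        d = ((time == t) & event).sum()
        d1 = ((time == t) & event & high).sum()
        U += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return U / np.sqrt(V) if V > 0 else 0.0


class TestFindCutpoints:
    def test_planted_changepoint_found(self, rng):
        n = 200
        mtv = rng.uniform(0, 100, n)
        lam = np.where(mtv > 50, 0.02, 0.004)
        t = rng.exponential(1 / lam)
        e = rng.random(n) < 0.9
        res = find_cutpoints(mtv, t, e, n_cuts=1)
        srt = np.sort(mtv)
        gap = np.diff(srt)[np.searchsorted(srt, 50.0) - 1]
        assert abs(res.cutpoints[0] - 50.0) <= max(gap, np.diff(srt).max())

    def test_equals_brute_force_maximizer(self, rng):
        for _ in range(10):
            n = int(rng.integers(15, 50))
            mtv = rng.uniform(0, 10, n)
            t = rng.exponential(50, n)
            e = rng.random(n) < 0.8
            if e.sum() < 2:
                continue
            res = find_cutpoints(mtv, t, e, min_prop=0.1, n_cuts=1)
            uniq = np.sort(np.unique(mtv))
            cands = (uniq[:-1] + uniq[1:]) / 2
            min_n = int(np.ceil(0.1 * n))
            best, best_z = None, -1
            for c in cands:
                hi = mtv > c
                if hi.sum() < min_n or (~hi).sum() < min_n:
                    continue
                z = abs(_slow_logrank_z(hi, t, e))
                if z > best_z:
                    best, best_z = c, z
            assert res.cutpoints[0] == pytest.approx(best)
            assert res.statistic == pytest.approx(best_z, abs=1e-10)

    def test_statistic_equals_trace_maximum(self, rng):
        mtv = rng.uniform(0, 10, 40)
        t = rng.exponential(50, 40)
        e = np.ones(40, dtype=bool)
        res = find_cutpoints(mtv, t, e, n_cuts=1)
        assert res.statistic == res.trace["statistic"].max()

    def test_two_cuts_ordered_and_three_groups(self, rng):
        mtv = rng.uniform(0, 100, 120)
        t = rng.exponential(1 / (0.005 + 0.0002 * mtv))
        e = np.ones(120, dtype=bool)
        res = find_cutpoints(mtv, t, e, n_cuts=2)
        assert len(res.cutpoints) == 2
        assert res.cutpoints[0] < res.cutpoints[1]
        groups = categorize_by_cutpoints(mtv, res.cutpoints)
        assert set(groups) == {"low", "moderate", "high"}

    def test_joint_strategy_respects_min_prop(self, rng):
        mtv = rng.uniform(0, 100, 40)
        t = rng.exponential(100, 40)
        e = np.ones(40, dtype=bool)
        res = find_cutpoints(mtv, t, e, n_cuts=2, strategy="joint")
        counts = pd.Series(categorize_by_cutpoints(mtv, res.cutpoints)).value_counts()
        assert counts.min() >= 4

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            find_cutpoints(np.ones(20), np.arange(1.0, 21.0), np.ones(20, bool))


class TestTertileBins:
    def test_exact_thirds(self):
        labels, cuts = tertile_bins(np.arange(1.0, 10.0))
        assert list(pd.Series(labels).value_counts()[["low", "mid", "high"]]) == [3, 3, 3]
        assert cuts == pytest.approx(tuple(np.percentile(np.arange(1.0, 10.0),
                                                         [100 / 3, 200 / 3])))

    def test_heavy_ties_follow_percentile_rule(self):
        vals = np.array([1.0] * 6 + [2.0, 3.0, 4.0])
        labels, cuts = tertile_bins(vals)
        assert (np.asarray(labels)[vals < cuts[0]] == "low").all()

    def test_too_few_distinct_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            tertile_bins(np.array([1.0, 1.0, 2.0, 2.0]))


def _kruskal_by_hand(samples):
    """Rank-sum H with tie correction, straight from the definition."""
    all_vals = np.concatenate(samples)
    order = np.argsort(all_vals, kind="stable")
    ranks = np.empty(len(all_vals))
    sorted_vals = all_vals[order]
    i = 0
    pos = np.empty(len(all_vals))
    while i < len(sorted_vals):
        j = i
        while j < len(sorted_vals) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        pos[i:j] = (i + j + 1) / 2.0
        i = j
    ranks[order] = pos
    n = len(all_vals)
    start, H = 0, 0.0
    for s in samples:
        r = ranks[start:start + len(s)]
        H += r.sum() ** 2 / len(s)
        start += len(s)
    H = 12.0 / (n * (n + 1)) * H - 3 * (n + 1)
    _, counts = np.unique(all_vals, return_counts=True)
    tie = 1 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    return H / tie


class TestClusterParamStats:
    def test_h_matches_hand_computation_on_worked_table(self):
        vals = np.array([3.1, 4.7, 2.2, 8.9, 6.5, 7.7, 1.0, 9.9, 5.0])
        labels = np.array(["A"] * 3 + ["B"] * 3 + ["C"] * 3)
        params = pd.DataFrame({"mtv_cm3": vals})
        res = cluster_param_stats(params, labels, log_transform=False)
        samples = [vals[labels == g] for g in ("A", "B", "C")]
        assert res["mtv_cm3"]["H"] == pytest.approx(_kruskal_by_hand(samples), abs=1e-10)

    def test_identical_values_h_zero(self):
        params = pd.DataFrame({"suv_max": np.full(9, 2.0)})
        labels = np.array(["A", "B", "C"] * 3)
        res = cluster_param_stats(params, labels)
        assert res["suv_max"]["H"] == 0.0

    def test_shifted_groups_detected(self, rng):
        base = rng.normal(0, 1, 30)
        params = pd.DataFrame(
            {"tlg": np.concatenate([base, base + 3, base + 6]) + 10}
        )
        labels = np.array(["A"] * 30 + ["B"] * 30 + ["C"] * 30)
        res = cluster_param_stats(params, labels)
        assert res["tlg"]["p"] < 0.001
        adj = res["tlg"]["pairwise"]["p_adj"]
        assert (adj < 0.01).all()

    def test_empty_group_rejected(self):
        params = pd.DataFrame({"mtv_cm3": [1.0, 2.0]})
        with pytest.raises(ValueError, match="2 groups"):
            cluster_param_stats(params, np.array(["A", "A"]))
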