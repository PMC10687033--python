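import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test

from clonotrace import km_logrank, maxstat_cutpoint, split_by_maxstat, split_by_median
from clonotrace.survival import standardized_logrank


def logrank_oracle(time, event, group):
    """Risk-table log-rank (O, E, V) for ``group`` by explicit enumeration."""
    n = len(time)
    o = e = v = 0.0
    for t in sorted({time[i] for i in range(n) if event[i]}):
        risk = [i for i in range(n) if time[i] >= t]
        n_at = len(risk)
        n1 = sum(1 for i in risk if group[i])
        d = sum(1 for i in range(n) if event[i] and time[i] == t)
        d1 = sum(1 for i in range(n) if event[i] and time[i] == t and group[i])
        o += d1
        e += d * n1 / n_at
        if n_at > 1:
            v += d * (n1 / n_at) * (1 - n1 / n_at) * (n_at - d) / (n_at - 1)
    return o, e, v


def maxstat_oracle(scores, time, event, min_prop, max_prop):
    """Exhaustive scan coded independently of the implementation."""
    n = len(scores)
    best = None
    for c in sorted(set(scores)):
        n_low = sum(s <= c for s in scores)
        if n_low < min_prop * n or n_low > max_prop * n:
            continue
        group = [s > c for s in scores]
        o, e, v = logrank_oracle(time, event, group)
        stat = abs(o - e) / np.sqrt(v) if v > 0 else 0.0
        if best is None or stat > best[1]:
            best = (c, stat)
    return best


class TestSplitByMedian:
    def test_even_cohort(self):
        scores = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        groups = split_by_median(scores)
        assert set(groups[groups == "high"].index) == {"c", "d"}

    def test_ties_at_median_go_low(self):
        scores = pd.Series([1.0, 2.0, 2.0, 3.0], index=list("abcd"))
        groups = split_by_median(scores)
        assert list(groups[groups == "high"].index) == ["d"]

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(0)
        scores = pd.Series(rng.normal(size=100), index=[f"s{i}" for i in range(100)])
        groups = split_by_median(scores)
        med = float(np.median(scores))
        for s in scores.index:
            assert groups[s] == ("high" if scores[s] > med else "low")

    def test_degenerate_identical_scores(self):
        with pytest.raises(ValueError):
            split_by_median(pd.Series([2.0, 2.0, 2.0]))


class TestMaxstat:
    def make_separable(self, n=30, seed=1):
        rng = np.random.default_rng(seed)
        scores = np.concatenate([rng.normal(0, 0.3, n // 2), rng.normal(3, 0.3, n - n // 2)])
        # high-score cluster survives much longer, with no overlap in times
        time = np.where(scores > 1.5, rng.uniform(10, 20, n), rng.uniform(1, 2, n))
        event = np.ones(n, dtype=bool)
        return pd.Series(scores, index=[f"s{i}" for i in range(n)]), time, event

    def test_cutpoint_falls_between_separated_clusters(self):
        scores, time, event = self.make_separable()
        cut = maxstat_cutpoint(scores, time, event)
        # chosen threshold separates the two score clusters (centres 0 and 3)
        assert -0.5 < cut.cutpoint < 2.0
        groups, _ = split_by_maxstat(scores, time, event)
        assert (groups == "high").sum() == (scores > 1.5).sum()

    def test_permuted_survival_scores_lower_statistic(self):
        scores, time, event = self.make_separable(seed=3)
        rng = np.random.default_rng(9)
        perm = rng.permutation(len(time))
        informative = maxstat_cutpoint(scores, time, event).standardized_statistic
        permuted = maxstat_cutpoint(scores, time[perm], event[perm]).standardized_statistic
        assert permuted < informative

    def test_matches_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(7)
        for trial in range(5):
            n = 30
            scores = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
            time = np.maximum(rng.exponential(5, n), 0.01)
            event = rng.random(n) > 0.3
            got = maxstat_cutpoint(scores, time, event, 0.1, 0.9)
            exp_cut, exp_stat = maxstat_oracle(
                scores.tolist(), time.tolist(), event.tolist(), 0.1, 0.9
            )
            assert got.cutpoint == pytest.approx(exp_cut, abs=1e-12)
            assert got.standardized_statistic == pytest.approx(exp_stat, abs=1e-10)

    def test_statistic_at_least_median_split(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n = 40
            scores = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
            time = np.maximum(rng.exponential(5, n), 0.01)
            event = rng.random(n) > 0.3
            cut = maxstat_cutpoint(scores, time, event)
            med_groups = split_by_median(scores)
            med_stat = standardized_logrank(time, event, (med_groups == "high").to_numpy())
            assert cut.standardized_statistic >= med_stat - 1e-12

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            maxstat_cutpoint(
                pd.Series([1.0, 2.0, 3.0]), np.array([1, 2, 3]), np.array([1, 1, 1])
            )

    def test_no_admissible_candidate_rejected(self):
        scores = pd.Series(np.arange(12, dtype=float))
        time = np.arange(1.0, 13.0)
        event = np.ones(12, dtype=int)
        # n_low would have to land in [5.4, 5.76]: no integer qualifies
        with pytest.raises(ValueError):
            maxstat_cutpoint(scores, time, event, min_prop=0.45, max_prop=0.48)


class TestKMLogrank:
    def test_identical_groups_null_test(self):
        time = np.array([1.0, 2.0, 3.0, 4.0] * 2)
        event = np.array([1, 0, 1, 1] * 2)
        groups = np.array(["a"] * 4 + ["b"] * 4)
        cmp_ = km_logrank(time, event, groups)
        assert cmp_.logrank_chi2 == pytest.approx(0.0, abs=1e-12)
        assert cmp_.logrank_p == pytest.approx(1.0, abs=1e-12)

    def test_no_events_flat_curves_no_median(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.zeros(4, dtype=int)
        groups = np.array(["a", "a", "b", "b"])
        cmp_ = km_logrank(time, event, groups)
        for curve in cmp_.curves.values():
            assert np.all(curve.survival == 1.0)
            assert curve.median is None

    def test_uncensored_km_equals_empirical_survivor(self):
        rng = np.random.default_rng(2)
        time = rng.exponential(5, size=40)
        event = np.ones(40, dtype=int)
        groups = np.array(["a"] * 20 + ["b"] * 20)
        cmp_ = km_logrank(time, event, groups)
        for lab, mask in [("a", slice(0, 20)), ("b", slice(20, 40))]:
            t_grp = time[mask]
            curve = cmp_.curves[lab]
            for t, s in zip(curve.times, curve.survival):
                assert s == pytest.approx(np.mean(t_grp > t), abs=1e-12)

    def test_chi2_matches_risk_table_oracle_and_lifelines(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            n = 24
            time = np.maximum(rng.exponential(4, n).round(1), 0.1)  # induce ties
            event = (rng.random(n) > 0.3).astype(int)
            groups = np.where(rng.random(n) > 0.5, "hi", "lo")
            cmp_ = km_logrank(time, event, groups)
            o, e, v = logrank_oracle(time.tolist(), event.tolist(), (groups == "lo").tolist())
            assert cmp_.logrank_chi2 == pytest.approx((o - e) ** 2 / v, abs=1e-10)
            ref = logrank_test(
                time[groups == "hi"], time[groups == "lo"],
                event[groups == "hi"], event[groups == "lo"],
            )
            assert cmp_.logrank_chi2 == pytest.approx(ref.test_statistic, abs=1e-8)
            assert cmp_.logrank_p == pytest.approx(ref.p_value, abs=1e-8)

    def test_median_is_first_time_survival_drops_to_half(self):
        # 4 subjects, all events: S = 0.75, 0.5, 0.25, 0 -> median at 2nd time
        time = np.array([1.0, 2.0, 3.0, 4.0, 10.0, 11.0, 12.0, 13.0])
        event = np.ones(8, dtype=int)
        groups = np.array(["a"] * 4 + ["b"] * 4)
        cmp_ = km_logrank(time, event, groups)
        assert cmp_.curves["a"].median == pytest.approx(2.0)
        assert cmp_.curves["b"].median == pytest.approx(11.0)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            km_logrank([1.0, 2.0], [1, 1], ["a", "a"])  # one group
        with pytest.raises(ValueError):
            km_logrank([0.0, 2.0], [1, 1], ["a", "b"])  # non-positive time
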